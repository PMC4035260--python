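import numpy as np
import pytest

import palmvein as pv

BENCHMARK_SEED = 7          # master seed of the shared synthetic benchmark


@pytest.fixture(scope="session")
def small_records():
    """3 identities x 2 samples, cheap enough for unit-level checks."""
    return pv.generate_gallery_records(3, 2, master_seed=11)


@pytest.fixture(scope="session")
def palm_sample():
    """One rendered palm with realistic degradation, plus its identity."""
    ident = pv.generate_identity(42)
    img, tform = pv.render_sample(ident, pv.AcquisitionSpec(
        rotation=5.0, illumination_gradient=0.25, blur_sigma=1.0,
        noise_sigma=4.0, seed=1))
    return ident, img, tform


@pytest.fixture(scope="session")
def benchmark_20x4():
    """The full seeded verification benchmark: 20 identities x 4 samples."""
    records = pv.generate_gallery_records(20, 4, master_seed=BENCHMARK_SEED)
    return pv.run_benchmark(records)


@pytest.fixture(scope="session")
def robustness_sweep():
    """RootSIFT-vs-SIFT match counts over the rotation/scale grids."""
    return pv.descriptor_robustness_sweep(identity_seed=BENCHMARK_SEED, acq_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
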