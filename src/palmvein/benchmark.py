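"""Ground-truth benchmarking of the pipeline on synthetic galleries.

Because every synthetic sample carries its exact forward transform, a
candidate correspondence between two samples of the same identity can be
labelled true or false by reprojection: map the first keypoint through
H_b @ inv(H_a) and call the match *true* iff it lands within a tolerance
(default 3 px) of the second keypoint.  Matches between different
identities are false by definition.  This yields exact precision/recall
accounting for the mismatch-removal filters, plus genuine/impostor score
lists (with and without filtering) for EER analysis — all from a single
pass over the gallery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import features as ft
from . import mismatch_removal as mm
from .synthetic_veins import SampleRecord
from .verification import (EvalReport, PalmFeatures, PipelineConfig,
                           ScoreRecord, extract_features, report_from_records)


@dataclass
class FilterBenchmark:
    """Aggregate outcome of one benchmark pass over a synthetic gallery."""

    n_true: int = 0
    n_false: int = 0
    true_kept: int = 0
    false_removed: int = 0
    records_filtered: List[ScoreRecord] = field(default_factory=list)
    records_unfiltered: List[ScoreRecord] = field(default_factory=list)

    @property
    def true_retention(self) -> float:
        return self.true_kept / self.n_true if self.n_true else float("nan")

    @property
    def false_removal(self) -> float:
        return self.false_removed / self.n_false if self.n_false else float("nan")

    def report(self, filtered: bool = True) -> EvalReport:
        return report_from_records(self.records_filtered if filtered
                                   else self.records_unfiltered)


def match_truth_labels(pairs: Sequence[ft.MatchPair],
                       fa: PalmFeatures, fb: PalmFeatures,
                       rec_a: SampleRecord, rec_b: SampleRecord,
                       tolerance: float = 3.0) -> List[bool]:
    """Ground-truth labels for candidate matches between two samples.

    True iff the samples share an identity and the first keypoint, mapped
    through the ground-truth inter-sample homography, lands within
    ``tolerance`` px of the second keypoint.
    """
    if rec_a.identity_id != rec_b.identity_id:
        return [False] * len(pairs)
    H = rec_b.transform.params @ np.linalg.inv(rec_a.transform.params)
    labels = []
    for p in pairs:
        ka = fa.desc.keypoints[p.index_a]
        kb = fb.desc.keypoints[p.index_b]
        v = H @ np.array([ka.x, ka.y, 1.0])
        err = float(np.hypot(v[0] / v[2] - kb.x, v[1] / v[2] - kb.y))
        labels.append(err <= tolerance)
    return labels


def run_benchmark(records: Sequence[SampleRecord],
                  cfg: PipelineConfig = PipelineConfig(),
                  tolerance: float = 3.0) -> FilterBenchmark:
    """Score every unordered sample pair and tally filter ground truth.

    Returns filtered and unfiltered genuine/impostor score records together
    with true-match retention and false-match removal rates of the
    hierarchical filter at the configured thresholds.
    """
    feats: Dict[Tuple[str, str], PalmFeatures] = {}
    for rec in records:
        feats[(rec.identity_id, rec.sample_id)] = extract_features(rec.image, cfg)

    out = FilterBenchmark()
    recs = list(records)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            ra, rb = recs[i], recs[j]
            fa = feats[(ra.identity_id, ra.sample_id)]
            fb = feats[(rb.identity_id, rb.sample_id)]
            pairs = ft.match(fa.desc, fb.desc, cfg.match)
            filtered = mm.hierarchical_filter(
                pairs, fa.desc.keypoints, fb.desc.keypoints,
                fa.mask, fb.mask, fa.enhanced, fb.enhanced,
                cfg.neighbor, cfg.lbp, _lbp_cache=(fa.lbp_cache, fb.lbp_cache))
            truth = match_truth_labels(pairs, fa, fb, ra, rb, tolerance)
            for is_true, label in zip(truth, filtered.labels):
                kept = label is mm.MatchLabel.KEPT
                if is_true:
                    out.n_true += 1
                    out.true_kept += kept
                else:
                    out.n_false += 1
                    out.false_removed += not kept
            genuine = ra.identity_id == rb.identity_id
            out.records_filtered.append(ScoreRecord(
                ra.identity_id, rb.identity_id, ra.sample_id, rb.sample_id,
                filtered.kept_count, genuine))
            out.records_unfiltered.append(ScoreRecord(
                ra.identity_id, rb.identity_id, ra.sample_id, rb.sample_id,
                len(pairs), genuine))
    return out


def descriptor_robustness_sweep(identity_seed: int,
                                rotations: Sequence[float] = (0, 5, 10, 15, 20),
                                scales: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2),
                                cfg: PipelineConfig = PipelineConfig(),
                                acq_seed: int = 0) -> Dict[str, List[dict]]:
    """Ratio-test match counts of RootSIFT vs plain SIFT under rotation/scale.

    Renders one synthetic sample, digitally rotates (about the centre) or
    rescales it, and counts the matches each descriptor normalization
    yields between the original and the transformed image — the classical
    robustness sweep for comparing the two descriptor variants.
    """
    from skimage.transform import rescale, rotate

    from .synthetic_veins import AcquisitionSpec, BACKGROUND, generate_identity, render_sample

    ident = generate_identity(identity_seed)
    img0, _ = render_sample(ident, AcquisitionSpec(
        illumination_gradient=0.25, blur_sigma=1.0, noise_sigma=4.0, seed=acq_seed))

    def to_frame(arr: np.ndarray) -> np.ndarray:
        h, w = img0.shape
        out = np.full((h, w), BACKGROUND)
        ah, aw = arr.shape
        r0, c0 = (h - ah) // 2, (w - aw) // 2
        rs, cs = max(r0, 0), max(c0, 0)
        hs, ws = min(ah, h), min(aw, w)
        out[rs:rs + hs, cs:cs + ws] = arr[max(-r0, 0):max(-r0, 0) + hs,
                                          max(-c0, 0):max(-c0, 0) + ws]
        return np.clip(np.round(out), 0, 255).astype(np.uint8)

    feats0 = {root: extract_features(img0, cfg.with_overrides(use_root_sift=root))
              for root in (True, False)}

    def counts(img_t: np.ndarray) -> Tuple[int, int]:
        vals = []
        for root in (True, False):
            f1 = extract_features(img_t, cfg.with_overrides(use_root_sift=root))
            vals.append(len(ft.match(feats0[root].desc, f1.desc, cfg.match)))
        return vals[0], vals[1]

    result: Dict[str, List[dict]] = {"rotation": [], "scale": []}
    for rot in rotations:
        warped = np.clip(np.round(rotate(img0, rot, preserve_range=True,
                                         cval=BACKGROUND)), 0, 255).astype(np.uint8)
        n_root, n_sift = counts(warped)
        result["rotation"].append({"value": float(rot), "rootsift": n_root,
                                   "sift": n_sift})
    for sc in scales:
        warped = to_frame(rescale(img0.astype(np.float64), sc, preserve_range=True))
        n_root, n_sift = counts(warped)
        result["scale"].append({"value": float(sc), "rootsift": n_root,
                                "sift": n_sift})
    return result
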