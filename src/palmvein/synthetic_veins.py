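"""Seeded synthetic NIR-like palm-vein image generator.

Provides ground-truth-labelled test data for every pipeline stage: each
*identity* is a reproducible hand-shaped polygon (palm disk, five finger
lobes and a forearm stub, the latter exercising the wrist crop) carrying a
random branching vein tree; each *sample* renders that identity under an
acquisition perturbation (rotation / scale / translation / perspective
tilt, multiplicative illumination gradient, Gaussian blur and noise) that
emulates the posture and illumination variation of contact-free NIR
capture: a brighter hand region on a dark background with veins as darker
curvilinear structures, low contrast and uneven lighting.

Every artifact is a pure function of integer seeds, so regeneration is
bit-identical, genuine pairs share their vein topology by construction,
and the exact pixel-level forward transform of each sample is returned for
correspondence oracles.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon
from skimage.transform import ProjectiveTransform, warp

CANVAS: Tuple[int, int] = (256, 256)   # (rows, cols) of the canonical render
BACKGROUND = 10.0                      # dark NIR background intensity
VEIN_CONTRAST = 35.0                   # vein darkening below hand intensity, pre-blur


# ---------------------------------------------------------------------------
# Identity (hand shape + vein tree)
# ---------------------------------------------------------------------------

@dataclass
class IdentitySpec:
    """A reproducible synthetic identity.

    ``tree`` is a list of (polyline, width) pairs; polylines are (N, 2)
    float arrays in (x, y) pixel coordinates, widths in pixels.
    ``hand_outline`` is the closed (M, 2) polygon of the hand silhouette
    (forearm stub included).  All branch points lie inside the outline.
    """

    seed: int
    tree: List[Tuple[np.ndarray, float]]
    hand_outline: np.ndarray
    base_intensity: float = 170.0
    texture_seed: int = 0
    texture_amplitude: float = 12.0


def _hand_polygon(rng: np.random.Generator) -> Polygon:
    """Palm disk + five finger capsules + forearm stub, mildly jittered."""
    h, w = CANVAS
    cx = w / 2 + rng.uniform(-4, 4)
    cy = h * 0.54 + rng.uniform(-4, 4)
    palm_r = rng.uniform(48, 54)
    parts = [Point(cx, cy).buffer(palm_r, quad_segs=24)]
    # four fingers fanned upward plus a thumb off to the side
    angles = np.deg2rad([-38, -17, 2, 21])
    for ang in angles:
        ang = ang + rng.uniform(-0.04, 0.04)
        length = rng.uniform(58, 80)
        width = rng.uniform(8, 11)
        x0 = cx + 0.85 * palm_r * np.sin(ang)
        y0 = cy - 0.85 * palm_r * np.cos(ang)
        x1 = x0 + length * np.sin(ang)
        y1 = y0 - length * np.cos(ang)
        parts.append(LineString([(x0, y0), (x1, y1)]).buffer(width, quad_segs=8))
    thumb_ang = np.deg2rad(rng.uniform(62, 72))
    x0 = cx - 0.75 * palm_r * np.sin(thumb_ang)
    y0 = cy - 0.75 * palm_r * np.cos(thumb_ang)
    x1 = x0 - rng.uniform(35, 48) * np.sin(thumb_ang)
    y1 = y0 - rng.uniform(35, 48) * np.cos(thumb_ang)
    parts.append(LineString([(x0, y0), (x1, y1)]).buffer(rng.uniform(9, 11), quad_segs=8))
    # forearm stub running off the bottom edge (removed later by the wrist crop)
    stub_half = rng.uniform(18, 24)
    parts.append(Polygon([(cx - stub_half, cy), (cx + stub_half, cy),
                          (cx + stub_half, h - 2), (cx - stub_half, h - 2)]))
    merged = unary_union(parts)
    if merged.geom_type != "Polygon":  # pragma: no cover - construction keeps parts joined
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def _grow_branch(rng: np.random.Generator, region: Polygon,
                 start: np.ndarray, heading: float,
                 n_steps: int, step: float) -> np.ndarray:
    """Random-walk polyline confined to ``region`` (rejection on steps)."""
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.28)
        for attempt in range(8):
            cand = pos + step * np.array([np.sin(heading), -np.cos(heading)])
            if region.contains(Point(cand)):
                pos = cand
                pts.append(pos.copy())
                break
            heading += rng.uniform(-1.2, 1.2)
        else:
            break
    return np.array(pts)


def generate_identity(seed: int) -> IdentitySpec:
    """Deterministically build the hand outline and vein tree for a seed."""
    rng = np.random.default_rng(seed)
    outline = _hand_polygon(rng)
    interior = outline.buffer(-4.0)
    minx, miny, maxx, maxy = interior.bounds

    tree: List[Tuple[np.ndarray, float]] = []
    n_roots = int(rng.integers(2, 5))
    for _ in range(n_roots):
        for _attempt in range(50):
            start = np.array([rng.uniform(minx, maxx),
                              rng.uniform(0.55 * (miny + maxy), maxy)])
            if interior.contains(Point(start)):
                break
        heading = rng.normal(0.0, 0.5)          # roughly upward
        trunk = _grow_branch(rng, interior, start, heading,
                             n_steps=int(rng.integers(25, 45)), step=5.0)
        if len(trunk) < 3:
            continue
        tree.append((trunk, float(rng.uniform(2.5, 4.0))))
        # side branches off the trunk
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.integers(2, len(trunk)))
            side = _grow_branch(rng, interior, trunk[k].copy(),
                                heading + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2),
                                n_steps=int(rng.integers(10, 25)), step=5.0)
            if len(side) >= 3:
                tree.append((side, float(rng.uniform(1.8, 3.0))))

    for polyline, _w in tree:
        assert all(outline.contains(Point(p)) for p in polyline)
    return IdentitySpec(seed=seed, tree=tree,
                        hand_outline=np.asarray(outline.exterior.coords, dtype=np.float64),
                        base_intensity=float(rng.uniform(160, 185)),
                        texture_seed=int(rng.integers(0, 2 ** 31)),
                        texture_amplitude=float(rng.uniform(10.0, 14.0)))


# ---------------------------------------------------------------------------
# Acquisition (posture + photometry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """One simulated capture: geometric pose + photometric degradation.

    rotation (deg, in-plane), scale (isotropic, about the image centre),
    translation (dx, dy) px, perspective_tilt (deg, forward/backward hand
    tilt realized as a projective foreshortening), illumination_gradient
    (fractional amplitude of a multiplicative linear ramp),
    blur_sigma / noise_sigma (px / 8-bit intensity units), seed (noise and
    ramp direction).
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: Tuple[float, float] = (0.0, 0.0)
    perspective_tilt: float = 0.0
    illumination_gradient: float = 0.0
    illumination_direction: Optional[float] = None  # degrees; None -> from seed
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.scale <= 2.0):
            raise ValueError("scale must lie in [0.5, 2]")


def acquisition_transform(acq: AcquisitionSpec,
                          shape: Tuple[int, int] = CANVAS) -> ProjectiveTransform:
    """Forward homography (canonical (x, y) -> sample (x, y)) for a capture."""
    h, w = shape
    cx, cy = w / 2.0, h / 2.0
    theta = np.deg2rad(acq.rotation)
    s = acq.scale
    rot_scale = np.array([[s * np.cos(theta), -s * np.sin(theta), 0.0],
                          [s * np.sin(theta), s * np.cos(theta), 0.0],
                          [0.0, 0.0, 1.0]])
    # projective foreshortening about the centre; tan(tilt) scaled by frame size
    g = np.tan(np.deg2rad(acq.perspective_tilt)) / (1.5 * h)
    persp = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, g, 1.0]])
    to_centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    back = np.array([[1, 0, cx + acq.translation[0]],
                     [0, 1, cy + acq.translation[1]], [0, 0, 1.0]])
    return ProjectiveTransform(matrix=back @ persp @ rot_scale @ to_centre)


def _rasterize_identity(identity: IdentitySpec) -> np.ndarray:
    """Canonical float render: bright hand, darker veins, dark background."""
    h, w = CANVAS
    hand = np.zeros(CANVAS, dtype=bool)
    rr, cc = draw_polygon(identity.hand_outline[:, 1], identity.hand_outline[:, 0],
                          shape=CANVAS)
    hand[rr, cc] = True

    veins = np.zeros(CANVAS, dtype=bool)
    for polyline, width in identity.tree:
        pts = []  # dense sampling of the polyline at sub-pixel spacing
        for p0, p1 in zip(polyline[:-1], polyline[1:]):
            seg_len = np.linalg.norm(p1 - p0)
            n = max(2, int(np.ceil(seg_len * 2)))
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts.append(p0[None, :] * (1 - t) + p1[None, :] * t)
        pts = np.vstack(pts)
        centerline = np.zeros(CANVAS, dtype=bool)
        ix = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        iy = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        centerline[ix, iy] = True
        r = max(1, int(round(width / 2)))
        yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
        veins |= ndimage.binary_dilation(centerline, structure=yy ** 2 + xx ** 2 <= r ** 2)

    img = np.full(CANVAS, BACKGROUND)
    img[hand] = identity.base_intensity
    img[veins & hand] = identity.base_intensity - VEIN_CONTRAST
    # identity-locked skin micro-texture: a smooth random field that warps
    # with the hand, emulating the stable mottle of real NIR palm skin
    # (without it every patch between veins would be pure per-sample noise
    # and patch texture could not identify correspondences)
    trng = np.random.default_rng(identity.texture_seed)
    field = ndimage.gaussian_filter(trng.normal(0.0, 1.0, CANVAS), 3.5)
    field /= max(field.std(), 1e-9)
    img[hand] += identity.texture_amplitude * field[hand]
    return img


def render_sample(identity: IdentitySpec,
                  acq: AcquisitionSpec = AcquisitionSpec()
                  ) -> Tuple[np.ndarray, ProjectiveTransform]:
    """Render one capture of an identity.

    Returns the 8-bit image and the exact forward transform mapping
    canonical identity coordinates (x, y) to sample coordinates, for use
    as a correspondence oracle.

    Raises
    ------
    ValueError
        If the warp pushes the hand fully out of frame.
    """
    canonical = _rasterize_identity(identity)
    tform = acquisition_transform(acq)
    sample = warp(canonical, tform.inverse, order=1, cval=BACKGROUND,
                  preserve_range=True)
    if sample.max() < identity.base_intensity - VEIN_CONTRAST - 5:
        raise ValueError("warp pushed the hand out of frame")

    rng = np.random.default_rng(acq.seed)
    if acq.illumination_gradient > 0:
        h, w = CANVAS
        if acq.illumination_direction is None:
            direction = rng.uniform(0, 2 * np.pi)
        else:
            direction = np.deg2rad(acq.illumination_direction)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (xx - w / 2) * np.cos(direction) + (yy - h / 2) * np.sin(direction)
        # normalize so the ramp spans [-1, 1] across the hand itself: the
        # gradient fraction then measures modulation over the palm, not the frame
        content = sample > BACKGROUND + 20
        span = u[content] if content.any() else u
        lo, hi = span.min(), span.max()
        u = 2.0 * (u - lo) / max(hi - lo, 1e-9) - 1.0
        sample = sample * (1.0 + acq.illumination_gradient * u)
    if acq.blur_sigma > 0:
        sample = ndimage.gaussian_filter(sample, acq.blur_sigma)
    if acq.noise_sigma > 0:
        sample = sample + rng.normal(0.0, acq.noise_sigma, size=sample.shape)
    return np.clip(np.round(sample), 0, 255).astype(np.uint8), tform


# ---------------------------------------------------------------------------
# Gallery generation
# ---------------------------------------------------------------------------

#: The six posture archetypes of contact-free capture: scale down/up,
#: in-plane tilt left/right, perspective tilt forward/backward.
POSTURES: List[Dict[str, float]] = [
    {"scale": 0.8},
    {"scale": 1.2},
    {"rotation": 15.0},
    {"rotation": -15.0},
    {"perspective_tilt": 10.0},
    {"perspective_tilt": -10.0},
]


@dataclass
class SampleRecord:
    """One rendered gallery sample plus its provenance."""

    identity_id: str
    sample_id: str
    image: np.ndarray
    transform: ProjectiveTransform
    acq: AcquisitionSpec
    identity_seed: int
    posture: int


def _sample_acquisition(rng: np.random.Generator, posture_idx: int,
                        seed: int) -> AcquisitionSpec:
    base = POSTURES[posture_idx % len(POSTURES)]
    return AcquisitionSpec(
        rotation=base.get("rotation", 0.0) + rng.uniform(-3, 3),
        scale=float(np.clip(base.get("scale", 1.0) + rng.uniform(-0.05, 0.05), 0.5, 2.0)),
        translation=(rng.uniform(-8, 8), rng.uniform(-8, 8)),
        perspective_tilt=base.get("perspective_tilt", 0.0) + rng.uniform(-2, 2),
        illumination_gradient=rng.uniform(0.15, 0.35),
        blur_sigma=rng.uniform(0.8, 1.2),
        noise_sigma=rng.uniform(3.0, 5.0),
        seed=seed,
    )


def generate_gallery_records(n_identities: int, n_samples: int,
                             master_seed: int) -> List[SampleRecord]:
    """Render a labelled gallery in memory; pure function of the seed."""
    if n_identities < 2 or n_samples < 2:
        raise ValueError("need at least 2 identities with 2 samples each")
    records: List[SampleRecord] = []
    root = np.random.SeedSequence(master_seed)
    id_seqs = root.spawn(n_identities)
    for i, seq in enumerate(id_seqs):
        id_seed = int(seq.generate_state(1)[0] % (2 ** 31))
        identity = generate_identity(id_seed)
        sample_rng = np.random.default_rng(seq)
        for j in range(n_samples):
            acq_seed = int(sample_rng.integers(0, 2 ** 31))
            acq = _sample_acquisition(sample_rng, j, acq_seed)
            image, tform = render_sample(identity, acq)
            records.append(SampleRecord(
                identity_id=f"id_{i:03d}", sample_id=f"s{j:02d}",
                image=image, transform=tform, acq=acq,
                identity_seed=id_seed, posture=j % len(POSTURES)))
    return records


def generate_gallery(n_identities: int, n_samples: int, master_seed: int,
                     out_dir: str) -> List[SampleRecord]:
    """Write a gallery to ``out_dir`` as out_dir/<identity>/<sample>.png
    plus a metadata.json recording seeds, acquisition parameters and the
    3x3 forward transform of every sample."""
    import imageio.v3 as iio

    records = generate_gallery_records(n_identities, n_samples, master_seed)
    meta = {"master_seed": master_seed, "n_identities": n_identities,
            "n_samples": n_samples, "samples": []}
    for rec in records:
        d = os.path.join(out_dir, rec.identity_id)
        os.makedirs(d, exist_ok=True)
        iio.imwrite(os.path.join(d, rec.sample_id + ".png"), rec.image)
        meta["samples"].append({
            "identity_id": rec.identity_id, "sample_id": rec.sample_id,
            "identity_seed": rec.identity_seed, "posture": rec.posture,
            "acquisition": asdict(rec.acq),
            "transform": rec.transform.params.tolist(),
        })
    with open(os.path.join(out_dir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return records
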