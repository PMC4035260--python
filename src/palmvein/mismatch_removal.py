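"""Hierarchical mismatch removal for palm-vein keypoint correspondences.

Ratio-test matching on vein images leaves many false correspondences
because vein textures repeat across the palm.  Two cheap geometric/textural
consistency filters remove most of them:

1.  Neighbor-based filter.  Express each matched keypoint in coordinates
    relative to its palm-mask centroid (optionally normalized by the mask's
    equivalent radius, which cancels isotropic scale).  A genuine
    correspondence maps to nearly the same relative position in both
    images, so pairs with a large relative-coordinate displacement are
    mismatches.

2.  LBP-based filter.  Compare the uniform local-binary-pattern histograms
    of fixed-size patches centred at the two matched points; genuinely
    corresponding points sit on the same vein micro-texture and give close
    histograms, mismatches do not.

Both filters are anti-extensive (they only ever remove pairs) and
idempotent.  The surviving pair count is the similarity score used for
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import Keypoint, MatchPair
from .preprocess import PalmMask


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborFilterConfig:
    """First-layer filter on centroid-relative keypoint coordinates.

    With ``scale_normalize`` the relative coordinates are divided by each
    mask's equivalent radius sqrt(area/pi) and the threshold is in those
    dimensionless units (0.35 of a palm radius by default, the equal point
    of true-match retention vs false-match removal on the seeded synthetic
    calibration fixtures); otherwise the threshold is in raw pixels.
    """

    distance_threshold: float = 0.35
    scale_normalize: bool = True

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")


class HistogramDistance(str, Enum):
    CHI_SQUARE = "chi_square"
    L1 = "l1"
    INTERSECTION = "intersection"


@dataclass(frozen=True)
class LBPFilterConfig:
    """Second-layer filter on uniform-LBP histograms of match patches.

    ``patch_size`` is the side of the square region around each matched
    point (default 32: (32-2)^2 = 900 codes, enough mass for a stable
    59-bin histogram while staying local).  ``distance_threshold`` applies
    to the chi-square histogram distance by default; see
    :func:`lbp_histogram_distance` for the alternatives.
    """

    patch_size: int = 32
    neighbors: int = 8
    radius: int = 1
    histogram_bins: int = 59
    distance_threshold: float = 200.0
    distance_kind: HistogramDistance = HistogramDistance.CHI_SQUARE

    def __post_init__(self) -> None:
        if self.patch_size < 4 or self.patch_size % 2:
            raise ValueError("patch_size must be an even integer >= 4")
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")


class MatchLabel(str, Enum):
    KEPT = "kept"
    REMOVED_NEIGHBOR = "removed_neighbor"
    REMOVED_LBP = "removed_lbp"


@dataclass
class FilteredMatches:
    """Match pairs with per-stage removal labels (parallel lists)."""

    pairs: List[MatchPair]
    labels: List[MatchLabel]
    reasons: Dict[int, str] = field(default_factory=dict)  # index -> removal note

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels):
            raise ValueError("labels must parallel pairs")

    @classmethod
    def raw(cls, pairs: Sequence[MatchPair]) -> "FilteredMatches":
        return cls(list(pairs), [MatchLabel.KEPT] * len(pairs))

    @property
    def kept(self) -> List[MatchPair]:
        return [p for p, l in zip(self.pairs, self.labels) if l is MatchLabel.KEPT]

    @property
    def kept_count(self) -> int:
        return sum(1 for l in self.labels if l is MatchLabel.KEPT)


# ---------------------------------------------------------------------------
# Layer 1: neighbor-based filtering
# ---------------------------------------------------------------------------

def neighbor_filter(matches: FilteredMatches,
                    kps_a: Sequence[Keypoint], kps_b: Sequence[Keypoint],
                    mask_a: PalmMask, mask_b: PalmMask,
                    cfg: NeighborFilterConfig = NeighborFilterConfig()) -> FilteredMatches:
    """Remove pairs whose centroid-relative coordinates disagree.

    For a pair (p_a, p_b): r_a = p_a - centroid(mask_a), r_b = p_b -
    centroid(mask_b) (each divided by its mask's equivalent radius when
    ``scale_normalize``); the pair is labelled ``removed_neighbor`` iff
    d = ||r_a - r_b|| exceeds the threshold.  Centroid-relative coordinates
    cancel translation exactly; radius normalization cancels isotropic
    scale.
    """
    if mask_a.area == 0 or mask_b.area == 0:
        raise ValueError("empty mask")
    ca = np.array([mask_a.centroid[1], mask_a.centroid[0]])  # (x, y)
    cb = np.array([mask_b.centroid[1], mask_b.centroid[0]])
    sa = mask_a.equivalent_radius if cfg.scale_normalize else 1.0
    sb = mask_b.equivalent_radius if cfg.scale_normalize else 1.0

    labels = list(matches.labels)
    reasons = dict(matches.reasons)
    for i, (pair, label) in enumerate(zip(matches.pairs, labels)):
        if label is not MatchLabel.KEPT:
            continue
        ka, kb = kps_a[pair.index_a], kps_b[pair.index_b]
        r_a = (np.array([ka.x, ka.y]) - ca) / sa
        r_b = (np.array([kb.x, kb.y]) - cb) / sb
        d = float(np.linalg.norm(r_a - r_b))
        if d > cfg.distance_threshold:
            labels[i] = MatchLabel.REMOVED_NEIGHBOR
            reasons[i] = f"relative displacement {d:.3f} > {cfg.distance_threshold}"
    return FilteredMatches(list(matches.pairs), labels, reasons)


# ---------------------------------------------------------------------------
# Layer 2: LBP-histogram filtering
# ---------------------------------------------------------------------------

def lbp_code(patch: np.ndarray) -> int:
    """8-bit LBP code of a full 3x3 block.

    code = sum_p s(g_p - g_c) 2^p with s(x) = 1 iff x >= 0 (ties count as
    greater-or-equal) and neighbors enumerated clockwise from the top-left
    corner.  A constant patch therefore codes to 255.
    """
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError("lbp_code expects a 3x3 block")
    center = patch[1, 1]
    order = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    code = 0
    for p, (r, c) in enumerate(order):
        if int(patch[r, c]) - int(center) >= 0:
            code |= 1 << p
    return code


def _transitions(code: int) -> int:
    """Number of circular 0/1 transitions in the 8-bit pattern."""
    bits = [(code >> p) & 1 for p in range(8)]
    return sum(bits[p] != bits[(p + 1) % 8] for p in range(8))


def _uniform_bin_table() -> np.ndarray:
    """Map each 8-bit code to its uniform-LBP bin: 58 uniform bins (by
    ascending code) + 1 shared bin (index 58) for non-uniform patterns."""
    table = np.empty(256, dtype=np.int64)
    nxt = 0
    for code in range(256):
        if _transitions(code) <= 2:
            table[code] = nxt
            nxt += 1
        else:
            table[code] = 58
    assert nxt == 58
    return table


_UNIFORM_TABLE = _uniform_bin_table()


def _lbp_codes_window(window: np.ndarray) -> np.ndarray:
    """Vectorized LBP codes at every interior pixel of a window."""
    w = window.astype(np.int64)
    center = w[1:-1, 1:-1]
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    codes = np.zeros_like(center)
    for p, (dr, dc) in enumerate(shifts):
        neighbor = w[1 + dr: w.shape[0] - 1 + dr, 1 + dc: w.shape[1] - 1 + dc]
        codes |= ((neighbor - center) >= 0).astype(np.int64) << p
    return codes


def uniform_lbp_histogram(img: np.ndarray, center: Keypoint,
                          cfg: LBPFilterConfig = LBPFilterConfig()) -> np.ndarray:
    """59-bin uniform-LBP histogram of the patch_size window around a keypoint.

    Codes are computed at every interior pixel of the window, so the
    histogram mass is exactly (patch_size - 2)^2.  Uniform patterns (at
    most two circular bit transitions) get their own bin; the rest share
    one.  Because LBP compares only signs of intensity differences, the
    histogram is invariant under non-clipping additive intensity offsets.

    Raises
    ------
    ValueError
        "patch out of bounds" when the window does not fit in the image.
    """
    img = np.asarray(img)
    half = cfg.patch_size // 2
    r0 = int(round(center.y)) - half
    c0 = int(round(center.x)) - half
    if r0 < 0 or c0 < 0 or r0 + cfg.patch_size > img.shape[0] or c0 + cfg.patch_size > img.shape[1]:
        raise ValueError("patch out of bounds")
    window = img[r0:r0 + cfg.patch_size, c0:c0 + cfg.patch_size]
    codes = _lbp_codes_window(window)
    return np.bincount(_UNIFORM_TABLE[codes.ravel()], minlength=59).astype(np.float64)


def lbp_histogram_distance(h1: np.ndarray, h2: np.ndarray,
                           kind: HistogramDistance = HistogramDistance.CHI_SQUARE) -> float:
    """Distance between two LBP histograms of equal size and total mass.

    chi_square:     sum_i (h1_i - h2_i)^2 / (h1_i + h2_i), empty bins skipped;
    l1:             sum_i |h1_i - h2_i|;
    intersection:   total mass minus sum_i min(h1_i, h2_i).

    All three are symmetric, nonnegative and zero iff the histograms are
    identical.
    """
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have equal bin counts")
    kind = HistogramDistance(kind)
    if kind is HistogramDistance.CHI_SQUARE:
        denom = h1 + h2
        nz = denom > 0
        return float((((h1 - h2) ** 2)[nz] / denom[nz]).sum())
    if kind is HistogramDistance.L1:
        return float(np.abs(h1 - h2).sum())
    return float(h1.sum() - np.minimum(h1, h2).sum())


def lbp_filter(matches: FilteredMatches,
               img_a: np.ndarray, img_b: np.ndarray,
               kps_a: Sequence[Keypoint], kps_b: Sequence[Keypoint],
               cfg: LBPFilterConfig = LBPFilterConfig(),
               _cache: Optional[Tuple[dict, dict]] = None) -> FilteredMatches:
    """Relabel kept pairs whose patch LBP-histogram distance is too large.

    Operates only on pairs currently labelled kept.  Pairs whose patch
    exits either image are removed conservatively with a logged reason.
    ``_cache`` optionally shares per-keypoint histogram memos across calls
    on the same images.
    """
    cache_a, cache_b = _cache if _cache is not None else ({}, {})

    def histo(img, kps, cache, idx):
        if idx not in cache:
            try:
                cache[idx] = uniform_lbp_histogram(img, kps[idx], cfg)
            except ValueError:
                cache[idx] = None
        return cache[idx]

    labels = list(matches.labels)
    reasons = dict(matches.reasons)
    for i, (pair, label) in enumerate(zip(matches.pairs, labels)):
        if label is not MatchLabel.KEPT:
            continue
        h1 = histo(img_a, kps_a, cache_a, pair.index_a)
        h2 = histo(img_b, kps_b, cache_b, pair.index_b)
        if h1 is None or h2 is None:
            labels[i] = MatchLabel.REMOVED_LBP
            reasons[i] = "patch out of bounds"
            continue
        d = lbp_histogram_distance(h1, h2, cfg.distance_kind)
        if d > cfg.distance_threshold:
            labels[i] = MatchLabel.REMOVED_LBP
            reasons[i] = f"LBP histogram distance {d:.1f} > {cfg.distance_threshold}"
    return FilteredMatches(list(matches.pairs), labels, reasons)


# ---------------------------------------------------------------------------
# Two-layer composition
# ---------------------------------------------------------------------------

def hierarchical_filter(pairs: Sequence[MatchPair],
                        kps_a: Sequence[Keypoint], kps_b: Sequence[Keypoint],
                        mask_a: PalmMask, mask_b: PalmMask,
                        img_a: np.ndarray, img_b: np.ndarray,
                        neighbor_cfg: NeighborFilterConfig = NeighborFilterConfig(),
                        lbp_cfg: LBPFilterConfig = LBPFilterConfig(),
                        _lbp_cache: Optional[Tuple[dict, dict]] = None) -> FilteredMatches:
    """Neighbor-based filtering, then LBP-based filtering of the survivors."""
    first = neighbor_filter(FilteredMatches.raw(pairs), kps_a, kps_b,
                            mask_a, mask_b, neighbor_cfg)
    return lbp_filter(first, img_a, img_b, kps_a, kps_b, lbp_cfg, _cache=_lbp_cache)
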