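"""Scale-invariant keypoint extraction and RootSIFT matching.

SIFT descriptors are 128-D histograms of local gradient orientations, i.e.
nonnegative vectors.  Comparing them with the Hellinger kernel
H(x, y) = sum_i sqrt(x_i y_i) (on L1-normalized descriptors) rather than
plain Euclidean distance markedly improves matching stability; the RootSIFT
trick implements this by the elementwise map v -> sqrt(v / sum(v)), after
which ordinary Euclidean distance satisfies

    ||x' - y'||^2 = 2 - 2 H(x_hat, y_hat)

so any Euclidean nearest-neighbour machinery computes Hellinger matching
unchanged.  Candidate correspondences are accepted by Lowe's ratio test:
a query descriptor matches its nearest gallery neighbour only if the
nearest/second-nearest distance ratio falls below ``dist_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

from .preprocess import PalmMask


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Keypoint:
    x: float              # column coordinate, pixels
    y: float              # row coordinate, pixels
    scale: float
    orientation: float    # radians


@dataclass
class DescriptorSet:
    """Parallel arrays of keypoints and their 128-D nonnegative descriptors."""

    vectors: np.ndarray                 # (N, 128) float64, entries >= 0
    keypoints: List[Keypoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.size == 0:
            self.vectors = self.vectors.reshape(0, 128)
        if self.vectors.shape[0] != len(self.keypoints):
            raise ValueError("vectors and keypoints must be parallel")
        if self.vectors.size and self.vectors.min() < 0:
            raise ValueError("descriptor entries must be nonnegative")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return np.array([[kp.x, kp.y] for kp in self.keypoints]).reshape(-1, 2)


@dataclass(frozen=True)
class MatchParams:
    """Lowe ratio-test parameters.

    ``dist_ratio`` in (0, 1]: accept a candidate only if nearest /
    second-nearest distance < dist_ratio.  ``mutual`` additionally requires
    the pair to survive the reverse-direction test.
    """

    dist_ratio: float = 0.8
    mutual: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.dist_ratio <= 1):
            raise ValueError("dist_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class MatchPair:
    index_a: int
    index_b: int
    distance: float
    ratio: float


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_sift(img: np.ndarray, mask: Optional[PalmMask] = None) -> DescriptorSet:
    """Detect scale-space keypoints and raw SIFT descriptors.

    Keypoints whose (x, y) location falls outside the mask are discarded.
    An image with no extrema yields an empty set, not an error.
    """
    img = np.asarray(img)
    detector = SIFT()
    try:
        detector.detect_and_extract(img)
    except RuntimeError:  # backend signals "no keypoints" by raising
        return DescriptorSet(np.empty((0, 128)), [])
    pos = detector.positions          # (N, 2) subpixel (row, col)
    vectors = detector.descriptors.astype(np.float64)
    keypoints = [
        Keypoint(x=float(c), y=float(r), scale=float(s), orientation=float(o))
        for (r, c), s, o in zip(pos, detector.scales, detector.orientations)
    ]
    if mask is not None and keypoints:
        h, w = mask.bits.shape
        keep = []
        for i, kp in enumerate(keypoints):
            r, c = int(round(kp.y)), int(round(kp.x))
            if 0 <= r < h and 0 <= c < w and mask.bits[r, c]:
                keep.append(i)
        vectors = vectors[keep]
        keypoints = [keypoints[i] for i in keep]
    return DescriptorSet(vectors, keypoints)


# ---------------------------------------------------------------------------
# RootSIFT transform and Hellinger kernel
# ---------------------------------------------------------------------------

def root_sift(d: DescriptorSet) -> DescriptorSet:
    """Map every descriptor v to sqrt(v / sum(v)).

    Output rows have unit Euclidean norm (||sqrt(v/sum v)||^2 = sum v_i/sum v
    = 1).  Rows with zero L1 mass carry no gradient information and are
    dropped together with their keypoints.
    """
    if len(d) == 0:
        return DescriptorSet(np.empty((0, 128)), [])
    sums = d.vectors.sum(axis=1)
    keep = sums > 0
    vectors = np.sqrt(d.vectors[keep] / sums[keep, None])
    keypoints = [kp for kp, k in zip(d.keypoints, keep) if k]
    return DescriptorSet(vectors, keypoints)


def l2_normalize(d: DescriptorSet) -> DescriptorSet:
    """Euclidean-unit normalization of raw descriptors (the plain-SIFT route)."""
    if len(d) == 0:
        return DescriptorSet(np.empty((0, 128)), [])
    norms = np.linalg.norm(d.vectors, axis=1)
    keep = norms > 0
    vectors = d.vectors[keep] / norms[keep, None]
    keypoints = [kp for kp, k in zip(d.keypoints, keep) if k]
    return DescriptorSet(vectors, keypoints)


def hellinger(x: np.ndarray, y: np.ndarray) -> float:
    """Hellinger kernel sum_i sqrt(x_i y_i) of two L1-normalized vectors.

    Both inputs must be nonnegative with unit L1 norm (tolerance 1e-8).
    Symmetric, H(x, x) = 1, and 0 for disjoint supports.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    for v in (x, y):
        if v.min() < 0 or abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("inputs must be nonnegative with unit L1 norm")
    return float(np.sqrt(x * y).sum())


# ---------------------------------------------------------------------------
# Ratio-test matching
# ---------------------------------------------------------------------------

def _check_unit_rows(vectors: np.ndarray, name: str) -> None:
    if vectors.size == 0:
        return
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError(f"{name} descriptors are not unit-normalized; "
                         "apply root_sift (or l2_normalize) first")


def _one_directional(a: np.ndarray, b: np.ndarray, dist_ratio: float) -> List[MatchPair]:
    dists = cdist(a, b)                    # Euclidean
    pairs: List[MatchPair] = []
    for i in range(dists.shape[0]):
        order = np.argsort(dists[i], kind="stable")  # ties -> smaller index
        j1, j2 = int(order[0]), int(order[1])
        d1, d2 = float(dists[i, j1]), float(dists[i, j2])
        ratio = d1 / d2 if d2 > 0 else 1.0  # duplicate gallery rows: reject
        if ratio < dist_ratio:
            pairs.append(MatchPair(index_a=i, index_b=j1, distance=d1, ratio=ratio))
    return pairs


def match(a: DescriptorSet, b: DescriptorSet,
          p: MatchParams = MatchParams()) -> List[MatchPair]:
    """Nearest-neighbour matching of unit-normalized descriptor sets.

    For each row of ``a`` the nearest and second-nearest rows of ``b`` (in
    Euclidean distance, which on RootSIFT vectors realizes the Hellinger
    kernel) are found; a pair is emitted iff d1/d2 < ``p.dist_ratio``.
    If ``b`` has fewer than 2 rows no pair can pass the ratio test.
    One-directional a -> b by default; ``p.mutual`` intersects with the
    reverse direction.
    """
    _check_unit_rows(a.vectors, "query")
    _check_unit_rows(b.vectors, "gallery")
    if len(a) == 0 or len(b) < 2:
        return []
    pairs = _one_directional(a.vectors, b.vectors, p.dist_ratio)
    if p.mutual and len(a) >= 2:
        reverse = {(q.index_b, q.index_a) for q in
                   _one_directional(b.vectors, a.vectors, p.dist_ratio)}
        pairs = [q for q in pairs if (q.index_a, q.index_b) in reverse]
    return pairs


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def descriptors_to_tsv(d: DescriptorSet, path: str) -> None:
    header = ["kp_x", "kp_y", "scale", "orientation"] + [f"d{i}" for i in range(128)]
    rows = [
        [kp.x, kp.y, kp.scale, kp.orientation] + list(v)
        for kp, v in zip(d.keypoints, d.vectors)
    ]
    _write_tsv(path, header, rows)


def matches_to_tsv(pairs: List[MatchPair], a: DescriptorSet, b: DescriptorSet,
                   path: str, labels: Optional[List[str]] = None) -> None:
    header = ["index_a", "index_b", "x_a", "y_a", "x_b", "y_b", "distance", "ratio"]
    if labels is not None:
        header.append("label")
    rows = []
    for k, q in enumerate(pairs):
        ka, kb = a.keypoints[q.index_a], b.keypoints[q.index_b]
        row = [q.index_a, q.index_b, ka.x, ka.y, kb.x, kb.y, q.distance, q.ratio]
        if labels is not None:
            row.append(labels[k])
        rows.append(row)
    _write_tsv(path, header, rows)


def _write_tsv(path: str, header: List[str], rows: List[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
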