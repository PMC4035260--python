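"""Verification scoring and FAR / FRR / EER evaluation.

The similarity score between two palm images is the number of keypoint
correspondences that survive the full pipeline (preprocess -> SIFT ->
RootSIFT -> ratio-test matching -> hierarchical mismatch removal); a
genuine pair (same identity) keeps many correspondences, an impostor pair
few.  Sweeping a decision threshold over the integer scores yields the
false acceptance rate FAR(t) (impostor scores >= t) and false rejection
rate FRR(t) (genuine scores < t); the equal error rate EER is the value
at their crossing, found by linear interpolation since the curves are step
functions of an integer threshold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import features as ft
from . import mismatch_removal as mm
from .preprocess import PalmMask, PreprocessConfig, SegmentationError, preprocess


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to score a pair of palm images."""

    preprocess: PreprocessConfig = PreprocessConfig()
    match: ft.MatchParams = ft.MatchParams()
    neighbor: mm.NeighborFilterConfig = mm.NeighborFilterConfig()
    lbp: mm.LBPFilterConfig = mm.LBPFilterConfig()
    use_root_sift: bool = True        # False: plain L2-normalized SIFT
    mismatch_removal: bool = True
    symmetric: bool = False           # score = min(a->b, b->a)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


@dataclass
class PalmFeatures:
    """Per-image cache: enhanced image, mask, normalized descriptors."""

    enhanced: np.ndarray
    mask: PalmMask
    desc: ft.DescriptorSet
    lbp_cache: dict = field(default_factory=dict)


def extract_features(img: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> PalmFeatures:
    """Run the per-image half of the pipeline once (reusable across pairs)."""
    enhanced, mask = preprocess(img, cfg.preprocess)
    raw = ft.detect_sift(enhanced, mask)
    desc = ft.root_sift(raw) if cfg.use_root_sift else ft.l2_normalize(raw)
    return PalmFeatures(enhanced=enhanced, mask=mask, desc=desc)


def score_features(fa: PalmFeatures, fb: PalmFeatures,
                   cfg: PipelineConfig = PipelineConfig()) -> Tuple[int, mm.FilteredMatches]:
    """Match two feature caches and count surviving correspondences."""
    pairs = ft.match(fa.desc, fb.desc, cfg.match)
    if cfg.mismatch_removal:
        filtered = mm.hierarchical_filter(
            pairs, fa.desc.keypoints, fb.desc.keypoints, fa.mask, fb.mask,
            fa.enhanced, fb.enhanced, cfg.neighbor, cfg.lbp,
            _lbp_cache=(fa.lbp_cache, fb.lbp_cache))
    else:
        filtered = mm.FilteredMatches.raw(pairs)
    return filtered.kept_count, filtered


def similarity_score(img_a: np.ndarray, img_b: np.ndarray,
                     cfg: PipelineConfig = PipelineConfig()) -> int:
    """Surviving-match count between two palm images.

    Propagates :class:`SegmentationError` for unsegmentable inputs (a
    missing score, not zero).  ``cfg.symmetric`` scores both directions and
    takes the minimum.
    """
    fa = extract_features(img_a, cfg)
    fb = extract_features(img_b, cfg)
    score, _ = score_features(fa, fb, cfg)
    if cfg.symmetric:
        score_ba, _ = score_features(fb, fa, cfg)
        score = min(score, score_ba)
    return score


# ---------------------------------------------------------------------------
# FAR / FRR / EER
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreRecord:
    id_a: str
    id_b: str
    sample_a: str
    sample_b: str
    score: int
    genuine: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")
        if self.genuine != (self.id_a == self.id_b):
            raise ValueError("genuine flag inconsistent with identity labels")


@dataclass
class RocCurve:
    thresholds: np.ndarray   # ascending
    far: np.ndarray          # non-increasing, in [0, 1]
    frr: np.ndarray          # non-decreasing, in [0, 1]

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.far = np.asarray(self.far, dtype=np.float64)
        self.frr = np.asarray(self.frr, dtype=np.float64)
        if not (len(self.thresholds) == len(self.far) == len(self.frr)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.far) > 1e-12) or np.any(np.diff(self.frr) < -1e-12):
            raise ValueError("FAR must be non-increasing and FRR non-decreasing")


@dataclass
class EvalReport:
    eer: float
    eer_threshold: float
    n_genuine: int
    n_impostor: int
    curve: RocCurve
    records: List[ScoreRecord] = field(default_factory=list)


def far_frr(records: Sequence[ScoreRecord]) -> RocCurve:
    """FAR / FRR over every integer threshold spanning the score range.

    FAR(t) = fraction of impostor scores >= t, FRR(t) = fraction of genuine
    scores < t.  Thresholds run from min(score) (FAR 1, FRR 0) through
    max(score)+1 (FAR 0, FRR 1) so the curves always cross.
    """
    genuine = np.array([r.score for r in records if r.genuine])
    impostor = np.array([r.score for r in records if not r.genuine])
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one genuine and one impostor record")
    scores = np.concatenate([genuine, impostor])
    thresholds = np.arange(scores.min(), scores.max() + 2)
    far = np.array([(impostor >= t).mean() for t in thresholds])
    frr = np.array([(genuine < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, far=far, frr=frr)


def eer(curve: RocCurve) -> Tuple[float, float]:
    """Equal error rate and its threshold, by linear interpolation.

    Finds the first threshold where FAR - FRR changes sign and solves the
    two-segment linear crossing; fully separated score distributions give
    EER 0 at the first threshold where both rates vanish.
    """
    diff = curve.far - curve.frr
    idx = np.nonzero(diff <= 0)[0]
    if idx.size == 0:  # degenerate: curves never cross inside the range
        k = int(np.argmin(np.abs(diff)))
        return float((curve.far[k] + curve.frr[k]) / 2), float(curve.thresholds[k])
    k = int(idx[0])
    if diff[k] == 0 or k == 0:
        return float(curve.far[k]), float(curve.thresholds[k])
    f0, f1 = curve.far[k - 1], curve.far[k]
    r0, r1 = curve.frr[k - 1], curve.frr[k]
    s = (f0 - r0) / ((r1 - r0) - (f1 - f0))
    value = f0 + (f1 - f0) * s
    threshold = curve.thresholds[k - 1] + s * (curve.thresholds[k] - curve.thresholds[k - 1])
    return float(value), float(threshold)


# ---------------------------------------------------------------------------
# Gallery evaluation
# ---------------------------------------------------------------------------

Gallery = Dict[str, Dict[str, np.ndarray]]  # identity -> sample -> image


def load_gallery(root: str) -> Gallery:
    """Read a directory laid out as root/<identity_id>/<sample_id>.png."""
    import imageio.v3 as iio

    gallery: Gallery = {}
    ids = sorted(d for d in os.listdir(root)
                 if os.path.isdir(os.path.join(root, d)))
    for identity in ids:
        samples = {}
        for fname in sorted(os.listdir(os.path.join(root, identity))):
            stem, ext = os.path.splitext(fname)
            if ext.lower() in {".png", ".pgm", ".jpg", ".jpeg"}:
                samples[stem] = np.asarray(iio.imread(os.path.join(root, identity, fname)))
        if samples:
            gallery[identity] = samples
    if len(gallery) < 2 or any(len(s) < 2 for s in gallery.values()):
        raise ValueError("degenerate gallery: need >= 2 identities with >= 2 samples")
    return gallery


def score_gallery(gallery: Gallery,
                  cfg: PipelineConfig = PipelineConfig(),
                  protocol: str = "all_pairs") -> List[ScoreRecord]:
    """Score genuine and impostor comparisons of a labelled gallery.

    ``all_pairs`` scores every unordered pair of distinct samples once
    (both within and across identities); ``first_sample_enrollment``
    enrolls each identity's first sample and probes all later samples
    against every enrolled sample.  Unsegmentable samples are dropped from
    the protocol (missing scores, not zeros).  Deterministic given config
    and gallery ordering.
    """
    if len(gallery) < 2 or any(len(s) < 2 for s in gallery.values()):
        raise ValueError("degenerate gallery: need >= 2 identities with >= 2 samples")
    keys = [(i, s) for i in sorted(gallery) for s in sorted(gallery[i])]
    feats: Dict[Tuple[str, str], Optional[PalmFeatures]] = {}
    for key in keys:
        try:
            feats[key] = extract_features(gallery[key[0]][key[1]], cfg)
        except (SegmentationError, ValueError):
            feats[key] = None
    keys = [k for k in keys if feats[k] is not None]

    if protocol == "all_pairs":
        candidates = [(keys[i], keys[j])
                      for i in range(len(keys)) for j in range(i + 1, len(keys))]
    elif protocol == "first_sample_enrollment":
        first = {}
        for i, s in keys:
            first.setdefault(i, (i, s))
        enrolled = sorted(first.values())
        probes = [k for k in keys if k not in set(enrolled)]
        candidates = [(e, p) for e in enrolled for p in probes]
    else:
        raise ValueError(f"unknown protocol: {protocol}")

    records = []
    for (ia, sa), (ib, sb) in candidates:
        score, _ = score_features(feats[(ia, sa)], feats[(ib, sb)], cfg)
        if cfg.symmetric:
            score_ba, _ = score_features(feats[(ib, sb)], feats[(ia, sa)], cfg)
            score = min(score, score_ba)
        records.append(ScoreRecord(id_a=ia, id_b=ib, sample_a=sa, sample_b=sb,
                                   score=score, genuine=ia == ib))
    return records


def evaluate(gallery: Gallery,
             cfg: PipelineConfig = PipelineConfig(),
             protocol: str = "all_pairs") -> EvalReport:
    """Score a gallery and report the ROC curve and EER."""
    records = score_gallery(gallery, cfg, protocol)
    curve = far_frr(records)
    value, threshold = eer(curve)
    return EvalReport(eer=value, eer_threshold=threshold,
                      n_genuine=sum(r.genuine for r in records),
                      n_impostor=sum(not r.genuine for r in records),
                      curve=curve, records=records)


def report_from_records(records: Sequence[ScoreRecord]) -> EvalReport:
    """Build an :class:`EvalReport` from precomputed score records."""
    curve = far_frr(records)
    value, threshold = eer(curve)
    return EvalReport(eer=value, eer_threshold=threshold,
                      n_genuine=sum(r.genuine for r in records),
                      n_impostor=sum(not r.genuine for r in records),
                      curve=curve, records=list(records))
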