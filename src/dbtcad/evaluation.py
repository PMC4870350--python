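"""Detection scoring and FROC analysis.

A detection is a true positive iff its bounding cube shares strictly
positive overlap volume with any ground-truth box; face- or edge-touching
counts as zero overlap and hence a false positive.  Metrics use view-based
pooling: sensitivity over all truths across volumes, false positives
averaged per volume (with a separate split for truth-containing versus
truth-free volumes).  The FROC curve sweeps the detection score and its
partial area over ``[0, fp_max]`` false positives per volume, divided by
``fp_max``, summarizes the detector (perfect detector -> 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fp_reduction import DetectedMCC
from .volume_io import Annotation


def box_overlap_volume(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection volume (mm^3) of two (3, 2) axis-aligned boxes."""
    lo = np.maximum(a[:, 0], b[:, 0])
    hi = np.minimum(a[:, 1], b[:, 1])
    edges = np.clip(hi - lo, 0.0, None)
    return float(np.prod(edges))


@dataclass
class MatchResult:
    """Per-volume matching of detections against ground truth."""

    det_is_tp: list[bool]
    truth_detected: list[bool]
    overlap_mm3: np.ndarray  # (n_det, n_truth)

    @property
    def n_tp(self) -> int:
        return sum(self.det_is_tp)

    @property
    def n_fp(self) -> int:
        return len(self.det_is_tp) - self.n_tp

    @property
    def n_truth(self) -> int:
        return len(self.truth_detected)

    @property
    def n_detected_truths(self) -> int:
        return sum(self.truth_detected)

    @property
    def sensitivity(self) -> float | None:
        """Detected truths / truths; None (not applicable) without truths."""
        if not self.truth_detected:
            return None
        return self.n_detected_truths / self.n_truth


@dataclass
class CaseMetrics:
    """View-based pooled metrics over a set of volumes."""

    sensitivity: float | None
    fps_per_volume: float
    fps_per_positive_volume: float | None
    fps_per_negative_volume: float | None
    n_volumes: int
    n_truths: int


@dataclass
class FROCResult:
    """Operating points (FPs/volume, sensitivity) sorted by FPs ascending."""

    points: np.ndarray  # (n, 2) columns: fps_per_volume, sensitivity
    thresholds: np.ndarray
    fp_max: float | None = None
    area_normalized: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


def match_detections(
    dets: list[DetectedMCC], truths: list[Annotation]
) -> MatchResult:
    """Pairwise box-intersection matching with the overlap>0 criterion.

    A detection overlapping several truths validates all of them; a truth
    overlapped by several detections is detected once.
    """
    overlap = np.zeros((len(dets), len(truths)))
    for i, d in enumerate(dets):
        for j, t in enumerate(truths):
            overlap[i, j] = box_overlap_volume(d.cube.bounds, t.box)
    det_is_tp = list((overlap > 0).any(axis=1)) if truths else [False] * len(dets)
    truth_detected = list((overlap > 0).any(axis=0)) if dets else [False] * len(truths)
    return MatchResult(det_is_tp, truth_detected, overlap)


def case_metrics(matches: list[MatchResult]) -> CaseMetrics:
    """Pool per-volume matches: overall sensitivity, mean FPs per volume,
    and the FP split between truth-containing and truth-free volumes."""
    if not matches:
        raise ValidationError("case_metrics requires at least one volume")
    n_truths = sum(m.n_truth for m in matches)
    n_detected = sum(m.n_detected_truths for m in matches)
    fps = np.array([m.n_fp for m in matches], dtype=float)
    positive = np.array([m.n_truth > 0 for m in matches])
    return CaseMetrics(
        sensitivity=(n_detected / n_truths) if n_truths else None,
        fps_per_volume=float(fps.mean()),
        fps_per_positive_volume=float(fps[positive].mean()) if positive.any() else None,
        fps_per_negative_volume=float(fps[~positive].mean()) if (~positive).any() else None,
        n_volumes=len(matches),
        n_truths=n_truths,
    )


def froc_curve(
    dets_per_volume: list[list[DetectedMCC]],
    truths_per_volume: list[list[Annotation]],
) -> FROCResult:
    """FROC operating points from score-carrying detections.

    The threshold sweeps the sorted distinct scores plus a +inf sentinel
    (zero detections kept); at each threshold detections with
    ``score >= threshold`` are kept and view-based metrics recomputed.  The
    overlap structure is computed once per volume, so the sweep is exact and
    cheap: a truth is detected at threshold t iff the best score among its
    overlapping detections is >= t, and a detection is an FP at t iff it
    overlaps no truth and scores >= t.
    """
    if len(dets_per_volume) != len(truths_per_volume):
        raise ValidationError("detections and truths must align per volume")
    n_vol = len(dets_per_volume)
    if n_vol == 0:
        raise ValidationError("froc_curve requires at least one volume")
    for dets in dets_per_volume:
        if any(not np.isfinite(d.score) for d in dets):
            raise ValidationError("every detection must carry a finite score")

    fp_scores: list[float] = []
    truth_best: list[float] = []  # best overlapping score per truth (-inf if none)
    n_truths = 0
    for dets, truths in zip(dets_per_volume, truths_per_volume):
        m = match_detections(dets, truths)
        scores = np.array([d.score for d in dets], dtype=float)
        for i, tp in enumerate(m.det_is_tp):
            if not tp:
                fp_scores.append(scores[i])
        for j in range(len(truths)):
            hits = scores[m.overlap_mm3[:, j] > 0] if dets else np.array([])
            truth_best.append(float(hits.max()) if hits.size else -np.inf)
        n_truths += len(truths)

    all_scores = np.concatenate([np.array(fp_scores), np.array(truth_best)])
    finite = all_scores[np.isfinite(all_scores)]
    thresholds = np.concatenate([np.unique(finite), [np.inf]])
    fp_sorted = np.sort(np.array(fp_scores))
    tb = np.array(truth_best)

    pts = []
    for t in thresholds:
        n_fp = len(fp_sorted) - np.searchsorted(fp_sorted, t, side="left")
        sens = float((tb >= t).sum() / n_truths) if n_truths else 0.0
        pts.append((n_fp / n_vol, sens))
    pts = sorted(set(pts))
    return FROCResult(points=np.array(pts), thresholds=thresholds)


def froc_area_normalized(fr: FROCResult, fp_max: float) -> float:
    """Partial area under the FROC curve over [0, fp_max] FPs/volume,
    normalized by ``fp_max`` so a detector at sensitivity 1 everywhere
    scores 1.0.

    The piecewise-linear curve through the operating points is extended
    rightward at its last sensitivity; points beyond ``fp_max`` are clipped
    by interpolation.
    """
    if fp_max <= 0:
        raise ValidationError("fp_max must be positive")
    pts = fr.points[np.lexsort((fr.points[:, 1], fr.points[:, 0]))]
    x, y = pts[:, 0], pts[:, 1]
    if x[-1] < fp_max:
        x = np.append(x, fp_max)
        y = np.append(y, y[-1])
    yi = np.interp(fp_max, x, y)
    keep = x <= fp_max
    xc = np.append(x[keep], fp_max)
    yc = np.append(y[keep], yi)
    area = float(np.trapezoid(yc, xc))
    return area / fp_max


def plot_froc(fr: FROCResult, path) -> None:
    """Render the FROC curve to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = fr.points[np.argsort(fr.points[:, 0])]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(pts[:, 0], pts[:, 1], drawstyle="default", marker="o", ms=3)
    ax.set_xlabel("false positives per volume")
    ax.set_ylabel("sensitivity")
    ax.set_ylim(0, 1.05)
    ax.grid(alpha=0.3)
    if fr.area_normalized is not None and fr.fp_max is not None:
        ax.set_title(f"area {fr.area_normalized:.3f} over [0, {fr.fp_max:g}] FP/vol")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
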