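"""Detection scoring against reference points, depth curves and agreement.

Detection metrics follow the focus-detection convention
    accuracy  = TP / (TP + FN + FP)      (a Jaccard-style index)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
computed from a one-to-one matching between detected and reference
centroids. Bland–Altman limits of agreement summarize per-image count
differences between two raters or methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulator import GroundTruth

DEFAULT_MATCH_RADIUS_PX = 30.0


@dataclass
class MatchResult:
    """One-to-one matching between detection and reference point sets."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (detection index, reference index)
    match_radius_px: float
    n_detections: int = 0
    n_reference: int = 0

    @property
    def matched_reference(self) -> set[int]:
        return {j for _, j in self.pairs}


@dataclass
class DetectionMetrics:
    accuracy: float
    precision: float
    recall: float


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float

    @property
    def loa_halfwidth(self) -> float:
        return (self.loa_high - self.loa_low) / 2.0


def match_detections(
    detections: np.ndarray,
    reference: np.ndarray,
    match_radius_px: float = DEFAULT_MATCH_RADIUS_PX,
) -> MatchResult:
    """Greedily match detections to reference points by ascending distance.

    Candidate pairs within ``match_radius_px`` are sorted by distance (ties
    by detection then reference index) and accepted one-to-one. Unmatched
    detections count as FP, unmatched reference points as FN.
    """
    if match_radius_px <= 0:
        raise ValueError("match radius must be positive")
    det = np.asarray(detections, dtype=np.float64).reshape(-1, 2)
    ref = np.asarray(reference, dtype=np.float64).reshape(-1, 2)
    nd, nr = len(det), len(ref)
    pairs: list[tuple[int, int]] = []
    if nd and nr:
        dist = np.hypot(det[:, None, 0] - ref[None, :, 0], det[:, None, 1] - ref[None, :, 1])
        ii, jj = np.nonzero(dist <= match_radius_px)
        order = sorted(range(len(ii)), key=lambda k: (dist[ii[k], jj[k]], ii[k], jj[k]))
        used_d: set[int] = set()
        used_r: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=nd - tp,
        fn=nr - tp,
        pairs=pairs,
        match_radius_px=match_radius_px,
        n_detections=nd,
        n_reference=nr,
    )


def detection_metrics(m: MatchResult) -> DetectionMetrics:
    """Accuracy, precision, recall from TP/FP/FN counts.

    All-zero counts make the metrics undefined; they are reported as NaN
    with a warning, never as 0.
    """
    if m.tp + m.fp + m.fn == 0:
        warnings.warn("no detections and no reference points: metrics undefined", stacklevel=2)
        return DetectionMetrics(float("nan"), float("nan"), float("nan"))
    accuracy = m.tp / (m.tp + m.fn + m.fp)
    precision = m.tp / (m.tp + m.fp) if m.tp + m.fp > 0 else float("nan")
    recall = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else float("nan")
    return DetectionMetrics(accuracy, precision, recall)


def depth_detection_curve(
    matches: MatchResult,
    truth: GroundTruth,
    bin_um: float = 50.0,
) -> list[tuple[float, float]]:
    """Percent of ground-truth foci detected per depth bin.

    Returns (bin lower edge µm, percent detected) for every bin containing
    at least one truth focus. Reference indices in ``matches`` must refer to
    ``truth`` entries in order.
    """
    if len(truth) != matches.n_reference:
        raise ValueError("ground truth length differs from the matched reference set")
    detected = np.zeros(len(truth), dtype=bool)
    for _, j in matches.pairs:
        detected[j] = True
    return pooled_depth_curve(truth.depth_um, detected, bin_um)


def pooled_depth_curve(
    depths_um: np.ndarray,
    detected: np.ndarray,
    bin_um: float = 50.0,
) -> list[tuple[float, float]]:
    """Depth curve from pooled per-focus depth and detected flags."""
    depths_um = np.asarray(depths_um, dtype=np.float64)
    detected = np.asarray(detected, dtype=bool)
    if len(depths_um) != len(detected):
        raise ValueError("depths and detected flags must have equal length")
    out = []
    if len(depths_um) == 0:
        return out
    nbins = int(np.floor(depths_um.max() / bin_um)) + 1
    for b in range(nbins):
        lo, hi = b * bin_um, (b + 1) * bin_um
        sel = (depths_um >= lo) & (depths_um < hi)
        if not sel.any():
            continue
        out.append((float(lo), 100.0 * float(detected[sel].mean())))
    return out


def bland_altman(counts_a: np.ndarray, counts_b: np.ndarray) -> BlandAltman:
    """Bland–Altman bias and 95% limits of agreement of paired counts.

    Differences d = a − b; bias = mean(d); LOA = bias ± 1.96 · SD(d) with
    the sample standard deviation.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired counts")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)
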