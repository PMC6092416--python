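"""Candidate foci detection: the intensity and gradient pipelines.

Shallow foci ride mostly on ballistic photons and appear as bright,
well-bounded peaks in the intensity image; deep foci survive only as
coherent gradient flow. Both pipelines therefore share one peak-extraction
engine, the extended maxima transform (EXMAX): the regional maxima of the
h-maxima transform (morphological reconstruction of ``raster − h`` under
``raster``). Its single parameter h is the minimum peak prominence.

Because the best h varies between images, it is set adaptively per image:
a heuristic scan picks the h whose component count is most stable, then the
candidate step deliberately over-counts by lowering h until the count would
exceed ``n`` times the heuristic count (over-counting ratio n, default 2).
The surplus candidates are later removed by the trained classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.filters import threshold_otsu

from .focus_flow import DEFAULT_RADIUS_PX, FlowMap, focus_flow_map
from .image_model import CandidateSet, ForegroundMask, Provenance, TissueImage


@dataclass
class ExmaxParams:
    """Extended-maxima parameters: prominence h and minimum region size."""

    h_value: float
    min_region_px: int = 4

    def __post_init__(self) -> None:
        if self.h_value <= 0:
            raise ValueError("h_value must be positive")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")


@dataclass
class HeuristicResult:
    """Outcome of the adaptive h scan.

    ``scan`` is the full (h, count) table for auditing; ``h_star`` is the
    midpoint of the longest count-stability plateau and ``count_star`` the
    component count there. ``low_confidence`` flags scans without a stable
    plateau (noise-dominated rasters).
    """

    h_star: float
    count_star: int
    scan: list[tuple[float, int]]
    low_confidence: bool = False


@dataclass
class DetectConfig:
    """Tunable parameters of the candidate-detection pipelines."""

    mean_size: int = 3
    median_size: int = 3
    flow_radius_px: int = DEFAULT_RADIUS_PX
    gradient_method: str = "central"  # or "sobel"
    overcount: float = 2.0
    h_steps: int = 32
    mad_k: float = 3.0
    min_region_px: int = 4
    count_cap: int = 500
    min_plateau_len: int = 4
    plateau_rtol: float = 0.15
    chan_vese_iters: int = 35
    chan_vese_smoothing: int = 3


@dataclass
class DetectionResult:
    """Candidates from both pipelines plus the intermediates they share."""

    intensity: CandidateSet
    gradient: CandidateSet
    mask: ForegroundMask
    flow: FlowMap
    preprocessed: TissueImage
    intensity_scan: HeuristicResult | None = None
    gradient_scan: HeuristicResult | None = None


def segment_tissue(image: TissueImage, config: DetectConfig | None = None) -> ForegroundMask:
    """Segment the tissue foreground with a region-based active contour.

    A Chan–Vese-style morphological active contour is evolved from an Otsu
    threshold of the image; holes are filled and the largest connected
    component is kept. A degenerate (empty or flat) result falls back to a
    full-frame mask with a warning.
    """
    config = config or DetectConfig()
    arr = image.pixels
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0:
        warnings.warn("uniform image: using full-frame foreground mask", stacklevel=2)
        return ForegroundMask.full(arr.shape)
    norm = (arr - lo) / (hi - lo)
    init = norm >= threshold_otsu(norm)
    if not init.any() or init.all():
        init = norm >= norm.mean()
    ls = segmentation.morphological_chan_vese(
        norm,
        num_iter=config.chan_vese_iters,
        init_level_set=init,
        smoothing=config.chan_vese_smoothing,
    ).astype(bool)
    # the level set may converge with foreground/background swapped
    if ls.any() and ls.all() is False and norm[ls].mean() < norm[~ls].mean():
        ls = ~ls
    ls = ndimage.binary_fill_holes(ls)
    if not ls.any():
        warnings.warn("active contour found no foreground: using full-frame mask", stacklevel=2)
        return ForegroundMask.full(arr.shape)
    labels, n = ndimage.label(ls)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        ls = labels == (1 + int(np.argmax(sizes)))
    return ForegroundMask(ls)


def preprocess(image: TissueImage, config: DetectConfig | None = None) -> TissueImage:
    """Averaging filter followed by a median filter (default 3×3 each)."""
    config = config or DetectConfig()
    arr = image.pixels
    if max(config.mean_size, config.median_size) > min(arr.shape):
        raise ValueError("filter window larger than image")
    out = ndimage.uniform_filter(arr, size=config.mean_size, mode="nearest")
    out = ndimage.median_filter(out, size=config.median_size, mode="nearest")
    return TissueImage(
        out,
        pixel_pitch_um=image.pixel_pitch_um,
        saturation_value=image.saturation_value,
        bit_depth=image.bit_depth,
    )


def exmax(
    raster: np.ndarray,
    params: ExmaxParams,
    mask: ForegroundMask | np.ndarray | None = None,
    provenance: Provenance = "intensity",
) -> CandidateSet:
    """Extended maxima transform: regional maxima of the h-maxima transform.

    The h-maxima transform is the morphological reconstruction (by dilation)
    of ``raster − h`` under ``raster``; its regional maxima are the peaks
    whose prominence exceeds h. Components are restricted to the foreground
    mask and components smaller than ``min_region_px`` are dropped.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.max() - arr.min() <= 0:
        return CandidateSet.empty(arr.shape)
    rec = morphology.reconstruction(arr - params.h_value, arr, method="dilation")
    peaks = morphology.local_maxima(rec, connectivity=2, allow_borders=True)
    if mask is not None:
        m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
        peaks &= m
    if params.min_region_px > 1:
        peaks = morphology.remove_small_objects(
            peaks, max_size=params.min_region_px - 1, connectivity=2
        )
    labels = measure.label(peaks, connectivity=2).astype(np.int32)
    ids = [int(i) for i in np.unique(labels) if i != 0]
    return CandidateSet(labels, {i: provenance for i in ids}, arr.shape)


def _h_grid(raster: np.ndarray, mask: np.ndarray | None, config: DetectConfig) -> np.ndarray:
    vals = raster[mask] if mask is not None else raster.ravel()
    dyn = float(vals.max() - vals.min())
    if dyn <= 0:
        raise ValueError("flat raster: zero dynamic range")
    # pixel-noise floor: robust SD of the high-pass residual, so that a
    # smooth non-uniform background does not inflate the scan's lower end
    resid = raster - ndimage.median_filter(raster, size=3, mode="nearest")
    rvals = resid[mask] if mask is not None else resid.ravel()
    sigma = 1.4826 * float(np.median(np.abs(rvals)))
    h_min = config.mad_k * sigma if sigma > 0 else dyn / 1000.0
    h_min = min(h_min, dyn / 2.0)
    h_min = max(h_min, dyn * 1e-6)
    return np.geomspace(h_min, dyn, config.h_steps)


def heuristic_h(
    raster: np.ndarray,
    mask: ForegroundMask | np.ndarray | None = None,
    config: DetectConfig | None = None,
) -> HeuristicResult:
    """Adaptively choose the prominence h giving a stable foci count.

    Scans h over a geometric grid from the pixel-noise floor (k · robust SD
    of the raster's high-pass residual, k = ``mad_k``) up to the dynamic
    range, counting extended-maxima components at each h, and selects the
    midpoint of the longest run of consecutive grid points whose counts
    agree to within ``plateau_rtol`` (a relaxed plateau: real images show a
    continuum of peak prominences, so exactly-identical counts rarely span
    more than a step or two). A long stability plateau marks a prominence
    regime where the segmentation is insensitive to the exact h — a
    realistic count. Scans are flagged
    low-confidence when no plateau reaches ``min_plateau_len`` steps, the
    count exceeds ``count_cap``, or the selected h sits in the top part of
    the dynamic range (only the global dome is stable).
    """
    config = config or DetectConfig()
    arr = np.asarray(raster, dtype=np.float64)
    m = None
    if mask is not None:
        m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    grid = _h_grid(arr, m, config)
    params = [ExmaxParams(h, config.min_region_px) for h in grid]
    counts = [len(exmax(arr, p, m)) for p in params]
    scan = list(zip([float(h) for h in grid], counts))

    # stability plateau: the longest run of grid points whose counts agree
    # to within plateau_rtol (counts >= 2, so the always-present global-dome
    # count-1 tail cannot win)
    best: tuple[int, int, int] | None = None  # (length, median count, start)
    rtol = config.plateau_rtol
    for i in range(len(counts)):
        # noise-end counts drift slowly and would fake a plateau; anything
        # above the realistic cap cannot be the foci count
        if not 2 <= counts[i] <= config.count_cap:
            continue
        cmin = cmax = counts[i]
        j = i
        while j + 1 < len(counts) and 2 <= counts[j + 1] <= config.count_cap:
            nmin, nmax = min(cmin, counts[j + 1]), max(cmax, counts[j + 1])
            if nmax > (1.0 + rtol) * nmin:
                break
            cmin, cmax, j = nmin, nmax, j + 1
        med = int(round(float(np.median(counts[i : j + 1]))))
        # equal-length ties go to the higher-count run: it retains more of
        # the image's structure than the late global-dome regime
        cand = (j - i + 1, med, i)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand

    dyn = float(grid[-1])
    if best is None:
        # no structured plateau: fall back to the longest identical-count
        # run (count >= 1) and flag the scan
        runs = []
        i = 0
        while i < len(counts):
            j = i
            while j + 1 < len(counts) and counts[j + 1] == counts[i]:
                j += 1
            if counts[i] >= 1:
                runs.append((j - i + 1, i))
            i = j + 1
        if not runs:
            return HeuristicResult(dyn, 0, scan, low_confidence=True)
        length, start = max(runs, key=lambda r: (r[0], r[1]))
        mid = start + (length - 1) // 2
        return HeuristicResult(float(grid[mid]), counts[mid], scan, low_confidence=True)

    length, count, start = best
    mid = start + (length - 1) // 2
    h_star = float(grid[mid])
    # a plateau sitting high in the dynamic range means only the global
    # dome is stable: nothing stands clear of the noise
    low_conf = (
        length < config.min_plateau_len
        or count > config.count_cap
        or h_star > 0.4 * dyn
    )
    return HeuristicResult(h_star, count, scan, low_confidence=low_conf)


def candidate_h(
    raster: np.ndarray,
    mask: ForegroundMask | np.ndarray | None = None,
    heuristic_count: int = 0,
    n: float = 2.0,
    config: DetectConfig | None = None,
    scan: list[tuple[float, int]] | None = None,
    provenance: Provenance = "intensity",
) -> CandidateSet:
    """Over-counting candidate extraction.

    Returns the extended-maxima set at the smallest h on the grid whose
    component count does not exceed ``n`` times the heuristic count. Lower h
    never removes maxima, so the resulting count is at least the heuristic
    count. A degenerate ``heuristic_count`` of 0 yields the set at the
    largest grid h.
    """
    config = config or DetectConfig()
    if n <= 1:
        raise ValueError("over-counting ratio n must exceed 1")
    arr = np.asarray(raster, dtype=np.float64)
    m = None
    if mask is not None:
        m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    if scan is None:
        grid = _h_grid(arr, m, config)
        scan = [
            (float(h), len(exmax(arr, ExmaxParams(h, config.min_region_px), m))) for h in grid
        ]
    if heuristic_count <= 0:
        h_sel = scan[-1][0]
    else:
        limit = n * heuristic_count
        # prefer the smallest h whose count sits within the over-counting
        # band [heuristic, n*heuristic]; the raw "smallest h with count <=
        # limit" rule can be fooled by dips below the heuristic count where
        # the minimum-region-size filter drops fragmented maxima
        in_band = [h for h, c in scan if heuristic_count <= c <= limit]
        if in_band:
            h_sel = in_band[0]
        else:
            h_sel = scan[-1][0]
            for h, count in scan:  # ascending h
                if count <= limit:
                    h_sel = h
                    break
    return exmax(arr, ExmaxParams(h_sel, config.min_region_px), m, provenance=provenance)


def detect_candidates(
    image: TissueImage,
    mask: ForegroundMask | None = None,
    config: DetectConfig | None = None,
) -> DetectionResult:
    """Run both candidate pipelines on one image.

    The intensity branch applies the adaptive-h over-counting extraction to
    the preprocessed image; the gradient branch applies the same extraction
    to the Focus-flow map of the preprocessed image. The two candidate sets
    are returned unmerged (fusion is a separate step).
    """
    config = config or DetectConfig()
    if mask is None:
        mask = segment_tissue(image, config)
    if mask.shape != image.shape:
        raise ValueError("mask shape differs from image shape")
    pre = preprocess(image, config)

    def _branch(raster: np.ndarray, provenance: Provenance):
        try:
            heur = heuristic_h(raster, mask, config)
        except ValueError:  # flat raster inside the mask
            return CandidateSet.empty(image.shape), None
        cands = candidate_h(
            raster,
            mask,
            heuristic_count=heur.count_star,
            n=config.overcount,
            config=config,
            scan=heur.scan,
            provenance=provenance,
        )
        return cands, heur

    intensity, int_scan = _branch(pre.pixels, "intensity")
    flow = focus_flow_map(
        pre, radius_px=config.flow_radius_px, mask=mask,
        gradient_method=config.gradient_method,
    )
    gradient, grad_scan = _branch(flow.values, "gradient")
    return DetectionResult(
        intensity=intensity,
        gradient=gradient,
        mask=mask,
        flow=flow,
        preprocessed=pre,
        intensity_scan=int_scan,
        gradient_scan=grad_scan,
    )
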