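"""Candidate fusion and the 18-dimensional per-candidate feature vector.

Fusion rule: gradient candidates that share any pixel with an intensity
candidate are removed (they are the same focus seen twice, and merging the
two region shapes would corrupt both), then the two binary candidate images
are combined with a pixel-wise OR.

The feature set spans the three information axes the detector relies on —
intensity, gradient flow and morphology — and is computed per candidate on
the preprocessed image, its Focus-flow map and the foreground mask. The
fixed feature order is given by ``FEATURE_NAMES``; the extractor sits
behind this single function so an alternative feature list can be swapped
in without touching the classifier.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .focus_flow import FlowMap, image_gradient
from .image_model import CandidateSet, FocusRecord, ForegroundMask, TissueImage

FEATURE_NAMES: tuple[str, ...] = (
    "area_px",
    "equivalent_diameter_px",
    "eccentricity",
    "solidity",
    "disk_mean_contrast",
    "mean_intensity",
    "max_intensity",
    "peak_contrast",
    "intensity_sd",
    "saturation_fraction",
    "mean_flow",
    "max_flow",
    "flow_contrast",
    "radial_decay_slope",
    "boundary_gradient_mean",
    "mask_edge_distance_um",
    "provenance_intensity",
    "local_candidate_density",
)

N_FEATURES = len(FEATURE_NAMES)


def fuse_candidates(intensity: CandidateSet, gradient: CandidateSet) -> CandidateSet:
    """Fuse the two candidate sets, intensity regions taking precedence.

    Every gradient region overlapping any intensity region (≥ 1 shared
    pixel) is dropped; all intensity regions survive unchanged; the
    remaining regions are relabeled consecutively (intensity first).
    """
    if intensity.parent_shape != gradient.parent_shape:
        raise ValueError("candidate sets come from different parent images")
    labels = np.zeros(intensity.parent_shape, dtype=np.int32)
    provenance = {}
    next_id = 1
    int_fg = intensity.labels > 0
    for rid in intensity.region_ids:
        labels[intensity.labels == rid] = next_id
        provenance[next_id] = intensity.provenance[rid]
        next_id += 1
    for rid in gradient.region_ids:
        sel = gradient.labels == rid
        if (int_fg & sel).any():
            continue
        labels[sel] = next_id
        provenance[next_id] = gradient.provenance[rid]
        next_id += 1
    return CandidateSet(labels, provenance, intensity.parent_shape)


def deduplicate_candidates(
    candidates: CandidateSet,
    strength: np.ndarray,
    min_separation_px: float = 30.0,
) -> CandidateSet:
    """Keep at most one gradient candidate per locus.

    A blurred focus often fragments into several nearby Focus-flow maxima.
    Gradient regions whose centroid lies within ``min_separation_px`` of an
    intensity region's centroid, or of a stronger (higher peak ``strength``)
    gradient region, are dropped. Intensity regions are never dropped.
    """
    ids = candidates.region_ids
    cents = {r: candidates.centroid(r) for r in ids}
    peak = {r: float(strength[candidates.labels == r].max()) for r in ids}
    kept = [r for r in ids if candidates.provenance[r] == "intensity"]
    gradient_ids = sorted(
        (r for r in ids if candidates.provenance[r] == "gradient"),
        key=lambda r: (-peak[r], r),
    )
    for r in gradient_ids:
        cx, cy = cents[r]
        if all(
            np.hypot(cents[k][0] - cx, cents[k][1] - cy) > min_separation_px for k in kept
        ):
            kept.append(r)
    labels = np.where(np.isin(candidates.labels, kept), candidates.labels, 0).astype(np.int32)
    return CandidateSet(
        labels, {r: candidates.provenance[r] for r in kept}, candidates.parent_shape
    )


def extract_features(
    candidates: CandidateSet,
    image: TissueImage,
    flow: FlowMap,
    mask: ForegroundMask | None = None,
    neighborhood_radius_px: int | None = None,
) -> list[FocusRecord]:
    """Compute the 18-feature vector for every candidate region.

    Geometry features come from the region shape; intensity and flow
    features use a local background taken as the median over a ring well
    outside the scattering blur (radii 1.2R–1.8R from the centroid, pushed
    outward for regions bigger than R) — a ring hugging the region would sit
    inside the blur of a deep focus and erase its contrast. The
    ``disk_mean_contrast`` feature averages the image over a disk of radius
    R/2 at the centroid, integrating a blurred focus's faint signal over
    many pixels. Features are translation invariant, and the contrast
    features are invariant to adding a constant to the image. Regions whose
    background ring leaves the image are computed on the clipped ring and
    flagged ``border_clipped``.
    """
    arr = image.pixels
    if flow.values.shape != arr.shape or candidates.parent_shape != arr.shape:
        raise ValueError("image, flow map and candidates must share one shape")
    if mask is None:
        mask = ForegroundMask.full(arr.shape)
    radius = int(neighborhood_radius_px or flow.radius_px)
    grad_mag = image_gradient(arr).magnitude
    # distance to the outside of the tissue mask, in px
    edge_dist = ndimage.distance_transform_edt(mask.mask)
    props = {p.label: p for p in measure.regionprops(candidates.labels)}
    ids = candidates.region_ids
    centroids = {rid: candidates.centroid(rid) for rid in ids}
    cent_arr = np.array([centroids[rid] for rid in ids]) if ids else np.empty((0, 2))

    records: list[FocusRecord] = []
    h, w = arr.shape
    for rid in ids:
        p = props[rid]
        cx, cy = centroids[rid]
        region_mask_full = candidates.labels == rid
        region_vals = arr[region_mask_full]
        area = float(p.area)
        eq_diam = float(p.equivalent_diameter_area)
        r_eq = eq_diam / 2.0
        eccentricity = float(p.eccentricity) if p.area > 1 else 0.0
        solidity = float(p.solidity)

        ring_in = max(1.2 * radius, r_eq + 0.5 * radius)
        ring_out = ring_in + 0.6 * radius
        pad = int(np.ceil(ring_out)) + 1
        iy, ix = int(round(cy)), int(round(cx))
        r0, r1 = max(iy - pad, 0), min(iy + pad + 1, h)
        c0, c1 = max(ix - pad, 0), min(ix + pad + 1, w)
        border_clipped = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        win_img = arr[r0:r1, c0:c1]
        win_flow = flow.values[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        rr = np.hypot(xx - cx, yy - cy)
        ring = (rr >= ring_in) & (rr < ring_out)
        if not ring.any():
            ring = rr >= ring_in  # clipped corner: use whatever remains
        bg = float(np.median(win_img[ring])) if ring.any() else float(np.median(win_img))
        flow_bg = float(np.median(win_flow[ring])) if ring.any() else 0.0

        disk = rr <= 0.5 * radius
        disk_contrast = float(win_img[disk].mean()) - bg if disk.any() else 0.0
        mean_int = float(region_vals.mean())
        max_int = float(region_vals.max())
        peak_contrast = max_int - bg
        sd_int = float(region_vals.std())
        sat_frac = float(np.mean(region_vals >= image.saturation_value))

        flow_vals = flow.values[region_mask_full]
        mean_flow = float(flow_vals.mean())
        max_flow = float(flow_vals.max())
        flow_contrast = max_flow - flow_bg

        sel = rr <= 1.5 * radius
        decay = 0.0
        if sel.sum() >= 3:
            above = np.maximum(win_img[sel] - bg, 1e-6)
            decay = float(np.polyfit(rr[sel], np.log(above), 1)[0])

        win_region = candidates.labels[r0:r1, c0:c1] == rid
        boundary = win_region & ~ndimage.binary_erosion(win_region)
        bnd_grad = float(grad_mag[r0:r1, c0:c1][boundary].mean()) if boundary.any() else 0.0

        jy, jx = int(round(np.clip(cy, 0, h - 1))), int(round(np.clip(cx, 0, w - 1)))
        edge_um = float(edge_dist[jy, jx]) * image.pixel_pitch_um

        prov = candidates.provenance[rid]
        prov_flag = 1.0 if prov == "intensity" else 0.0
        if len(cent_arr) > 1:
            d = np.hypot(cent_arr[:, 0] - cx, cent_arr[:, 1] - cy)
            density = float(np.sum(d <= 3.0 * radius) - 1)
        else:
            density = 0.0

        features = np.array(
            [
                area,
                eq_diam,
                eccentricity,
                solidity,
                disk_contrast,
                mean_int,
                max_int,
                peak_contrast,
                sd_int,
                sat_frac,
                mean_flow,
                max_flow,
                flow_contrast,
                decay,
                bnd_grad,
                edge_um,
                prov_flag,
                density,
            ]
        )
        records.append(
            FocusRecord(
                centroid=(cx, cy),
                region_id=rid,
                features=features,
                provenance=prov,
                area_px=int(area),
                border_clipped=border_clipped,
            )
        )
    return records


def feature_matrix(records: list[FocusRecord]) -> np.ndarray:
    """Stack record features into an (n, 18) matrix."""
    if not records:
        return np.empty((0, N_FEATURES))
    return np.vstack([r.features for r in records])
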