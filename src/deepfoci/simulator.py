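"""Synthetic wide-field images of fluorescent foci in thick scattering tissue.

The generator reproduces the in-silico validation conditions: fluorescent
cell clusters placed uniformly at random in a tissue slab (default 200
clusters in 10 × 10 × 0.5 mm³), each cluster with a random cell count and
per-cell fluorophore concentration; a smooth non-uniform autofluorescence
background; depth-dependent scattering rendered by convolving each depth
plane with a Monte Carlo scattering point spread function (sPSF); a
wide-field microscope PSF; and a camera model with shot noise, read noise
and sensor saturation.

Photon transport uses exponential free paths with rate µs + µa,
Henyey–Greenstein scattering with anisotropy g, and absorption handled as
survival-weight attenuation; photons are binned where their path first
crosses the tissue surface. Optical defaults (µs = 10 mm⁻¹, g = 0.9,
µa = 0.1 mm⁻¹) are generic soft-tissue values; NA = 0.04 and λ = 520 nm
match a 1× objective imaging EGFP emission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .image_model import DEFAULT_PIXEL_PITCH_UM, TissueImage


@dataclass
class Phantom:
    """3-D fluorophore distribution: cell clusters in a tissue slab."""

    volume_mm: tuple[float, float, float]
    centroids_um: np.ndarray  # (n, 3) in µm, z measured down from the surface
    n_cells: np.ndarray  # (n,) int
    intensities: np.ndarray  # (n,) total fluorophore per cluster (relative units)
    radii_um: np.ndarray  # (n,) effective cluster radius
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.centroids_um)
        if not (len(self.n_cells) == len(self.intensities) == len(self.radii_um) == n):
            raise ValueError("phantom arrays must have one entry per focus")
        if n:
            lim = np.array(self.volume_mm) * 1000.0
            if (self.centroids_um < 0).any() or (self.centroids_um > lim).any():
                raise ValueError("focus centroid outside the tissue volume")

    def __len__(self) -> int:
        return len(self.centroids_um)


@dataclass
class ScatteringPSFStack:
    """Per-depth Monte Carlo sPSF kernels on a common pixel grid."""

    kernels: list[np.ndarray]
    depths_um: np.ndarray
    mu_s_per_mm: float
    g: float
    mu_a_per_mm: float
    pixel_pitch_um: float
    n_photons: int
    seed: int | None = None

    def kernel_for_depth(self, depth_um: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.depths_um - depth_um)))
        return self.kernels[idx]


@dataclass
class GroundTruth:
    """Per-focus surface-projected centroid, depth and emitted intensity."""

    x_px: np.ndarray
    y_px: np.ndarray
    depth_um: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.x_px)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])


@dataclass
class CameraConfig:
    """Sensor model: gain, noise and clipping."""

    bit_depth: int = 16
    gain: float | None = None  # None → auto-gain from target_peak_frac
    target_peak_frac: float = 2.0  # brightest noiseless pixel at this × saturation
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    quantize: bool = True

    @property
    def saturation_value(self) -> float:
        return float(2**self.bit_depth - 1)


def generate_phantom(
    seed: int | None,
    n_foci: int = 200,
    volume_mm: tuple[float, float, float] = (10.0, 10.0, 0.5),
    cell_radius_um: float = 7.0,
    max_cells: int = 50,
) -> Phantom:
    """Place ``n_foci`` cell clusters uniformly at random in the slab.

    Each cluster holds a discrete-uniform number of cells in [1, max_cells];
    each cell carries a fluorophore concentration uniform in [0.5, 1.5]
    relative units. The effective cluster radius scales as
    ``cell_radius_um · n_cells^(1/3)`` (cells packed into a ball).
    """
    if n_foci < 0:
        raise ValueError("n_foci must be non-negative")
    rng = np.random.default_rng(seed)
    lim = np.array(volume_mm, dtype=float) * 1000.0
    centroids = rng.uniform(0.0, lim, size=(n_foci, 3))
    n_cells = rng.integers(1, max_cells + 1, size=n_foci)
    intensities = np.array(
        [rng.uniform(0.5, 1.5, size=k).sum() for k in n_cells], dtype=np.float64
    )
    radii = cell_radius_um * np.cbrt(n_cells.astype(np.float64))
    return Phantom(tuple(volume_mm), centroids, n_cells, intensities, radii, seed=seed)


def generate_background(
    seed: int | None,
    shape: tuple[int, int],
    mean: float = 500.0,
    contrast: float = 0.3,
    corr_length_um: float = 1000.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> np.ndarray:
    """Smooth positive autofluorescence field.

    A Gaussian random field built by smoothing white noise with a Gaussian
    kernel of σ = ℓ/2 px, which gives a normalized autocovariance
    exp(−r²/ℓ²) — i.e. 1/e at lag ℓ = ``corr_length_um``. The field is
    scaled to the requested mean with relative fluctuation ``contrast``
    (one SD), floored at 10% of the mean to stay positive.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma_px = 0.5 * corr_length_um / pixel_pitch_um
    if contrast == 0:
        return np.full(shape, float(mean))
    smooth = gaussian_filter(white, sigma=sigma_px, mode="reflect")
    sd = smooth.std()
    field = (smooth - smooth.mean()) / (sd if sd > 0 else 1.0)
    out = mean * (1.0 + contrast * field)
    return np.maximum(out, 0.1 * mean)


def widefield_psf(
    na: float = 0.04,
    wavelength_nm: float = 520.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> np.ndarray:
    """In-focus wide-field PSF: normalized Gaussian with σ = 0.21 λ / NA."""
    if not 0 < na < 1.5:
        raise ValueError("numerical aperture must be in (0, 1.5)")
    sigma_px = 0.21 * (wavelength_nm / 1000.0) / na / pixel_pitch_um
    half = max(1, int(np.ceil(4.0 * sigma_px)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    kern = np.exp(-(x**2 + y**2) / (2.0 * sigma_px**2))
    return kern / kern.sum()


def _henyey_greenstein_cos(rng: np.random.Generator, g: float, n: int) -> np.ndarray:
    xi = rng.random(n)
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


def _scatter(rng: np.random.Generator, u: np.ndarray, g: float) -> np.ndarray:
    """Rotate unit direction vectors by an HG polar angle, uniform azimuth."""
    n = len(u)
    cost = _henyey_greenstein_cos(rng, g, n)
    sint = np.sqrt(np.maximum(0.0, 1.0 - cost**2))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    cosp, sinp = np.cos(phi), np.sin(phi)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1e-30, 1.0 - uz**2))
    new = np.empty_like(u)
    new[:, 0] = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
    new[:, 1] = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
    new[:, 2] = -sint * cosp * denom + uz * cost
    # photons travelling along ±z need the degenerate-rotation branch
    sign = np.sign(uz[near_pole])
    new[near_pole, 0] = sint[near_pole] * cosp[near_pole]
    new[near_pole, 1] = sint[near_pole] * sinp[near_pole]
    new[near_pole, 2] = sign * cost[near_pole]
    norm = np.linalg.norm(new, axis=1, keepdims=True)
    return new / norm


def monte_carlo_spsf(
    depth_um: float,
    mu_s_per_mm: float = 10.0,
    g: float = 0.9,
    mu_a_per_mm: float = 0.1,
    n_photons: int = 10_000,
    seed: int | None = None,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    kernel_half_px: int = 64,
    max_events: int = 2000,
    acceptance_deg: float | None = 20.0,
) -> np.ndarray:
    """Monte Carlo scattering PSF of a point emitter at ``depth_um``.

    Photons start isotropically at (0, 0, depth) and random-walk with
    exponential free paths (rate µs + µa per µm), Henyey–Greenstein
    scattering and absorption as multiplicative survival weight. Where a
    path first crosses the surface z = 0 the photon's residual weight is
    binned at the crossing point. The kernel sums to the transmitted weight
    fraction captured inside the window (≤ 1); exits beyond the window and
    photons still in flight after ``max_events`` scatterings are dropped.

    ``acceptance_deg`` models the angular selectivity of the collection
    optics: only photons exiting within this half-angle of the surface
    normal enter the kernel. An isotropic point source under a free surface
    would otherwise produce a heavy-tailed exit fan (radius ~ depth · tan θ)
    that no low-NA objective actually images. The kernel is then normalized
    by the cone's solid-angle fraction, so an unscattered surface emitter
    has kernel sum 1 and deeper kernels sum to the relative transmission.
    Set ``None`` to accept every exit without renormalization (pure
    transport, e.g. for energy-conservation checks).

    A zero depth returns a unit delta kernel (no propagation).
    """
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    if n_photons < 1000:
        raise ValueError("n_photons must be at least 1000")
    if n_photons < 10_000:
        warnings.warn("fewer than 1e4 photons: sPSF kernel will be noisy", stacklevel=2)
    size = 2 * kernel_half_px + 1
    kernel = np.zeros((size, size), dtype=np.float64)
    if depth_um == 0:
        kernel[kernel_half_px, kernel_half_px] = 1.0
        return kernel

    rng = np.random.default_rng(seed)
    mu_s = mu_s_per_mm / 1000.0  # per µm
    mu_a = mu_a_per_mm / 1000.0
    mu_t = mu_s + mu_a
    albedo = mu_s / mu_t if mu_t > 0 else 1.0

    pos = np.zeros((n_photons, 3))
    pos[:, 2] = depth_um
    cost = rng.uniform(-1.0, 1.0, n_photons)
    sint = np.sqrt(1.0 - cost**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_photons)
    dirs = np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])
    w = np.ones(n_photons)

    half_um = (kernel_half_px + 0.5) * pixel_pitch_um
    edges = np.linspace(-half_um, half_um, size + 1)
    cos_acc = -1.0 if acceptance_deg is None else float(np.cos(np.radians(acceptance_deg)))
    for _ in range(max_events):
        if len(w) == 0:
            break
        step = rng.exponential(1.0 / mu_t, size=len(w))
        new_z = pos[:, 2] + dirs[:, 2] * step
        exiting = new_z <= 0.0
        if exiting.any():
            t = pos[exiting, 2] / -dirs[exiting, 2]
            ex = pos[exiting, 0] + dirs[exiting, 0] * t
            ey = pos[exiting, 1] + dirs[exiting, 1] * t
            # exit direction within the collection cone: -uz >= cos(theta_acc)
            acc = -dirs[exiting, 2] >= cos_acc
            hist, _, _ = np.histogram2d(
                ey[acc], ex[acc], bins=[edges, edges], weights=w[exiting][acc]
            )
            kernel += hist
        keep = ~exiting
        pos = pos[keep] + dirs[keep] * step[keep, None]
        dirs, w = dirs[keep], w[keep] * albedo
        # Russian roulette on low-weight photons keeps the walk unbiased
        low = w < 1e-4
        if low.any():
            survive = rng.random(low.sum()) < 0.1
            kill = low.copy()
            kill[np.nonzero(low)[0][survive]] = False
            w = np.where(low, w * 10.0, w)[~kill]
            pos, dirs = pos[~kill], dirs[~kill]
        if len(w):
            dirs = _scatter(rng, dirs, g)
    norm = float(n_photons)
    if acceptance_deg is not None:
        norm *= (1.0 - cos_acc) / 2.0  # cone fraction of isotropic emission
    return kernel / norm


def default_depth_grid(z_mm: float = 0.5, plane_um: float = 25.0) -> np.ndarray:
    """Depth-plane centers: ``plane_um`` slabs spanning [0, z_mm·1000] µm."""
    n = max(1, int(round(z_mm * 1000.0 / plane_um)))
    return (np.arange(n) + 0.5) * plane_um


def build_spsf_stack(
    depths_um: np.ndarray,
    mu_s_per_mm: float = 10.0,
    g: float = 0.9,
    mu_a_per_mm: float = 0.1,
    n_photons: int = 10_000,
    seed: int | None = None,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    kernel_half_px: int = 64,
    acceptance_deg: float | None = 20.0,
) -> ScatteringPSFStack:
    """Simulate one sPSF kernel per depth plane (seeded independently per depth)."""
    depths_um = np.asarray(depths_um, dtype=np.float64)
    kernels = []
    for i, d in enumerate(depths_um):
        sub = None if seed is None else (int(seed) * 1009 + i) % (2**31 - 1)
        kernels.append(
            monte_carlo_spsf(
                float(d),
                mu_s_per_mm=mu_s_per_mm,
                g=g,
                mu_a_per_mm=mu_a_per_mm,
                n_photons=n_photons,
                seed=sub,
                pixel_pitch_um=pixel_pitch_um,
                kernel_half_px=kernel_half_px,
                acceptance_deg=acceptance_deg,
            )
        )
    return ScatteringPSFStack(
        kernels, depths_um, mu_s_per_mm, g, mu_a_per_mm, pixel_pitch_um, n_photons, seed
    )


def _rasterize_plane(
    shape: tuple[int, int],
    xs_px: np.ndarray,
    ys_px: np.ndarray,
    sigmas_px: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of normalized Gaussian spots (total mass = amplitude each)."""
    out = np.zeros(shape)
    h, w = shape
    for x, y, s, a in zip(xs_px, ys_px, sigmas_px, amplitudes):
        s = max(s, 0.3)
        half = int(np.ceil(4 * s))
        r0, r1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        c0, c1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
        spot = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s * s))
        tot = spot.sum()
        if tot > 0:
            out[r0c:r1c, c0c:c1c] += a * spot / tot
    return out


def render_image(
    phantom: Phantom,
    background: np.ndarray,
    psf: np.ndarray,
    spsf_stack: ScatteringPSFStack | None,
    camera: CameraConfig | None = None,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    noise_seed: int | None = None,
    focus_brightness: float = 1.0,
) -> tuple[TissueImage, GroundTruth]:
    """Render a camera image of the phantom through scattering tissue.

    Each cluster is assigned to its nearest depth plane and rasterized as a
    Gaussian spot (σ = radius/2) whose integral is the cluster intensity.
    Each plane is convolved with the sPSF of its depth, planes are summed,
    the autofluorescence background is added, the result is convolved with
    the wide-field PSF, then camera gain, Poisson shot noise, Gaussian read
    noise and saturation clipping are applied. ``spsf_stack=None`` renders
    the scattering-free case (sPSF ≡ delta at every depth).

    ``focus_brightness`` converts relative fluorophore units into the
    background's intensity units (cellular EGFP emission per fluorophore
    unit versus diffuse autofluorescence per pixel).
    """
    camera = camera or CameraConfig()
    background = np.asarray(background, dtype=np.float64)
    if background.ndim != 2:
        raise ValueError("background must be a 2-D raster")
    if spsf_stack is not None and not np.isclose(
        spsf_stack.pixel_pitch_um, pixel_pitch_um, rtol=1e-6
    ):
        raise ValueError("sPSF stack pixel pitch differs from the rendering pixel pitch")
    shape = background.shape
    n = len(phantom)
    xs = phantom.centroids_um[:, 0] / pixel_pitch_um if n else np.empty(0)
    ys = phantom.centroids_um[:, 1] / pixel_pitch_um if n else np.empty(0)
    zs = phantom.centroids_um[:, 2] if n else np.empty(0)
    sigmas = phantom.radii_um / (2.0 * pixel_pitch_um) if n else np.empty(0)
    if n:  # clusters projecting outside the raster are out of the field of view
        inside = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
        xs, ys, zs, sigmas = xs[inside], ys[inside], zs[inside], sigmas[inside]
        intensities = phantom.intensities[inside] * focus_brightness
        n = int(inside.sum())
    else:
        intensities = phantom.intensities * focus_brightness

    if spsf_stack is None:
        depths = np.array([0.0])
        plane_of = np.zeros(n, dtype=int)
        kernels = [None]
    else:
        depths = spsf_stack.depths_um
        plane_of = np.argmin(np.abs(zs[:, None] - depths[None, :]), axis=1) if n else np.empty(0, int)
        kernels = spsf_stack.kernels

    surface = np.zeros(shape)
    for k in range(len(depths)):
        sel = plane_of == k
        if not sel.any():
            continue
        plane = _rasterize_plane(shape, xs[sel], ys[sel], sigmas[sel], intensities[sel])
        kern = kernels[k]
        surface += plane if kern is None else fftconvolve(plane, kern, mode="same")

    noiseless = fftconvolve(surface + background, psf, mode="same")
    noiseless = np.maximum(noiseless, 0.0)

    sat = camera.saturation_value
    if camera.gain is None:
        peak = float(noiseless.max())
        gain = camera.target_peak_frac * sat / peak if peak > 0 else 1.0
    else:
        gain = camera.gain
    signal = noiseless * gain

    rng = np.random.default_rng(noise_seed)
    if camera.shot_noise:
        signal = rng.poisson(signal).astype(np.float64)
    if camera.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, camera.read_noise_sd, size=shape)
    signal = np.clip(signal, 0.0, sat)
    if camera.quantize:
        signal = np.round(signal)

    truth = GroundTruth(
        x_px=xs.copy(), y_px=ys.copy(), depth_um=zs.copy(), intensity=intensities.copy()
    )
    image = TissueImage(
        signal, pixel_pitch_um=pixel_pitch_um, saturation_value=sat, bit_depth=camera.bit_depth
    )
    return image, truth
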