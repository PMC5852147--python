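"""Wiener-deconvolution resolution analysis for planar current-density
imaging.

A thin slab of tissue (standoff ``z0``, active depth ``d``) carrying a
y-directed current density acts, seen from the sensor plane, as a spatial
low-pass filter: in the spatial-frequency domain the measured B_X is the
2D transform of the current density multiplied by an analytic, radially
symmetric transfer function ``f(k)``.  Reconstruction of the current
density is therefore a 2D deconvolution problem; with additive white pixel
noise the optimal linear inverse is the Wiener filter.  The reconstruction
of an ideal point source is the system's point spread function (PSF); its
full width at half maximum (FWHM) defines the achievable resolution and
the ratio of its peak to the propagated noise standard deviation is the
peak signal-to-noise ratio (pSNR).

Spatial frequencies are angular (rad/um) and the usable band for pixel
size ``Delta`` is ``[-pi/Delta, pi/Delta]^2``.  The area-normalized noise
level ``eta`` (nT.um) fixes the per-pixel noise standard deviation as
``eta/Delta`` independently of the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import exp1

from .forward import MU0, MU0_OVER_4PI, VolumeCorrection

__all__ = [
    "SlabSource",
    "TransferFunction",
    "NoiseSpec",
    "ReconstructionResult",
    "transfer_function",
    "wiener_filter",
    "psf",
    "calibrate_source_strength",
    "psnr",
    "reconstruct_map",
    "resolution_scan",
    "noise_level_at_psnr",
]


@dataclass(frozen=True)
class SlabSource:
    """A y-directed current slab: dead-layer standoff ``z0``, active depth
    ``d`` (both um) and point-source amplitude ``sigma_j`` (nA).

    ``sigma_j`` is the flat-spectrum amplitude of the areal current density
    ``j_y(x, y) = sigma_j delta(x) delta(y)`` carried by every depth slice
    of the active layer.
    """

    z0: float
    d: float
    sigma_j: float = 1.0
    correction: VolumeCorrection = field(default_factory=VolumeCorrection)

    def __post_init__(self) -> None:
        if self.z0 < 0 or self.d <= 0:
            raise ValueError("z0 must be >= 0 and d > 0")
        if self.sigma_j <= 0:
            raise ValueError("sigma_j must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Area-normalized white sensor noise.

    ``eta`` is in nT.um at the chosen sampling rate and NV-layer height;
    the pixel noise standard deviation is ``eta / Delta`` and the noise
    power spectral density over the field of view is
    ``s_eta = eta^2 * A_FoV`` (nT^2.um^2 x um^2).
    """

    eta: float
    area_fov: float = 1.0e6  # um^2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0 or self.area_fov <= 0:
            raise ValueError("eta must be >= 0 and area_fov > 0")

    @property
    def s_eta(self) -> float:
        return self.eta**2 * self.area_fov

    def pixel_std(self, delta: float) -> float:
        return self.eta / delta


def transfer_function(k, source: SlabSource) -> np.ndarray:
    """Analytic slab transfer function ``f(k)`` in nT.um^2/nA.

    ``f(k) = a1 mu0 exp(-(z0+d/2) k) sinh(d k / 2)/k
           + (a2 mu0 / 2) [E1((z0+c) k) - E1((z0+c+d) k)]``

    with the analytic ``k -> 0`` limit
    ``a1 mu0 d/2 + (a2 mu0/2) ln((z0+c+d)/(z0+c))``.  The function is
    radially symmetric, positive and strictly decreasing: the tissue-sensor
    geometry acts as a spatial low-pass filter whose cutoff shrinks with
    standoff and slab depth.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("spatial frequency k must be >= 0")
    a1, a2, c = source.correction.a1, source.correction.a2, source.correction.c
    z0, d = source.z0, source.d
    out = np.empty(np.shape(k), dtype=float)
    scalar = out.ndim == 0
    out = np.atleast_1d(out)
    kk = np.atleast_1d(k)
    nz = kk > 0
    kn = kk[nz]
    # exp(-(z0+d/2)k) sinh(dk/2)/k written as a difference of decaying
    # exponentials for numerical stability at large k
    out[nz] = a1 * MU0 * (np.exp(-z0 * kn) - np.exp(-(z0 + d) * kn)) / (2.0 * kn)
    f0 = a1 * MU0 * d / 2.0
    if a2 != 0.0:
        if z0 + c <= 0:
            raise ValueError("z0 + c must be > 0 for the E1 correction terms")
        out[nz] += a2 * MU0 / 2.0 * (exp1((z0 + c) * kn) - exp1((z0 + c + d) * kn))
        f0 += a2 * MU0 / 2.0 * math.log((z0 + c + d) / (z0 + c))
    out[~nz] = f0
    return out[0] if scalar else out.reshape(np.shape(k))


@dataclass
class TransferFunction:
    """Callable wrapper around :func:`transfer_function` for one source."""

    source: SlabSource

    def __call__(self, kx, ky=None) -> np.ndarray:
        k = np.abs(kx) if ky is None else np.hypot(kx, ky)
        return transfer_function(k, self.source)

    def cutoff_k(self) -> float:
        """k at which f drops to half its DC value (bisection)."""
        f0 = float(transfer_function(0.0, self.source))
        lo, hi = 1e-9, 1.0
        while float(transfer_function(hi, self.source)) > f0 / 2.0:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if float(transfer_function(mid, self.source)) > f0 / 2.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def wiener_filter(f_values: np.ndarray, noise: NoiseSpec, sigma_j: float) -> np.ndarray:
    """Wiener inverse filter ``f / (f^2 + eta^2 A_FoV / sigma_j^2)``.

    ``f`` is real, so the conjugate is ``f`` itself.  The regularization
    ratio depends only on ``(eta, A_FoV, sigma_j)``, never on the pixel
    size: evaluating the filter at identical spatial frequencies on
    different grids gives identical values.
    """
    if sigma_j <= 0:
        raise ValueError("sigma_j must be > 0")
    f = np.asarray(f_values, dtype=float)
    return f / (f**2 + noise.s_eta / sigma_j**2)


@dataclass
class ReconstructionResult:
    """Reconstructed current-density map with PSF metrics."""

    j_map: np.ndarray  # (M, M), nA/um^2; PSF when the input is a point source
    pixel_size: float  # um
    fwhm: float | None = None  # um
    psnr: float | None = None
    sigma_j: float | None = None

    @property
    def psf(self) -> np.ndarray:
        return self.j_map


def _grid_mn(delta: float, area_fov: float) -> int:
    side = math.sqrt(area_fov)
    m = side / delta
    if abs(m - round(m)) > 1e-9:
        raise ValueError(f"pixel size {delta} um does not divide the FoV side {side} um")
    return int(round(m))


def _k_grid(m: int, delta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k1 = 2.0 * np.pi * np.fft.fftfreq(m, d=delta)
    kx, ky = np.meshgrid(k1, k1, indexing="ij")
    return kx, ky, np.hypot(kx, ky)


def _pixel_sinc(kx: np.ndarray, ky: np.ndarray, delta: float) -> np.ndarray:
    return np.sinc(kx * delta / (2.0 * np.pi)) * np.sinc(ky * delta / (2.0 * np.pi))


def _fwhm_from_profile(profile: np.ndarray, delta: float) -> float:
    """FWHM by linear interpolation on an axis cut through the peak."""
    ipk = int(np.argmax(profile))
    half = profile[ipk] / 2.0

    def cross(direction: int) -> float:
        j = ipk
        while 0 < j < profile.size - 1 and profile[j + direction] > half:
            j += direction
        a, b = profile[j], profile[j + direction]
        frac = (a - half) / (a - b) if a != b else 0.0
        return abs(j - ipk) + frac

    return (cross(+1) + cross(-1)) * delta


def continuous_peak_field(source: SlabSource) -> float:
    """Noiseless on-axis B_X peak (nT) of the point slab source.

    For the identity correction the radial Hankel integral has the closed
    form ``mu0/(4 pi) sigma_j (1/z0 - 1/(z0+d))``; otherwise the integral
    ``(1/2 pi) int f(k) k dk`` is evaluated numerically.
    """
    if source.correction.is_identity:
        if source.z0 <= 0:
            raise ValueError("z0 must be > 0 for a finite point-source peak")
        return MU0_OVER_4PI * source.sigma_j * (1.0 / source.z0 - 1.0 / (source.z0 + source.d))
    # generic: radial quadrature of the inverse 2D Fourier transform at r=0
    kmax = 60.0 / max(source.z0, 1e-6)
    k = np.linspace(0.0, kmax, 200001)
    fk = transfer_function(k, replace(source, sigma_j=1.0))
    val = np.trapezoid(fk * k, k) / (2.0 * np.pi)
    return float(val * source.sigma_j)


def calibrate_source_strength(
    source: SlabSource,
    target_peak_B: float,
    delta: float | None = None,
    area_fov: float = 1.0e6,
    mode: str = "point",
) -> float:
    """Source amplitude ``sigma_j`` giving the requested noiseless B_X peak.

    ``mode='point'`` (default) calibrates the continuous field peak at the
    sensor surface; the pixel-recorded peak of a rendered map then falls
    slightly below the target because of spatial averaging over the pixel
    area.  ``mode='pixel_mean'`` calibrates the pixel-averaged rendered
    peak instead (requires ``delta``).
    """
    if target_peak_B <= 0:
        raise ValueError("target_peak_B must be > 0")
    unit = replace(source, sigma_j=1.0)
    if mode == "point":
        peak = continuous_peak_field(unit)
    elif mode == "pixel_mean":
        if delta is None:
            raise ValueError("pixel_mean calibration requires delta")
        m = _grid_mn(delta, area_fov)
        kx, ky, k = _k_grid(m, delta)
        fk = transfer_function(k, unit)
        bmap = np.fft.ifft2(fk * _pixel_sinc(kx, ky, delta)).real / delta**2
        peak = float(bmap.max())
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    if peak <= 0:
        raise ValueError("unit-source peak field is not positive")
    return target_peak_B / peak


def render_point_source_map(
    source: SlabSource, delta: float, area_fov: float = 1.0e6, pixel_averaged: bool = True
) -> np.ndarray:
    """Noiseless B_X map (nT) of the point slab source, centred on the grid."""
    m = _grid_mn(delta, area_fov)
    kx, ky, k = _k_grid(m, delta)
    fk = transfer_function(k, source) * source.sigma_j
    if pixel_averaged:
        fk = fk * _pixel_sinc(kx, ky, delta)
    return np.fft.fftshift(np.fft.ifft2(fk).real) / delta**2


def _band_limited_oversample(spectrum: np.ndarray, oversample: int) -> np.ndarray:
    """Evaluate the band-limited inverse transform on a finer grid by
    zero-padding the spectrum (exact sinc interpolation within the band)."""
    m = spectrum.shape[0]
    n = m * oversample
    padded = np.zeros((n, n), dtype=spectrum.dtype)
    lo = (n - m) // 2
    padded[lo : lo + m, lo : lo + m] = np.fft.fftshift(spectrum)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(padded)).real) * oversample**2


def psf(
    source: SlabSource,
    noise: NoiseSpec,
    delta: float,
    profile: str = "axis",
    oversample: int = 4,
) -> ReconstructionResult:
    """Point spread function of the Wiener-reconstructed point source.

    ``PSF = sigma_j IFT{ f^2 / (f^2 + eta^2 A_FoV / sigma_j^2) }`` band
    limited to ``[-pi/Delta, pi/Delta]^2``.  The FWHM is measured on an
    axis cut (``profile='axis'``) or azimuthal average (``'radial'``)
    through the peak, linearly interpolated on a sinc-oversampled grid so
    sub-pixel widths are resolved.
    """
    m = _grid_mn(delta, noise.area_fov)
    _, _, k = _k_grid(m, delta)
    fk = transfer_function(k, source)
    ratio = noise.s_eta / source.sigma_j**2
    W = fk**2 / (fk**2 + ratio) if noise.eta > 0 else np.ones_like(fk)
    psf_map = np.fft.fftshift(np.fft.ifft2(W).real) * source.sigma_j / delta**2
    fine = _band_limited_oversample(W, oversample) * source.sigma_j / delta**2
    pitch = delta / oversample
    n = fine.shape[0]
    if profile == "axis":
        fwhm = _fwhm_from_profile(fine[n // 2, :], pitch)
    elif profile == "radial":
        fwhm = _azimuthal_fwhm(fine, pitch)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return ReconstructionResult(
        j_map=psf_map, pixel_size=delta, fwhm=fwhm, sigma_j=source.sigma_j
    )


def _azimuthal_fwhm(psf_map: np.ndarray, pitch: float) -> float:
    """FWHM of the azimuthally averaged radial profile through the centre."""
    m = psf_map.shape[0]
    c = m // 2
    y, x = np.indices(psf_map.shape)
    r = np.hypot(x - c, y - c)
    bins = np.round(r).astype(int).ravel()
    nbins = c
    sums = np.bincount(bins, weights=psf_map.ravel())
    counts = np.bincount(bins)
    prof = sums[:nbins] / counts[:nbins]
    half = prof[0] / 2.0
    j = 0
    while j < nbins - 1 and prof[j + 1] > half:
        j += 1
    frac = (prof[j] - half) / (prof[j] - prof[j + 1]) if prof[j] != prof[j + 1] else 0.0
    return 2.0 * (j + frac) * pitch


def reconstruction_noise_std(
    source: SlabSource, noise: NoiseSpec, delta: float
) -> float:
    """Standard deviation of the Wiener-reconstructed noise (nA/um^2).

    White pixel noise of standard deviation ``eta/Delta`` has power
    spectral density ``eta^2`` (per unit k-area, continuous convention);
    propagated through the inverse filter the per-pixel variance is
    ``(1/(2 pi)^2) int_band |f^I|^2 eta^2 dk``.
    """
    m = _grid_mn(delta, noise.area_fov)
    _, _, k = _k_grid(m, delta)
    fI = wiener_filter(transfer_function(k, source), noise, source.sigma_j)
    # dk^2/(2 pi)^2 = 1/A_FoV for the discrete band sum
    var = noise.eta**2 * float(np.sum(fI**2)) / noise.area_fov
    return math.sqrt(var)


def psnr(
    source: SlabSource,
    noise: NoiseSpec,
    delta: float,
    method: str = "analytic",
    n_realizations: int = 200,
    rng_seed: int | None = None,
) -> float:
    """Peak signal-to-noise ratio of the reconstructed point source.

    The peak is the PSF maximum; the noise is the standard deviation of the
    reconstruction of pure sensor noise, either propagated analytically or
    estimated over seeded white-noise realizations.  Returns ``inf`` for a
    noiseless system.
    """
    if noise.eta == 0:
        return float("inf")
    result = psf(source, noise, delta)
    peak = float(result.j_map.max())
    if method == "analytic":
        std = reconstruction_noise_std(source, noise, delta)
    elif method == "monte_carlo":
        m = _grid_mn(delta, noise.area_fov)
        _, _, k = _k_grid(m, delta)
        fI = wiener_filter(transfer_function(k, source), noise, source.sigma_j)
        rng = np.random.default_rng(noise.rng_seed if rng_seed is None else rng_seed)
        acc = 0.0
        for _ in range(n_realizations):
            n = rng.normal(0.0, noise.pixel_std(delta), size=(m, m))
            jn = np.fft.ifft2(np.fft.fft2(n) * fI).real
            acc += float(jn.var())
        std = math.sqrt(acc / n_realizations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return peak / std


def reconstruct_map(
    field_map: np.ndarray,
    source: SlabSource,
    noise: NoiseSpec,
    delta: float,
    add_noise: bool = False,
    rng_seed: int | None = None,
) -> ReconstructionResult:
    """Wiener-deconvolve a measured (or rendered) B_X map.

    Optionally adds white pixel noise of standard deviation ``eta/Delta``
    before deconvolution (seeded).  The map must be square; the FoV implied
    by ``delta`` must match the noise spec.
    """
    bmap = np.asarray(field_map, dtype=float)
    if bmap.ndim != 2 or bmap.shape[0] != bmap.shape[1]:
        raise ValueError("field map must be square")
    m = bmap.shape[0]
    if abs(m * delta - math.sqrt(noise.area_fov)) > 1e-6:
        raise ValueError("map size, pixel size and FoV area are inconsistent")
    if add_noise:
        rng = np.random.default_rng(noise.rng_seed if rng_seed is None else rng_seed)
        bmap = bmap + rng.normal(0.0, noise.pixel_std(delta), size=bmap.shape)
    _, _, k = _k_grid(m, delta)
    fI = wiener_filter(transfer_function(k, source), noise, source.sigma_j)
    j_map = np.fft.ifft2(np.fft.fft2(np.fft.ifftshift(bmap)) * fI).real
    return ReconstructionResult(
        j_map=np.fft.fftshift(j_map), pixel_size=delta, sigma_j=source.sigma_j
    )


def resolution_scan(
    source: SlabSource,
    deltas,
    etas,
    area_fov: float = 1.0e6,
) -> pd.DataFrame:
    """Full factorial (pixel size x noise level) table of FWHM and pSNR."""
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    etas = np.atleast_1d(np.asarray(etas, dtype=float))
    if deltas.size == 0 or etas.size == 0:
        raise ValueError("non-empty pixel-size and noise grids required")
    rows = []
    for delta in deltas:
        for eta in etas:
            noise = NoiseSpec(eta=float(eta), area_fov=area_fov)
            res = psf(source, noise, float(delta))
            rows.append(
                {
                    "delta_um": float(delta),
                    "eta_nT_um": float(eta),
                    "fwhm_um": res.fwhm,
                    "psnr": psnr(source, noise, float(delta)),
                }
            )
    return pd.DataFrame(rows)


def noise_level_at_psnr(
    source: SlabSource,
    delta: float,
    target_psnr: float = 10.0,
    area_fov: float = 1.0e6,
    rel_tol: float = 0.01,
) -> float:
    """Largest area-normalized noise level eta at which the reconstruction
    still reaches ``target_psnr`` (bisection on log eta to ``rel_tol``)."""
    lo, hi = math.log(1e-4), math.log(1e4)
    while math.exp(hi) / math.exp(lo) - 1.0 > rel_tol:
        mid = 0.5 * (lo + hi)
        value = psnr(source, NoiseSpec(eta=math.exp(mid), area_fov=area_fov), delta)
        if value > target_psnr:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))
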