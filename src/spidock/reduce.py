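"""Polar resampling and azimuth-based reductions of scattering patterns.

Two reduced representations drive both SAXS-style scoring and fast
orientation matching:

* the radial profile, the per-ring azimuthal mean (aggregated over patterns
  it is the virtual SAXS curve), and
* the angular auto-correlation AC(q, dphi) = integral I(q,phi) I(q,phi+dphi)
  dphi, whose circular form makes it invariant to in-plane rotation of the
  pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, map_coordinates

from .geometry import QMap
from .simulate import Pattern, PatternSet, SIGMA_FLOOR

__all__ = ["PolarPattern", "RadialProfile", "ACPattern", "to_polar",
           "radial_profile", "auto_correlation", "circular_correlation"]


@dataclass
class PolarPattern:
    """Pattern resampled on (q, phi) rings; NaN marks out-of-mask samples."""

    q_centers: np.ndarray     # (K,)
    phi: np.ndarray           # (B,) radians, bin centers
    intensity: np.ndarray     # (K, B)
    sigma: np.ndarray         # (K, B)

    @property
    def phi_width(self) -> float:
        return float(2.0 * np.pi / self.phi.size)


@dataclass
class RadialProfile:
    """Azimuthally (and optionally pattern-) averaged intensity vs q."""

    q_centers: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    count: np.ndarray = None      # effective samples per bin

    def __post_init__(self) -> None:
        if self.q_centers.size < 2:
            raise ValueError("need at least two q bins")
        if np.any(np.diff(self.q_centers) <= 0):
            raise ValueError("q centers must be strictly increasing")


@dataclass
class ACPattern:
    """Per-ring circular auto-correlation AC(q, dphi)."""

    q_centers: np.ndarray
    ac: np.ndarray            # (K, B)
    sigma: np.ndarray = None  # propagated sigma of AC, same shape
    phi_width: float = 0.0


def _polar_pixel_coords(qmap: QMap, q_centers, phi):
    """Detector (row, col) coordinates of the polar sample points."""
    det = qmap.detector
    if det is None:
        raise ValueError("QMap lacks detector geometry needed for polar mapping")
    q = np.asarray(q_centers, float)[:, None]
    sin_theta = np.clip(q * det.wavelength / (4.0 * np.pi), 0.0, 1.0)
    r_mm = det.distance * np.tan(2.0 * np.arcsin(sin_theta))
    x = r_mm * np.cos(phi)[None, :]
    y = r_mm * np.sin(phi)[None, :]
    col = x / det.pixel_size + det.beam_center[0]
    row = y / det.pixel_size + det.beam_center[1]
    return row, col


#: margin (pixels) kept between polar samples and the resolution-mask edge so
#: the cubic interpolation support never touches masked-out pixels
_EDGE_MARGIN_PX = 3.0


def default_q_centers(qmap: QMap, n_qbins: int, q_min_frac: float = 0.05) -> np.ndarray:
    """Ring radii at bin midpoints spanning the usable q range.

    The innermost fraction is skipped (rings collapsing onto the beam center
    carry a handful of pixels and no azimuthal information) and the outermost
    rings stay a few pixels inside the resolution mask so interpolation never
    samples masked-out pixels.
    """
    det = qmap.detector
    q_max = det.q_max if det else float(qmap.qmag[qmap.mask].max())
    if det is not None:
        # pull the top edge in by the interpolation margin, in q units
        sin_t = q_max * det.wavelength / (4.0 * np.pi)
        r_mm = det.distance * np.tan(2.0 * np.arcsin(sin_t))
        r_mm = max(r_mm - _EDGE_MARGIN_PX * det.pixel_size, det.pixel_size)
        two_theta = np.arctan2(r_mm, det.distance)
        q_max = 4.0 * np.pi * np.sin(two_theta / 2.0) / det.wavelength
    lo = q_min_frac * q_max
    edges = np.linspace(lo, q_max, n_qbins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _eroded_mask(qmap: QMap, order: int) -> np.ndarray:
    """Resolution mask eroded by the spline half-support, cached per QMap."""
    cache = getattr(qmap, "_eroded_cache", None)
    if cache is None:
        cache = {}
        qmap._eroded_cache = cache
    if order not in cache:
        cache[order] = binary_erosion(
            qmap.mask, iterations=max(1, order - 1)).astype(float)
    return cache[order]


def to_polar(p: Pattern, qmap: QMap, n_qbins: int = 32, n_phibins: int = 72,
             q_centers=None, order: int = 3) -> PolarPattern:
    """Resample a Cartesian pattern onto (q, phi) rings by spline interpolation.

    phi = 0 lies along the fast detector axis, counter-clockwise positive.
    Cubic splines (default) keep the azimuthal/radial averages faithful to the
    underlying smooth intensity; samples whose interpolation support can leave
    the resolution mask are flagged NaN (the mask is eroded by the spline
    half-support before the in-mask check).
    """
    if n_qbins < 2 or n_phibins < 2:
        raise ValueError("need at least 2 bins per polar axis")
    if q_centers is None:
        q_centers = default_q_centers(qmap, n_qbins)
    q_centers = np.asarray(q_centers, float)
    phi = (np.arange(n_phibins) + 0.5) * 2.0 * np.pi / n_phibins
    row, col = _polar_pixel_coords(qmap, q_centers, phi)
    coords = np.stack([row.ravel(), col.ravel()])
    inten = map_coordinates(p.intensity, coords, order=order, mode="constant",
                            cval=np.nan).reshape(row.shape)
    sig = map_coordinates(p.sigma, coords, order=1, mode="constant",
                          cval=np.nan).reshape(row.shape)
    mval = map_coordinates(_eroded_mask(qmap, order), coords, order=1,
                           mode="constant", cval=0.0).reshape(row.shape)
    bad = mval < 1.0 - 1e-9
    inten[bad] = np.nan
    sig[bad] = np.nan
    return PolarPattern(q_centers, phi, inten, sig)


def radial_profile(p, qmap: QMap, n_qbins: int = 32, n_phibins: int = 72,
                   q_centers=None) -> RadialProfile:
    """Per-ring azimuthal mean; for a PatternSet additionally the mean over N.

    Implements the discretized angular average (the 1/2pi and dphi of the
    continuous form cancel in the mean).  Sigma is propagated photon
    statistics: sqrt(mean intensity / effective sample count), floored by the
    per-pixel floor.  Rings with no valid samples are NaN.
    """
    patterns = p.patterns if isinstance(p, PatternSet) else [p]
    stack = np.stack([to_polar(pp, qmap, n_qbins, n_phibins, q_centers).intensity
                      for pp in patterns])             # (N, K, B)
    qc = (np.asarray(q_centers, float) if q_centers is not None
          else default_q_centers(qmap, n_qbins))
    valid = np.isfinite(stack)
    count = valid.sum(axis=(0, 2)).astype(float)       # (K,)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(np.nan_to_num(stack), axis=(0, 2))
                        / np.maximum(count, 1), np.nan)
    sigma = np.sqrt(np.maximum(mean, SIGMA_FLOOR**2) / np.maximum(count, 1))
    sigma[count == 0] = np.nan
    return RadialProfile(qc, mean, sigma, count)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c[d] = sum_i a[i] * b[(i+d) mod B] along the last axis, via FFT."""
    fa = np.fft.rfft(a, axis=-1)
    fb = np.fft.rfft(b, axis=-1)
    return np.fft.irfft(np.conj(fa) * fb, n=a.shape[-1], axis=-1)


def auto_correlation(p: Pattern, qmap: QMap, n_qbins: int = 32,
                     n_phibins: int = 72, q_centers=None) -> ACPattern:
    """Angular auto-correlation AC(q, dphi) = sum_phi I(q,phi) I(q,phi+dphi) dphi.

    Computed by fast circular correlation per ring (identical to the direct
    O(B^2) sum).  Rings that are not fully inside the resolution mask are NaN;
    a first-order error propagation of the per-sample sigma is attached for
    chi-style comparisons of AC patterns.
    """
    pol = to_polar(p, qmap, n_qbins, n_phibins, q_centers)
    dphi = pol.phi_width
    K, B = pol.intensity.shape
    ac = np.full((K, B), np.nan)
    sig = np.full((K, B), np.nan)
    full = np.all(np.isfinite(pol.intensity), axis=1)
    if full.any():
        I = pol.intensity[full]
        ac[full] = circular_correlation(I, I) * dphi
        # Var(AC) ~ sum_phi [I(phi+d)^2 s(phi)^2 + I(phi)^2 s(phi+d)^2] dphi^2
        s2 = pol.sigma[full] ** 2
        v = circular_correlation(s2, I**2) + circular_correlation(I**2, s2)
        sig[full] = np.sqrt(np.maximum(v, 0.0)) * dphi
    return ACPattern(pol.q_centers, ac, sig, dphi)
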