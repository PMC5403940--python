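"""Forward simulation of single-particle scattering patterns.

The scattered amplitude of an atomic model is the direct sum of atomic
wavelets, F(q) = sum_j f_j(|q|) exp(i q . r_j), with f_j the International
Tables 4-Gaussian + constant atomic form factor.  A pattern is |F|^2 sampled
on the Ewald sphere of a detector, photon-scaled so that the mean count in a
chosen resolution shell is one (the photon budget of a just-measurable
highest-resolution shell), and optionally degraded with Poisson counting
noise plus a Gaussian background at a prescribed signal-to-noise ratio.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import h5py
import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .geometry import BeamDetector, QMap, d_to_q
from .models import AtomicModel

__all__ = [
    "Pattern", "PatternSet", "form_factor", "structure_factor",
    "simulate_pattern", "simulate_set", "scale_to_photons", "add_noise",
    "sample_orientations", "debye_profile", "save_pattern_set",
    "load_pattern_set", "SIGMA_FLOOR", "euler_to_matrix",
]

#: Smallest allowed per-pixel standard deviation, photons.  The Poisson sigma
#: sqrt(I) vanishes at empty pixels; flooring at one photon (the sigma of the
#: smallest countable signal) keeps every chi-score denominator finite.
SIGMA_FLOOR = 1.0


def euler_to_matrix(orientation_deg) -> np.ndarray:
    """Intrinsic z-y'-z'' Euler triple (degrees) to an active rotation matrix.

    R = Rz(alpha) @ Ry(beta) @ Rz(gamma); applied to model coordinates.  The
    leading lab-frame Rz(alpha) rotates the detector pattern in-plane, so
    azimuth-invariant reductions (radial profile, angular auto-correlation)
    depend only on (beta, gamma).
    """
    return Rotation.from_euler("ZYZ", np.asarray(orientation_deg, float),
                               degrees=True).as_matrix()


@functools.lru_cache(maxsize=None)
def _it92_coeffs(symbol: str):
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"no form-factor parameters for element {symbol!r}")
    it = el.it92
    return np.asarray(it.a, float), np.asarray(it.b, float), float(it.c)


def form_factor(symbol: str, qmag) -> np.ndarray:
    """Atomic form factor f(|q|), 4-Gaussian + constant parameterization.

    Tabulated against s^2 = (sin theta / lambda)^2 = (q / 4 pi)^2.
    """
    a, b, c = _it92_coeffs(symbol)
    s2 = (np.asarray(qmag, float) / (4.0 * np.pi)) ** 2
    return np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + c


def structure_factor(model: AtomicModel, qvecs) -> np.ndarray:
    """Complex scattered amplitude F(q) = sum_j f_j(|q|) exp(i q . r_j)."""
    qvecs = np.asarray(qvecs, float)
    flat = qvecs.reshape(-1, 3)
    if not np.all(np.isfinite(flat)):
        raise ValueError("q vectors must be finite")
    qmag = np.linalg.norm(flat, axis=1)
    F = np.zeros(flat.shape[0], complex)
    elements = np.asarray(model.elements)
    for sym in np.unique(elements):
        sel = elements == sym
        phases = np.exp(1j * (flat @ model.coords[sel].T))  # (npix, n_sel)
        F += form_factor(str(sym), qmag) * phases.sum(axis=1)
    return F.reshape(qvecs.shape[:-1])


@dataclass
class Pattern:
    """One detector snapshot: photon counts, their sigma, and the orientation."""

    intensity: np.ndarray
    sigma: np.ndarray
    orientation: np.ndarray          # (alpha, beta, gamma) degrees
    noise_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        self.sigma = np.asarray(self.sigma, float)
        self.orientation = np.asarray(self.orientation, float).reshape(3)
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and non-negative")


@dataclass
class PatternSet:
    """N same-geometry patterns sharing one QMap."""

    patterns: list
    qmap: QMap
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.patterns) < 1:
            raise ValueError("PatternSet needs at least one pattern")
        shape = self.patterns[0].intensity.shape
        for p in self.patterns:
            if p.intensity.shape != shape:
                raise ValueError("patterns are not shape-identical")

    def __len__(self) -> int:
        return len(self.patterns)

    def intensities(self) -> np.ndarray:
        return np.stack([p.intensity for p in self.patterns])

    def sigmas(self) -> np.ndarray:
        return np.stack([p.sigma for p in self.patterns])

    def orientations(self) -> np.ndarray:
        return np.stack([p.orientation for p in self.patterns])

    @property
    def photon_scale(self) -> float:
        return float(self.meta.get("photon_scale", 1.0))


def simulate_pattern(model: AtomicModel, orientation_deg, qmap: QMap) -> Pattern:
    """Noise-free intensity of `model` rotated by the Euler triple.

    Rotating the model by R is evaluated through the reciprocal-space dual
    F_rot(q) = F(R^T q), which avoids touching the coordinates.  Pixels
    masked out by the resolution cutoff are left at zero.
    """
    R = euler_to_matrix(orientation_deg)
    qv = qmap.qvecs[qmap.mask] @ R          # rows: R^T q
    F = structure_factor(model, qv)
    intensity = np.zeros(qmap.shape, float)
    intensity[qmap.mask] = np.abs(F) ** 2
    sigma = np.maximum(np.sqrt(intensity), SIGMA_FLOOR)
    return Pattern(intensity, sigma, orientation_deg, {"noise": "none"})


def sample_orientations(n: int, bounds=None, seed: int = 0,
                        mode: str = "per_angle") -> np.ndarray:
    """Random Euler triples, degrees.

    mode='per_angle' draws each angle uniformly within its bounds (the
    confined-subspace convention; NOT uniform on SO(3)).  mode='so3' draws
    Haar-uniform rotations and ignores bounds.
    """
    rng = np.random.default_rng(seed)
    if mode == "so3":
        return Rotation.random(n, random_state=rng).as_euler("ZYZ", degrees=True)
    if bounds is None:
        bounds = ((0.0, 360.0), (0.0, 180.0), (0.0, 360.0))
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    return rng.uniform(lows, highs, size=(n, 3))


def simulate_set(model: AtomicModel, orientations, qmap: QMap,
                 label: str = "") -> PatternSet:
    pats = [simulate_pattern(model, ori, qmap) for ori in np.atleast_2d(orientations)]
    return PatternSet(pats, qmap, source_label=label)


def scale_to_photons(ps: PatternSet, d_target: float = 4.0,
                     shell_frac: float = 0.05) -> PatternSet:
    """Rescale so the mean count in the d_target resolution shell is 1 photon.

    One global multiplicative factor (the role of the incident fluence I0) is
    applied to every pattern; the shell is |q - q_t| <= shell_frac * q_t with
    q_t = 2 pi / d_target.  Sigma becomes sqrt(intensity), floored at one
    photon; the factor is recorded in ``meta['photon_scale']``.
    """
    q_t = d_to_q(d_target)
    shell = ps.qmap.mask & (np.abs(ps.qmap.qmag - q_t) <= shell_frac * q_t)
    if not shell.any():
        raise ValueError(f"no masked pixels in the {d_target} A target shell")
    mean = float(np.mean([p.intensity[shell].mean() for p in ps.patterns]))
    if mean <= 0:
        raise ValueError("zero mean intensity in target shell; cannot scale")
    factor = 1.0 / mean
    pats = []
    for p in ps.patterns:
        inten = p.intensity * factor
        sigma = np.maximum(np.sqrt(inten), SIGMA_FLOOR)
        pats.append(Pattern(inten, sigma, p.orientation, dict(p.noise_meta)))
    meta = dict(ps.meta)
    meta["photon_scale"] = ps.photon_scale * factor
    meta["d_target"] = d_target
    meta["shell_frac"] = shell_frac
    return PatternSet(pats, ps.qmap, ps.source_label, meta)


def add_noise(p: Pattern, qmap: QMap, poisson: bool = True,
              snr: float | None = None, seed: int = 0) -> Pattern:
    """Poisson counting noise, then an additive Gaussian background.

    The background variance is Var(noise-free signal over masked pixels)/snr,
    matching an SNR defined as the ratio of signal to noise variances.
    Negative results are clipped at zero.  Sigma is inherited from the
    noise-free photon statistics (set at scaling time), not re-estimated from
    the noisy draw.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    inten = p.intensity.copy()
    mask = qmap.mask
    if poisson:
        inten[mask] = rng.poisson(inten[mask]).astype(float)
    if snr is not None:
        sig_var = float(np.var(p.intensity[mask]))
        noise_sd = np.sqrt(sig_var / snr)
        inten[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
    np.clip(inten, 0.0, None, out=inten)
    meta = dict(p.noise_meta)
    meta.update({"noise": "poisson" if poisson else "background-only",
                 "poisson": poisson, "snr": snr, "seed": seed})
    return Pattern(inten, p.sigma.copy(), p.orientation, meta)


def add_noise_set(ps: PatternSet, poisson: bool = True, snr: float | None = None,
                  seed: int = 0) -> PatternSet:
    """Per-pattern :func:`add_noise` with one sub-seed per pattern."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(ps))
    pats = [add_noise(p, ps.qmap, poisson, snr, int(s))
            for p, s in zip(ps.patterns, seeds)]
    meta = dict(ps.meta)
    meta.update({"noise_seed": seed, "poisson": poisson, "snr": snr})
    return PatternSet(pats, ps.qmap, ps.source_label, meta)


def debye_profile(model: AtomicModel, qmag) -> np.ndarray:
    """Exact rotationally averaged intensity (Debye formula).

    I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij)/(q r_ij); the orientation average
    of |F|^2 over uniform SO(3), used as the analytic SAXS oracle/model side.
    """
    q = np.atleast_1d(np.asarray(qmag, float))
    f = np.stack([form_factor(str(s), q) for s in model.elements])  # (n_atoms, K)
    # self terms
    I = np.sum(f * f, axis=0)
    if model.n_atoms > 1:
        r = pdist(model.coords)                       # (n_pairs,)
        i_idx, j_idx = np.triu_indices(model.n_atoms, k=1)
        x = np.outer(r, q)                            # (n_pairs, K)
        sinc = np.sinc(x / np.pi)
        I = I + 2.0 * np.sum(f[i_idx] * f[j_idx] * sinc, axis=0)
    return I if np.ndim(qmag) else float(I[0])


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_pattern_set(ps: PatternSet, path) -> None:
    """Persist patterns + geometry: /qmap/{qvecs,qmag,mask}, /patterns/{...}."""
    det = ps.qmap.detector
    with h5py.File(path, "w") as f:
        g = f.create_group("qmap")
        g.create_dataset("qvecs", data=ps.qmap.qvecs)
        g.create_dataset("qmag", data=ps.qmap.qmag)
        g.create_dataset("mask", data=ps.qmap.mask)
        g = f.create_group("patterns")
        g.create_dataset("intensity", data=ps.intensities())
        g.create_dataset("sigma", data=ps.sigmas())
        f.create_dataset("orientations", data=ps.orientations())
        meta = f.create_group("meta")
        meta.attrs["source_label"] = ps.source_label
        for k, v in ps.meta.items():
            if v is not None:
                meta.attrs[k] = v
        if det is not None:
            for k in ("wavelength", "distance", "pixel_size", "n_fast",
                      "n_slow", "d_min"):
                meta.attrs[f"det_{k}"] = getattr(det, k)
            meta.attrs["det_beam_center"] = det.beam_center


def load_pattern_set(path) -> PatternSet:
    with h5py.File(path, "r") as f:
        attrs = dict(f["meta"].attrs)
        det = None
        if "det_wavelength" in attrs:
            det = BeamDetector(
                wavelength=float(attrs["det_wavelength"]),
                distance=float(attrs["det_distance"]),
                pixel_size=float(attrs["det_pixel_size"]),
                n_fast=int(attrs["det_n_fast"]),
                n_slow=int(attrs["det_n_slow"]),
                beam_center=tuple(attrs["det_beam_center"]),
                d_min=float(attrs["det_d_min"]),
            )
        qmap = QMap(f["qmap/qvecs"][...], f["qmap/qmag"][...],
                    f["qmap/mask"][...].astype(bool), det)
        inten = f["patterns/intensity"][...]
        sigma = f["patterns/sigma"][...]
        oris = f["orientations"][...]
        label = str(attrs.pop("source_label", ""))
        meta = {k: v for k, v in attrs.items() if not k.startswith("det_")}
    pats = [Pattern(inten[i], sigma[i], oris[i]) for i in range(inten.shape[0])]
    return PatternSet(pats, qmap, label, meta)
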