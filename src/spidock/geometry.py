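"""Beam/detector geometry and the Ewald-sphere momentum-transfer map.

Elastic scattering at wavelength lambda samples Fourier space on the Ewald
sphere: a pixel seen from the sample along unit vector k0_hat records
q = (2*pi/lambda) * (k0_hat - ki_hat), with the incident beam ki_hat along +z.
The magnitude satisfies |q| = 4*pi*sin(theta)/lambda where 2*theta is the
scattering angle.  Resolution follows the crystallographic convention
d = 2*pi/q, so the 4 A shell sits at q = pi/2 A^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeamDetector", "QMap", "build_qmap", "d_to_q", "q_to_d"]


def d_to_q(d: float) -> float:
    """Resolution (A) to momentum transfer magnitude (A^-1), d = 2*pi/q."""
    return 2.0 * np.pi / d


def q_to_d(q):
    return 2.0 * np.pi / np.asarray(q)


@dataclass
class BeamDetector:
    """Flat square-pixel detector normal to the beam.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength, Angstrom.
    distance : float
        Sample-to-detector distance, mm.
    pixel_size : float
        Pixel edge, mm.
    n_fast, n_slow : int
        Pixel counts along the fast (x) and slow (y) axes.
    beam_center : (2,) float
        Beam position in fractional pixel coordinates (fast, slow).  The
        default puts it exactly on the central pixel so one pixel sits at q=0.
    d_min : float
        Requested highest resolution, Angstrom; pixels beyond 2*pi/d_min are
        masked out.  The detector edge must reach at least this resolution.
    """

    wavelength: float = 1.0
    distance: float = 100.0
    pixel_size: float = 0.45
    n_fast: int = 128
    n_slow: int = 128
    beam_center: tuple = None
    d_min: float = 4.0

    def __post_init__(self) -> None:
        if min(self.wavelength, self.distance, self.pixel_size, self.d_min) <= 0:
            raise ValueError("wavelength, distance, pixel_size, d_min must be > 0")
        if self.beam_center is None:
            self.beam_center = (self.n_fast // 2, self.n_slow // 2)
        self.beam_center = (float(self.beam_center[0]), float(self.beam_center[1]))
        if self.edge_resolution() > self.d_min + 1e-12:
            raise ValueError(
                f"detector edge only reaches d = {self.edge_resolution():.3f} A, "
                f"coarser than requested d_min = {self.d_min} A")

    def edge_resolution(self) -> float:
        """Resolution at the nearest detector edge midpoint (inscribed circle)."""
        cx, cy = self.beam_center
        half = min(cx, self.n_fast - 1 - cx, cy, self.n_slow - 1 - cy) * self.pixel_size
        if half <= 0:
            return np.inf
        two_theta = np.arctan2(half, self.distance)
        q_edge = 4.0 * np.pi * np.sin(two_theta / 2.0) / self.wavelength
        return float(2.0 * np.pi / q_edge)

    @property
    def q_max(self) -> float:
        return d_to_q(self.d_min)


@dataclass
class QMap:
    """Per-pixel momentum-transfer vectors on the Ewald sphere."""

    qvecs: np.ndarray   # (n_slow, n_fast, 3), A^-1
    qmag: np.ndarray    # (n_slow, n_fast), A^-1
    mask: np.ndarray    # (n_slow, n_fast) bool, True = usable
    detector: BeamDetector = None

    @property
    def shape(self) -> tuple:
        return self.qmag.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def masked_qvecs(self) -> np.ndarray:
        return self.qvecs[self.mask]


def build_qmap(det: BeamDetector) -> QMap:
    """Map every pixel to its Ewald-sphere q vector and mask beyond d_min.

    Full Ewald curvature is kept: q_z = (2*pi/lambda)(cos 2theta - 1) is not
    approximated away even at small angles.
    """
    jj, ii = np.meshgrid(np.arange(det.n_slow), np.arange(det.n_fast), indexing="ij")
    x = (ii - det.beam_center[0]) * det.pixel_size
    y = (jj - det.beam_center[1]) * det.pixel_size
    z = np.full_like(x, det.distance, dtype=float)
    norm = np.sqrt(x * x + y * y + z * z)
    k0 = np.stack([x / norm, y / norm, z / norm], axis=-1)   # unit scattered dir
    ki = np.array([0.0, 0.0, 1.0])
    qvecs = (2.0 * np.pi / det.wavelength) * (k0 - ki)
    qmag = np.linalg.norm(qvecs, axis=-1)
    mask = qmag <= det.q_max
    return QMap(qvecs, qmag, mask, det)
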