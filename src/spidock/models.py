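"""Atomic models, PDB I/O, rigid-body decoys, RMSD and density rasterization.

This module holds the structural side of the pipeline: the point-cloud
representation of a protein (element symbols + coordinates), the two-subunit
complex used for docking, a seedable rigid-body decoy generator that stands in
for an external docking sampler, the no-superposition RMSD used to measure
decoy quality, and a Gaussian rasterizer that turns a model into an electron
density map for overlap (s-score) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomicModel",
    "ComplexModel",
    "RigidTransform",
    "DecoySet",
    "DensityMap",
    "read_pdb",
    "write_pdb",
    "rmsd_to_native",
    "generate_decoys",
    "rasterize_density",
    "make_toy_complex",
]

# Elements accepted without a warning in the synthetic fixtures; anything that
# gemmi can map to a form-factor table is allowed in general.
_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


def _element_electrons(symbol: str) -> int:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return el.atomic_number


@dataclass
class AtomicModel:
    """Element-typed point set.

    Parameters
    ----------
    elements : array of str
        Per-atom element symbols ('C', 'N', 'O', ...); each must resolve to an
        International-Tables form-factor parameter set.
    coords : (n_atoms, 3) float array
        Cartesian coordinates in Angstrom.
    label : str
        Free-text identifier.
    """

    elements: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValueError("AtomicModel requires at least one atom")
        if self.elements.shape[0] != self.coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for sym in set(self.elements.tolist()):
            _element_electrons(sym)  # raises on unknown symbol

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def electron_counts(self) -> np.ndarray:
        """Per-atom electron number Z (neutral atoms)."""
        return np.array([_element_electrons(s) for s in self.elements], dtype=float)

    def center_of_mass(self, weights: str = "electrons") -> np.ndarray:
        """Weighted centroid; 'electrons' weights by Z, 'uniform' by 1."""
        if weights == "uniform":
            return self.coords.mean(axis=0)
        w = self.electron_counts
        return (self.coords * w[:, None]).sum(axis=0) / w.sum()

    def translated(self, t) -> "AtomicModel":
        return AtomicModel(self.elements.copy(), self.coords + np.asarray(t, float), self.label)

    def transformed(self, tf: "RigidTransform") -> "AtomicModel":
        return AtomicModel(self.elements.copy(), tf.apply(self.coords), self.label)

    def __add__(self, other: "AtomicModel") -> "AtomicModel":
        return AtomicModel(
            np.concatenate([self.elements, other.elements]),
            np.vstack([self.coords, other.coords]),
            self.label or other.label,
        )


@dataclass
class ComplexModel:
    """Two-subunit complex: the fixed subunit defines the frame, the mobile one moves."""

    fixed_subunit: AtomicModel
    mobile_subunit: AtomicModel
    label: str = ""

    @property
    def n_atoms(self) -> int:
        return self.fixed_subunit.n_atoms + self.mobile_subunit.n_atoms

    @property
    def combined(self) -> AtomicModel:
        m = self.fixed_subunit + self.mobile_subunit
        m.label = self.label
        return m

    def with_mobile(self, mobile: AtomicModel, label: str = "") -> "ComplexModel":
        return ComplexModel(self.fixed_subunit, mobile, label or self.label)


@dataclass
class RigidTransform:
    """Proper rigid-body motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class DecoySet:
    """Native complex plus rigid-body decoys sharing its fixed subunit."""

    native: ComplexModel
    decoys: list
    rmsd: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.rmsd = np.asarray(self.rmsd, float)
        if len(self.decoys) != self.rmsd.shape[0]:
            raise ValueError("one rmsd per decoy required")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd must be non-negative")
        for d in self.decoys:
            if d.n_atoms != self.native.n_atoms:
                raise ValueError("decoy atom count differs from native")

    def __len__(self) -> int:
        return len(self.decoys)


@dataclass
class DensityMap:
    """Scalar density on a regular 3D grid."""

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3D with >=2 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def integral(self) -> float:
        return float(self.values.sum() * self.voxel_size**3)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, include_waters: bool = False, label: str | None = None) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB file into an AtomicModel.

    Element symbols come from the element column when present, falling back to
    the first alphabetic character of the atom name.  Waters are excluded by
    default.  Atoms whose element cannot be resolved are dropped with a
    warning; an empty result is an error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    elements, coords, dropped = [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                if not include_waters and res.name.strip() in _WATER_RESNAMES:
                    continue
                for atom in res:
                    el = atom.element
                    if el.atomic_number == 0:
                        # fall back to the first letter of the atom name
                        name = atom.name.strip().lstrip("0123456789")
                        el = gemmi.Element(name[:1]) if name else el
                    if el.atomic_number == 0:
                        dropped.append(atom.name)
                        continue
                    elements.append(el.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if dropped:
        warnings.warn(f"dropped {len(dropped)} atoms with unresolvable elements: "
                      f"{sorted(set(dropped))}")
    if not coords:
        raise ValueError(f"no accepted atoms in {path}")
    return AtomicModel(np.array(elements, dtype=object), np.array(coords),
                       label if label is not None else path.stem)


def write_pdb(model: AtomicModel, path, chain_id: str = "A") -> None:
    """Write a model as HETATM-free single-chain PDB (one atom per residue)."""
    st = gemmi.Structure()
    st.name = model.label or "model"
    gm = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for i, (sym, xyz) in enumerate(zip(model.elements, model.coords), start=1):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = str(sym)
        atom.element = gemmi.Element(str(sym))
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(str(path))


def write_complex_pdb(cm: ComplexModel, path) -> None:
    """Write a two-subunit complex with the fixed subunit as chain A, mobile as B."""
    st = gemmi.Structure()
    st.name = cm.label or "complex"
    gm = gemmi.Model("1")
    for chain_id, sub in (("A", cm.fixed_subunit), ("B", cm.mobile_subunit)):
        chain = gemmi.Chain(chain_id)
        for i, (sym, xyz) in enumerate(zip(sub.elements, sub.coords), start=1):
            res = gemmi.Residue()
            res.name = "UNK"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = str(sym)
            atom.element = gemmi.Element(str(sym))
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(str(path))


def read_complex_pdb(path) -> ComplexModel:
    """Inverse of :func:`write_complex_pdb` (chain A fixed, chain B mobile)."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    subs = {}
    for model in st:
        for chain in model:
            elements, coords = [], []
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            subs[chain.name] = AtomicModel(np.array(elements, dtype=object),
                                           np.array(coords), f"{path.stem}_{chain.name}")
        break
    if "A" not in subs or "B" not in subs:
        raise ValueError(f"{path} lacks chains A and B")
    return ComplexModel(subs["A"], subs["B"], path.stem)


# ---------------------------------------------------------------------------
# RMSD and decoy generation
# ---------------------------------------------------------------------------

def rmsd_to_native(decoy: ComplexModel, native: ComplexModel) -> float:
    """All-atom RMSD without re-superposition.

    The fixed subunit defines the common frame (docking convention), so the
    deviation is the plain root-mean-square per-atom displacement over every
    atom of the complex, in the order given.
    """
    if decoy.n_atoms != native.n_atoms or \
            decoy.fixed_subunit.n_atoms != native.fixed_subunit.n_atoms:
        raise ValueError("atom counts differ between decoy and native")
    d = decoy.combined.coords - native.combined.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def generate_decoys(native: ComplexModel, n: int, rot_max: float, trans_max: float,
                    seed: int) -> DecoySet:
    """Generate rigid-body decoys by perturbing the mobile subunit.

    Each decoy rotates the mobile subunit about its own (uniform-weight)
    center of mass by a uniform-random axis and an angle uniform in
    [0, rot_max] degrees, then translates it by a uniform-random direction
    scaled by a length uniform in [0, trans_max] Angstrom.  This is a
    controllable, seedable spread generator, NOT a physical docking sampler.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rot_max < 0 or trans_max < 0:
        raise ValueError("rot_max and trans_max must be >= 0")
    rng = np.random.default_rng(seed)
    decoys, rmsds, rows = [], [], []
    com = native.mobile_subunit.coords.mean(axis=0)
    for i in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, rot_max)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.0, trans_max)
        t = direction * length
        R = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
        coords = (native.mobile_subunit.coords - com) @ R.T + com + t
        mobile = AtomicModel(native.mobile_subunit.elements.copy(), coords,
                             native.mobile_subunit.label)
        decoy = native.with_mobile(mobile, label=f"decoy_{i:04d}")
        decoys.append(decoy)
        rmsds.append(rmsd_to_native(decoy, native))
        rows.append({"decoy_id": f"decoy_{i:04d}", "rmsd_A": rmsds[-1],
                     "seed": seed, "rot_deg": angle, "trans_A": length})
    return DecoySet(native, decoys, np.array(rmsds), pd.DataFrame(rows))


def generate_decoy_ladder(native: ComplexModel, n: int, rmsd_max: float = 15.0,
                          rot_max: float = 20.0, seed: int = 0) -> DecoySet:
    """Decoys with an exact monotone RMSD ramp from 0 to rmsd_max.

    Decoy k combines a rotation of the mobile subunit about its center of
    mass (random axis, angle ramping to rot_max) with a translation along a
    random direction whose length is solved so the all-atom RMSD equals
    rmsd_max * k/(n-1) exactly (rotation about the COM and translation add
    in quadrature).  Gives the graded "ladder" spread used to probe how
    scores track structural difference; like :func:`generate_decoys`, not a
    physical docking sampler.
    """
    if n < 2:
        raise ValueError("a ladder needs at least 2 rungs")
    rng = np.random.default_rng(seed)
    com = native.mobile_subunit.coords.mean(axis=0)
    w = native.mobile_subunit.n_atoms / native.n_atoms
    decoys, rmsds, rows = [], [], []
    for k in range(n):
        target = rmsd_max * k / (n - 1)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        angle = rot_max * k / (n - 1)
        R = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
        centered = native.mobile_subunit.coords - com
        rot = centered @ R.T
        rmsd_rot_sq = np.mean(np.sum((rot - centered) ** 2, axis=1)) * w
        if rmsd_rot_sq > target ** 2:
            # shrink the rotation so the target stays reachable
            scale = 0.7 * target / np.sqrt(rmsd_rot_sq) if target > 0 else 0.0
            R = Rotation.from_rotvec(np.deg2rad(angle * scale) * axis).as_matrix()
            rot = centered @ R.T
            rmsd_rot_sq = np.mean(np.sum((rot - centered) ** 2, axis=1)) * w
            angle = angle * scale
        t_len = np.sqrt(max(target ** 2 - rmsd_rot_sq, 0.0) / w)
        coords = rot + com + direction * t_len
        mobile = AtomicModel(native.mobile_subunit.elements.copy(), coords,
                             native.mobile_subunit.label)
        decoy = native.with_mobile(mobile, label=f"decoy_{k:04d}")
        decoys.append(decoy)
        rmsds.append(rmsd_to_native(decoy, native))
        rows.append({"decoy_id": f"decoy_{k:04d}", "rmsd_A": rmsds[-1],
                     "seed": seed, "rot_deg": angle, "trans_A": t_len})
    return DecoySet(native, decoys, np.array(rmsds), pd.DataFrame(rows))


def save_decoy_set(ds: DecoySet, outdir) -> Path:
    """Persist a DecoySet as numbered PDB files plus a TSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_complex_pdb(ds.native, outdir / "native.pdb")
    for i, d in enumerate(ds.decoys):
        write_complex_pdb(d, outdir / f"decoy_{i:04d}.pdb")
    meta = ds.meta if ds.meta is not None else pd.DataFrame(
        {"decoy_id": [f"decoy_{i:04d}" for i in range(len(ds))], "rmsd_A": ds.rmsd})
    meta.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir


def load_decoy_set(outdir) -> DecoySet:
    outdir = Path(outdir)
    native = read_complex_pdb(outdir / "native.pdb")
    meta = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    decoys = [read_complex_pdb(outdir / f"{did}.pdb") for did in meta["decoy_id"]]
    return DecoySet(native, decoys, meta["rmsd_A"].to_numpy(), meta)


# ---------------------------------------------------------------------------
# Density rasterization
# ---------------------------------------------------------------------------

#: Standard deviation of the Gaussian deposited per atom, Angstrom.  One fixed
#: width for every element keeps the map linear in the model; the amplitude is
#: the atomic number so the map integrates to the total electron count.
ATOM_SIGMA = 1.5

_GAUSS_CUTOFF_SIGMAS = 5.0


def rasterize_density(model: AtomicModel, voxel_size: float, padding: float = 6.0,
                      origin: np.ndarray | None = None,
                      shape: tuple | None = None) -> DensityMap:
    """Deposit per-atom Gaussians (sigma ATOM_SIGMA, weight Z) on a grid.

    The grid either derives from the model bounding box plus `padding`, or is
    pinned explicitly with `origin`/`shape` so two models can share one grid.
    Total deposited weight matches the summed electron count to within the
    Gaussian truncation tolerance (<1%).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    coords = model.coords
    if origin is None or shape is None:
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        n = np.ceil((hi - lo) / voxel_size).astype(int) + 1
        if np.any(n < 2):
            raise ValueError("voxel_size larger than padded model extent")
        origin = lo
        shape = tuple(n)
    origin = np.asarray(origin, float)
    grid = np.zeros(shape, float)
    weights = model.electron_counts
    # normalized 3D Gaussian sampled at voxel centers
    half = int(np.ceil(_GAUSS_CUTOFF_SIGMAS * ATOM_SIGMA / voxel_size))
    offs = np.arange(-half, half + 1)
    norm = voxel_size**3 / ((2 * np.pi) ** 1.5 * ATOM_SIGMA**3)
    for xyz, w in zip(coords, weights):
        idx_f = (xyz - origin) / voxel_size
        idx0 = np.round(idx_f).astype(int)
        sub = [idx0[k] + offs for k in range(3)]
        keep = [np.clip(sub[k], 0, shape[k] - 1) for k in range(3)]
        d = [(sub[k] - idx_f[k]) * voxel_size for k in range(3)]
        g = [np.exp(-0.5 * (dk / ATOM_SIGMA) ** 2) for dk in d]
        stamp = w * norm * g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        # out-of-grid contributions are discarded, not wrapped
        inside = [(sub[k] >= 0) & (sub[k] < shape[k]) for k in range(3)]
        stamp = stamp * (inside[0][:, None, None] & inside[1][None, :, None]
                         & inside[2][None, None, :])
        np.add.at(grid, np.ix_(keep[0], keep[1], keep[2]), stamp)
    return DensityMap(grid / voxel_size**3, voxel_size, origin)


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

#: protein-like bulk composition used by the toy generator
_TOY_ELEMENTS = np.array(["C", "N", "O"], dtype=object)
_TOY_WEIGHTS = np.array([0.62, 0.17, 0.21])


def toy_subunit_radius(n_atoms: int) -> float:
    """Sphere radius giving a protein-like packing density (~0.1 atom/A^3)."""
    return max(2.0, (3.0 * n_atoms / (4.0 * np.pi * 0.1)) ** (1.0 / 3.0))


def make_toy_complex(n_fixed: int, n_mobile: int, seed: int) -> ComplexModel:
    """Compact pseudo-random two-sphere complex for tests and demos.

    Atoms are drawn uniformly inside two tangent spheres with protein-like
    C/N/O composition; each subunit is re-centered so the (uniform-weight)
    centers of mass sit exactly at the documented placement: the fixed subunit
    at the origin, the mobile one at (r_fixed + r_mobile, 0, 0).
    """
    if n_fixed < 1 or n_mobile < 1:
        raise ValueError("subunit atom counts must be >= 1")
    rng = np.random.default_rng(seed)

    def ball(n, radius, center):
        pts = np.empty((0, 3))
        while pts.shape[0] < n:
            cand = rng.uniform(-radius, radius, size=(2 * n + 8, 3))
            cand = cand[np.sum(cand**2, axis=1) <= radius**2]
            pts = np.vstack([pts, cand])
        pts = pts[:n]
        pts = pts - pts.mean(axis=0) + center  # exact COM placement
        el = rng.choice(_TOY_ELEMENTS, size=n, p=_TOY_WEIGHTS)
        return AtomicModel(el, pts)

    r_f = toy_subunit_radius(n_fixed)
    r_m = toy_subunit_radius(n_mobile)
    fixed = ball(n_fixed, r_f, np.zeros(3))
    mobile = ball(n_mobile, r_m, np.array([r_f + r_m, 0.0, 0.0]))
    fixed.label, mobile.label = "toy_fixed", "toy_mobile"
    return ComplexModel(fixed, mobile, label=f"toy_{n_fixed}_{n_mobile}_s{seed}")


def toy_complex_separation(n_fixed: int, n_mobile: int) -> float:
    """The documented COM separation of :func:`make_toy_complex` output."""
    return toy_subunit_radius(n_fixed) + toy_subunit_radius(n_mobile)
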