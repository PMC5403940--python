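"""Decoy-level scoring functions and ranking-power evaluation.

Scores (all lower = better):

* SPI chi-score — variance-normalized mean squared per-pixel residual between
  model and data patterns, either at known matched orientations or with the
  orientation of each data pattern recovered by chi minimization over a
  reference bank.
* SAXS chi-score — the same statistic on rotationally aggregated 1D profiles,
  with the model side available analytically (Debye formula) or by pattern
  averaging.
* s-score = 1 - max_R cc — one minus the best density cross-correlation over
  relative rotations of the COM-centered models; a sequence-blind structural
  difference measure.

Ranking power is quantified by the RMSD (or s-score) probability distribution
of the n best-scored decoys, its cumulative curve, and the area under that
curve (AUC in [0, 1]; 1 = perfect ordering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matching import OrientationGrid, build_bank, make_grid, match_set, total_comparisons
from .models import AtomicModel, ComplexModel, DecoySet, rasterize_density, ATOM_SIGMA
from .reduce import radial_profile
from .simulate import (PatternSet, Pattern, SIGMA_FLOOR, debye_profile,
                       sample_orientations, simulate_pattern)

__all__ = ["spi_score_matched", "spi_score_matching", "model_patterns_for",
           "saxs_score", "profile_chi", "s_score", "combine_zscores", "ranking_curves",
           "score_difference_correlation", "RankingCurves", "score_decoys",
           "write_score_table", "read_score_table"]


# ---------------------------------------------------------------------------
# SPI chi-scores
# ---------------------------------------------------------------------------

def _pattern_chi(model_i: np.ndarray, data_i: np.ndarray, data_s: np.ndarray,
                 mask: np.ndarray) -> float:
    s = np.maximum(data_s[mask], SIGMA_FLOOR)
    r = (model_i[mask] - data_i[mask]) / s
    return float(np.mean(r * r))


def spi_score_matched(exp: PatternSet, model_patterns: PatternSet,
                      per_pattern: bool = False,
                      check_orientations: bool = True):
    """SPI chi-score with known (index-matched) orientations.

    Mean over patterns of the mean over masked pixels of
    ((I_model - I_data)/sigma_data)^2, sigma_data floored at one photon.
    """
    if len(exp) != len(model_patterns):
        raise ValueError("pattern counts differ")
    if exp.patterns[0].intensity.shape != model_patterns.patterns[0].intensity.shape:
        raise ValueError("pattern shapes differ")
    if check_orientations and not np.allclose(
            exp.orientations(), model_patterns.orientations(), atol=1e-9):
        raise ValueError("orientations are not index-matched; use the "
                         "orientation-matching score instead")
    mask = exp.qmap.mask
    chis = np.array([_pattern_chi(m.intensity, d.intensity, d.sigma, mask)
                     for m, d in zip(model_patterns.patterns, exp.patterns)])
    return (float(chis.mean()), chis) if per_pattern else float(chis.mean())


def model_patterns_for(exp: PatternSet, model, label: str = "model") -> PatternSet:
    """Noise-free model patterns at the data's orientations and photon scale."""
    atomic = model.combined if isinstance(model, ComplexModel) else model
    scale = exp.photon_scale
    pats = []
    for ori in exp.orientations():
        p = simulate_pattern(atomic, ori, exp.qmap)
        pats.append(Pattern(p.intensity * scale,
                            np.maximum(np.sqrt(p.intensity * scale), SIGMA_FLOOR),
                            ori))
    return PatternSet(pats, exp.qmap, label, {"photon_scale": scale})


def spi_score_matching(exp: PatternSet, decoy, grid: OrientationGrid,
                       representation: str = "raw", n_qbins: int = 32,
                       n_phibins: int = 72, bank=None, return_results: bool = False):
    """SPI chi-score with orientations recovered by bank minimization.

    For each experimental pattern the minimum chi over all bank entries is
    taken; the score is the mean of those minima.  When the true orientations
    lie on the grid and the data are noise-free this equals the matched-mode
    score.
    """
    if bank is None:
        bank = build_bank(decoy, grid, exp.qmap, representation,
                          scale=exp.photon_scale, n_qbins=n_qbins,
                          n_phibins=n_phibins)
    results = match_set(exp, bank)
    score = float(np.mean([r.best_chi for r in results]))
    return (score, results) if return_results else score


# ---------------------------------------------------------------------------
# SAXS chi-score
# ---------------------------------------------------------------------------

def profile_chi(model_intensity: np.ndarray, data) -> float:
    """Chi-score between a model profile and a data RadialProfile:
    mean over shared valid bins of ((I_model - I_data)/sigma_data)^2."""
    model_intensity = np.asarray(model_intensity, float)
    ok = np.isfinite(data.intensity) & np.isfinite(model_intensity)
    if not ok.any():
        raise ValueError("no shared valid q bins between profiles")
    r = (model_intensity[ok] - data.intensity[ok]) / data.sigma[ok]
    return float(np.mean(r * r))


def saxs_score(exp: PatternSet, decoy, n_qbins: int = 32, n_phibins: int = 72,
               method: str = "debye", n_orientations: int = 512, seed: int = 0,
               return_profiles: bool = False):
    """SAXS chi-score between the data's aggregated profile and the model's.

    The data profile aggregates the experimental patterns (azimuthal then
    pattern average).  The model side is the analytic Debye rotational
    average by default (exact, noise-free), or the same pattern-aggregation
    applied to freshly simulated model patterns at Haar-random orientations
    (method='patterns', the validation route).
    """
    atomic = decoy.combined if isinstance(decoy, ComplexModel) else decoy
    data = radial_profile(exp, exp.qmap, n_qbins, n_phibins)
    if method == "debye":
        model_i = debye_profile(atomic, data.q_centers) * exp.photon_scale
    elif method == "patterns":
        oris = sample_orientations(n_orientations, mode="so3", seed=seed)
        pats = [simulate_pattern(atomic, o, exp.qmap) for o in oris]
        scale = exp.photon_scale
        pats = [Pattern(p.intensity * scale, p.sigma, p.orientation) for p in pats]
        mset = PatternSet(pats, exp.qmap, "model")
        model_i = radial_profile(mset, exp.qmap, n_qbins, n_phibins,
                                 data.q_centers).intensity
    else:
        raise ValueError(f"unknown SAXS model method {method!r}")
    chi = profile_chi(model_i, data)
    return (chi, data, model_i) if return_profiles else chi


# ---------------------------------------------------------------------------
# Density-overlap s-score
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("degenerate (constant) density map")
    return float((a @ b) / denom)


def s_score(decoy, native, rot_step: float = 10.0, voxel_size: float = 2.0,
            bounds=None, return_cc: bool = False):
    """Density-difference score s = 1 - max_R cc(native, R(decoy)).

    Both models are shifted so their electron-weighted centers of mass sit at
    the origin (no translational search); the relative orientation is scanned
    on an Euler grid and the Pearson correlation of the two maps on a common
    grid is maximized.  s is 0 for identical models and ~1 for unrelated ones.
    """
    nat = (native.combined if isinstance(native, ComplexModel) else native)
    dec = (decoy.combined if isinstance(decoy, ComplexModel) else decoy)
    nat = nat.translated(-nat.center_of_mass())
    dec = dec.translated(-dec.center_of_mass())
    # common cubic grid covering either model in any orientation
    radius = max(np.linalg.norm(nat.coords, axis=1).max(),
                 np.linalg.norm(dec.coords, axis=1).max())
    half = radius + 3.0 * ATOM_SIGMA + voxel_size
    n = int(np.ceil(2 * half / voxel_size)) + 1
    origin = np.full(3, -half)
    shape = (n, n, n)
    ref = rasterize_density(nat, voxel_size, origin=origin, shape=shape).values
    grid = make_grid(rot_step, bounds)
    from .simulate import euler_to_matrix
    best = -np.inf
    for tri in grid.triples:
        R = euler_to_matrix(tri)
        rot = AtomicModel(dec.elements, dec.coords @ R.T)
        mv = rasterize_density(rot, voxel_size, origin=origin, shape=shape).values
        cc = _pearson(ref, mv)
        if cc > best:
            best = cc
    # cc can exceed 1 by a few ulp on identical maps; s is defined >= 0
    s = max(1.0 - best, 0.0) if abs(1.0 - best) < 1e-9 else 1.0 - best
    return (s, best) if return_cc else s


# ---------------------------------------------------------------------------
# Score combination and ranking evaluation
# ---------------------------------------------------------------------------

def combine_zscores(scores_a, scores_b, higher_is_better=(False, False)) -> np.ndarray:
    """Standardized (Z-score) sum of two score columns, lower = better.

    Each column is shifted/scaled to zero mean and unit variance over the
    decoys, sign-flipped if higher values mean better models, and summed.
    Experimental: a plain linear combination, no reweighting.
    """
    out = np.zeros(len(np.asarray(scores_a, float)))
    for col, flip in zip((scores_a, scores_b), higher_is_better):
        col = np.asarray(col, float)
        if col.shape[0] != out.shape[0]:
            raise ValueError("score columns differ in length")
        if not np.all(np.isfinite(col)):
            raise ValueError("scores must be finite")
        sd = col.std()
        if sd == 0:
            raise ValueError("zero-variance score column cannot be standardized")
        z = (col - col.mean()) / sd
        out += -z if flip else z
    return out


@dataclass
class RankingCurves:
    """P(difference | top-n selection), cumulative curves, and their AUCs."""

    score_column: str
    difference_column: str
    bin_edges: np.ndarray
    n_select: tuple
    pdf: dict
    cumulative: dict
    auc: dict


def _key(n) -> str:
    return "all" if n is None else str(int(n))


def ranking_curves(table: pd.DataFrame, score_column: str,
                   difference_column: str = "rmsd",
                   n_select=(25, 100, None), bins: int = 25) -> RankingCurves:
    """Difference distributions of the n lowest-scored decoys and their AUCs.

    The difference axis is normalized by the largest difference in the whole
    decoy set, the cumulative curve includes the endpoints (0, CDF(0)) and
    (1, 1), and the AUC is its trapezoidal area — 1.0 exactly when every
    selected decoy is identical to the native.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    diffs_all = table[difference_column].to_numpy(float)
    scores = table[score_column].to_numpy(float)
    dmax = float(diffs_all.max())
    edges = np.linspace(0.0, dmax if dmax > 0 else 1.0, bins + 1)
    pdf, cum, auc = {}, {}, {}
    order = np.argsort(scores, kind="stable")
    for n in n_select:
        take = len(table) if n is None else int(n)
        if take < 1 or take > len(table):
            raise ValueError(f"cannot select {n} of {len(table)} decoys")
        sel = diffs_all[order[:take]]
        if dmax == 0:
            p = np.zeros(bins)
            p[0] = 1.0
            pdf[_key(n)] = p
            cum[_key(n)] = np.ones(bins)
            auc[_key(n)] = 1.0
            continue
        counts, _ = np.histogram(sel, bins=edges)
        # clip at the top edge: differences == dmax land in the last bin
        counts[-1] += int(np.sum(sel > edges[-1]))
        p = counts / take
        c = np.cumsum(p)
        x = np.concatenate([[0.0], edges[1:] / dmax])
        y = np.concatenate([[float(np.mean(sel <= 0.0))], c])
        pdf[_key(n)] = p
        cum[_key(n)] = c
        auc[_key(n)] = float(np.trapezoid(y, x))
    return RankingCurves(score_column, difference_column, edges,
                         tuple(n_select), pdf, cum, auc)


def score_difference_correlation(table: pd.DataFrame, score_column: str,
                                 difference_column: str = "rmsd",
                                 method: str = "pearson") -> float:
    """Correlation between a score and a structural-difference measure."""
    if len(table) < 3:
        raise ValueError("need at least 3 decoys")
    x = table[score_column].to_numpy(float)
    y = table[difference_column].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance column")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Pipeline helper and TSV persistence
# ---------------------------------------------------------------------------

def score_decoys(exp: PatternSet, decoy_set: DecoySet, mode: str = "matched",
                 grid: OrientationGrid = None, representation: str = "raw",
                 n_qbins: int = 32, n_phibins: int = 72,
                 with_s_score: bool = False, s_rot_step: float = 30.0,
                 progress=None) -> pd.DataFrame:
    """Score every decoy of a set against one experimental pattern set.

    Returns a table with one row per decoy: spi_score, saxs_score, rmsd, and
    optionally s_score.  `mode` picks matched (known orientations) or
    matching (bank minimization, needs `grid`) for the SPI column.
    """
    rows = []
    comparisons = 0
    for i, decoy in enumerate(decoy_set.decoys):
        if mode == "matched":
            spi = spi_score_matched(exp, model_patterns_for(exp, decoy),
                                    check_orientations=True)
        elif mode == "matching":
            if grid is None:
                raise ValueError("matching mode requires an orientation grid")
            spi, res = spi_score_matching(exp, decoy, grid, representation,
                                          n_qbins, n_phibins, return_results=True)
            comparisons += total_comparisons(res)
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
        row = {"decoy_id": f"decoy_{i:04d}", "spi_score": spi,
               "saxs_score": saxs_score(exp, decoy, n_qbins, n_phibins),
               "rmsd": float(decoy_set.rmsd[i])}
        if with_s_score:
            row["s_score"] = s_score(decoy, decoy_set.native, rot_step=s_rot_step)
        rows.append(row)
        if progress is not None:
            progress(i + 1, len(decoy_set))
    df = pd.DataFrame(rows)
    df.attrs["comparison_count"] = comparisons
    return df


def write_score_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """TSV with '#'-commented header metadata lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
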