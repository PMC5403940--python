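"""SPI/SAXS chi-scores, s-score, Z-combination, ranking curves."""

import numpy as np
import pandas as pd
import pytest

import spidock as sd
from spidock.geometry import QMap
from spidock.matching import SUBSPACE_BOUNDS, build_bank, make_grid
from spidock.reduce import RadialProfile
from spidock.scoring import (combine_zscores, model_patterns_for, profile_chi,
                             ranking_curves, s_score, saxs_score,
                             score_difference_correlation, spi_score_matched,
                             spi_score_matching)
from spidock.simulate import Pattern, PatternSet


def _single_pixel_qmap():
    return QMap(np.zeros((1, 1, 3)), np.zeros((1, 1)),
                np.ones((1, 1), bool), None)


def _single_pixel_set(value, sigma=1.0):
    qm = _single_pixel_qmap()
    p = Pattern(np.array([[float(value)]]), np.array([[sigma]]), (0, 0, 0))
    return PatternSet([p], qm)


class TestSpiMatched:
    def test_identity_is_zero(self, scaled_patterns):
        assert spi_score_matched(scaled_patterns, scaled_patterns) == 0.0

    def test_single_pixel_arithmetic(self):
        data = _single_pixel_set(1.0, sigma=1.0)
        model = _single_pixel_set(3.0)
        assert spi_score_matched(data, model) == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self, toy_complex, small_qmap):
        rng = np.random.default_rng(9)
        oris = sd.sample_orientations(2, SUBSPACE_BOUNDS, seed=1)
        exp = sd.scale_to_photons(
            sd.simulate_set(toy_complex.combined, oris, small_qmap), 4.0)
        decoy = sd.generate_decoys(toy_complex, 1, 5.0, 3.0, seed=2).decoys[0]
        model = model_patterns_for(exp, decoy)
        got = spi_score_matched(exp, model)
        mask = small_qmap.mask
        acc = 0.0
        for n in range(2):
            im = model.patterns[n].intensity[mask]
            idat = exp.patterns[n].intensity[mask]
            s = np.maximum(exp.patterns[n].sigma[mask], 1.0)
            acc += np.mean(((im - idat) / s) ** 2)
        assert got == pytest.approx(acc / 2, rel=1e-12)

    def test_shape_mismatch_raises(self, scaled_patterns):
        with pytest.raises(ValueError):
            spi_score_matched(scaled_patterns, _single_pixel_set(1.0))


class TestSpiMatching:
    @pytest.fixture(scope="class")
    def on_grid_exp(self, toy_complex, small_qmap):
        grid = make_grid(11.25, SUBSPACE_BOUNDS)
        rng = np.random.default_rng(12)
        tris = grid.triples[rng.choice(len(grid), 5, replace=False)]
        exp = sd.scale_to_photons(
            sd.simulate_set(toy_complex.combined, tris, small_qmap), 4.0)
        return grid, exp

    def test_native_on_grid_noise_free_is_zero(self, toy_complex, small_qmap,
                                               on_grid_exp):
        grid, exp = on_grid_exp
        assert spi_score_matching(exp, toy_complex, grid) == 0.0

    def test_min_property_vs_fixed_assignment(self, toy_complex, small_qmap,
                                              on_grid_exp):
        grid, exp = on_grid_exp
        decoy = sd.generate_decoys(toy_complex, 1, 8.0, 5.0, seed=4).decoys[0]
        bank = build_bank(decoy, grid, small_qmap, "raw",
                          scale=exp.photon_scale)
        matching = spi_score_matching(exp, decoy, grid, bank=bank)
        # any fixed orientation assignment (here: the true ones) bounds it
        fixed = spi_score_matched(exp, model_patterns_for(exp, decoy))
        assert matching <= fixed + 1e-12
        rng = np.random.default_rng(3)
        for _ in range(5):
            tris = grid.triples[rng.integers(0, len(grid), len(exp))]
            pats = [sd.simulate_pattern(decoy.combined, t, small_qmap)
                    for t in tris]
            pats = [Pattern(p.intensity * exp.photon_scale, p.sigma, o.orientation)
                    for p, o in zip(pats, exp.patterns)]
            other = spi_score_matched(exp, PatternSet(pats, small_qmap),
                                      check_orientations=False)
            assert matching <= other + 1e-12

    def test_equals_exhaustive_pair_loop(self, toy_complex, small_qmap):
        grid = make_grid(22.5, SUBSPACE_BOUNDS)    # 27 triples
        oris = sd.sample_orientations(4, SUBSPACE_BOUNDS, seed=6)
        exp = sd.scale_to_photons(
            sd.simulate_set(toy_complex.combined, oris, small_qmap), 4.0)
        decoys = sd.generate_decoys(toy_complex, 3, 6.0, 4.0, seed=5).decoys
        mask = small_qmap.mask
        for decoy in decoys:
            got = spi_score_matching(exp, decoy, grid)
            bank_i = [sd.simulate_pattern(decoy.combined, t, small_qmap)
                      .intensity[mask] * exp.photon_scale
                      for t in grid.triples]
            acc = 0.0
            for p in exp.patterns:
                s = np.maximum(p.sigma[mask], 1.0)
                acc += min(np.mean(((bi - p.intensity[mask]) / s) ** 2)
                           for bi in bank_i)
            assert got == pytest.approx(acc / len(exp), rel=1e-10)


class TestSaxs:
    def test_profile_chi_identity_and_arithmetic(self):
        data = RadialProfile(np.array([0.1, 0.2]), np.array([1.0, 2.0]),
                             np.array([1.0, 1.0]))
        assert profile_chi(data.intensity, data) == 0.0
        # residual/sigma = (1, 3) -> chi = (1 + 9)/2 = 5
        assert profile_chi(np.array([2.0, 5.0]), data) == pytest.approx(5.0)

    def test_debye_and_pattern_routes_agree(self, toy_complex, small_qmap):
        oris = sd.sample_orientations(150, mode="so3", seed=8)
        exp = sd.scale_to_photons(
            sd.simulate_set(toy_complex.combined, oris, small_qmap), 4.0)
        decoy = sd.generate_decoys(toy_complex, 1, 10.0, 6.0, seed=9).decoys[0]
        chi_d, data, prof_d = saxs_score(exp, decoy, n_qbins=12,
                                         return_profiles=True)
        chi_p, _, prof_p = saxs_score(exp, decoy, n_qbins=12,
                                      method="patterns", n_orientations=400,
                                      seed=10, return_profiles=True)
        np.testing.assert_allclose(prof_p, prof_d, rtol=0.1)

    def test_score_invariant_to_model_orientation_resampling(self, toy_complex,
                                                              small_qmap):
        # the pattern-averaged model profile depends only on the decoy's
        # internal structure: re-randomizing its orientations leaves the
        # score unchanged within sampling error of the rotational average
        decoy = sd.generate_decoys(toy_complex, 1, 12.0, 8.0, seed=11).decoys[0]
        oris = sd.sample_orientations(200, mode="so3", seed=1)
        exp = sd.scale_to_photons(
            sd.simulate_set(toy_complex.combined, oris, small_qmap), 4.0)
        chis = [saxs_score(exp, decoy, n_qbins=12, method="patterns",
                           n_orientations=400, seed=s) for s in (5, 6)]
        assert chis[0] == pytest.approx(chis[1], rel=0.5)

    def test_bin_mismatch_raises(self):
        data = RadialProfile(np.array([0.1, 0.2]), np.array([np.nan, np.nan]),
                             np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            profile_chi(np.array([1.0, 1.0]), data)


class TestSScore:
    def test_identity_is_zero(self):
        cm = sd.make_toy_complex(20, 12, seed=13)
        s = s_score(cm, cm, rot_step=90.0)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = sd.make_toy_complex(20, 12, seed=14)
        b = sd.generate_decoys(a, 1, 15.0, 6.0, seed=15).decoys[0]
        bounds = ((-30.0, 30.0),) * 3
        s_ab = s_score(a, b, rot_step=15.0, bounds=bounds)
        s_ba = s_score(b, a, rot_step=15.0, bounds=bounds)
        assert s_ab == pytest.approx(s_ba, abs=0.03)

    def test_refinement_never_decreases_max_cc(self):
        a = sd.make_toy_complex(15, 10, seed=16)
        b = sd.generate_decoys(a, 1, 25.0, 5.0, seed=17).decoys[0]
        _, cc_coarse = s_score(a, b, rot_step=90.0, return_cc=True)
        _, cc_fine = s_score(a, b, rot_step=45.0, return_cc=True)
        assert cc_coarse <= cc_fine + 1e-12

    def test_unrelated_wide_clouds_decorrelate(self):
        rng = np.random.default_rng(18)
        from spidock.models import AtomicModel
        mk = lambda seed: AtomicModel(
            np.array(["C"] * 40, dtype=object),
            np.random.default_rng(seed).uniform(-18, 18, (40, 3)))
        s = s_score(mk(1), mk(2), rot_step=1.0,
                    bounds=((0.0, 0.0),) * 3)       # identity rotation only
        assert s == pytest.approx(1.0, abs=0.35)


class TestCombineZScores:
    def test_self_combination_preserves_order(self):
        rng = np.random.default_rng(19)
        a = rng.normal(size=30)
        c = combine_zscores(a, a)
        np.testing.assert_array_equal(np.argsort(c), np.argsort(a))

    def test_opposite_standardized_columns_cancel(self):
        a = np.array([-1.5, -0.5, 0.5, 1.5])
        a = (a - a.mean()) / a.std()
        np.testing.assert_allclose(combine_zscores(a, -a), 0.0, atol=1e-12)

    def test_matches_hand_computed_sum(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=(2, 25))
        got = combine_zscores(a, b)
        expect = (a - a.mean()) / a.std() + (b - b.mean()) / b.std()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            combine_zscores(np.ones(5), np.arange(5.0))


class TestRankingCurves:
    def test_all_identical_decoys_auc_one(self):
        df = pd.DataFrame({"spi_score": [0.3, 0.1, 0.2], "rmsd": [0.0, 0.0, 0.0]})
        rc = ranking_curves(df, "spi_score", "rmsd", n_select=(None,), bins=25)
        assert rc.auc["all"] == 1.0
        np.testing.assert_array_equal(rc.cumulative["all"], 1.0)

    def test_perfect_ranking_uniform_ladder_closed_form(self):
        # off-edge differences so the histogram boundary convention is moot
        N, bins = 100, 25
        diffs = np.sort(np.random.default_rng(30).uniform(0.5, 15.0, N))
        df = pd.DataFrame({"s": diffs.copy(), "rmsd": diffs})
        rc = ranking_curves(df, "s", "rmsd", n_select=(None,), bins=bins)
        # closed form: CDF at edge e is floor-free fraction count(d<=e)/N for
        # the uniform ladder; trapezoid over the same bin grid
        dmax = diffs.max()
        edges = np.linspace(0.0, dmax, bins + 1)
        cdf = np.array([np.sum(diffs <= e) / N for e in edges[1:]])
        x = np.concatenate([[0.0], edges[1:] / dmax])
        y = np.concatenate([[0.0], cdf])
        expect = np.trapezoid(y, x)
        assert rc.auc["all"] == pytest.approx(expect, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame({"s": rng.normal(size=60),
                           "rmsd": rng.uniform(0, 15, 60)})
        df2 = df.assign(s=np.exp(3 * df["s"]))
        a = ranking_curves(df, "s", "rmsd", n_select=(25, None))
        b = ranking_curves(df2, "s", "rmsd", n_select=(25, None))
        assert a.auc == b.auc

    def test_selection_improves_auc_for_informative_score(self):
        rng = np.random.default_rng(23)
        rmsd = rng.uniform(0, 15, 200)
        df = pd.DataFrame({"s": rmsd + rng.normal(0, 2.0, 200), "rmsd": rmsd})
        rc = ranking_curves(df, "s", "rmsd", n_select=(25, None))
        assert rc.auc["25"] >= rc.auc["all"]

    def test_oversized_selection_raises(self):
        df = pd.DataFrame({"s": [1.0, 2.0], "rmsd": [0.1, 0.2]})
        with pytest.raises(ValueError):
            ranking_curves(df, "s", "rmsd", n_select=(5,))


class TestCorrelation:
    def test_affine_and_anti_correlation(self):
        df = pd.DataFrame({"rmsd": [1.0, 2.0, 3.0, 4.0]})
        df["up"] = 2 * df["rmsd"] + 1
        df["down"] = -df["rmsd"]
        assert score_difference_correlation(df, "up") == pytest.approx(1.0)
        assert score_difference_correlation(df, "down") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(24)
        df = pd.DataFrame({"s": rng.normal(size=40),
                           "rmsd": rng.uniform(0, 10, 40)})
        r = score_difference_correlation(df, "s")
        x, y = df["s"], df["rmsd"]
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std(ddof=0) * y.std(ddof=0))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_degenerate_raises(self):
        df = pd.DataFrame({"s": [1.0, 1.0, 1.0], "rmsd": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            score_difference_correlation(df, "s")
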