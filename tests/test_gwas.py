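"""Three-step GWAS: screening, SBC cofactors, conditioned scan, Holm,
founder effects and explained variance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from magicwas.gwas import (HaplotypeGWAS, explained_variance, founder_effects,
                           holm_adjust, sbc, step1_cv_screen,
                           step2_sbc_cofactors, step3_scan)


def binary_markers(n, M, seed=0, freqs=None):
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.uniform(0.1, 0.5, size=M)
    X = (rng.random((n, M)) < freqs).astype(np.int8)
    return pd.DataFrame(X, index=[f"L{i}" for i in range(n)],
                        columns=[f"m{j}" for j in range(M)])


class TestStep1:
    def test_planted_signal_almost_always_included(self):
        X = binary_markers(400, 1000, seed=1)
        rng = np.random.default_rng(2)
        x = X.to_numpy(float)[:, 7]
        # marker explains ~90% of variance
        y = pd.Series(3.0 * x + 0.45 * rng.normal(size=400), index=X.index)
        trace = step1_cv_screen(X, y, n_reps=100, seed=3)
        assert trace.inclusion_count.iloc[7] >= 95

    def test_null_robust_set_near_empty(self):
        X = binary_markers(400, 500, seed=4)
        y = pd.Series(np.random.default_rng(5).normal(size=400), index=X.index)
        trace = step1_cv_screen(X, y, n_reps=50, seed=6)
        # a handful of chance markers may recur; the set stays tiny
        assert len(trace.robust()) <= 0.02 * 500

    def test_single_repetition_cannot_be_robust(self):
        X = binary_markers(100, 20, seed=7)
        y = pd.Series(X.to_numpy(float)[:, 0] * 2.0, index=X.index)
        trace = step1_cv_screen(X, y, n_reps=1, seed=8)
        assert trace.robust(min_count=2) == []
        assert trace.inclusion_count.max() <= 1

    def test_too_few_lines_error(self):
        X = binary_markers(3, 5)
        y = pd.Series([1.0, 2.0, 3.0], index=X.index)
        with pytest.raises(ValueError, match="too few lines"):
            step1_cv_screen(X, y, train_frac=0.999)

    def test_seed_determinism(self):
        X = binary_markers(200, 100, seed=9)
        y = pd.Series(np.random.default_rng(10).normal(size=200), index=X.index)
        a = step1_cv_screen(X, y, n_reps=10, seed=11)
        b = step1_cv_screen(X, y, n_reps=10, seed=11)
        pd.testing.assert_series_equal(a.inclusion_count, b.inclusion_count)
        assert a.selected_sets == b.selected_sets


class TestStep2:
    def test_sbc_closed_form(self):
        assert sbc(100, 50.0, 3) == pytest.approx(
            100 * np.log(0.5) + 3 * np.log(100))
        assert sbc(100, 50.0, 3) == pytest.approx(-55.49, abs=0.01)

    def test_no_improvement_gives_empty_set(self):
        X = binary_markers(200, 5, seed=1)
        y = pd.Series(np.random.default_rng(2).normal(size=200), index=X.index)
        cof = step2_sbc_cofactors(X, y)
        assert len(cof) <= 1  # pure noise rarely beats the SBC penalty
        assert all(np.diff(cof.sbc_path) < 0)

    def test_true_predictors_selected_noise_rejected(self):
        rng = np.random.default_rng(3)
        X = binary_markers(300, 10, seed=4)
        xv = X.to_numpy(float)
        y = pd.Series(2.0 * xv[:, 2] - 1.5 * xv[:, 6]
                      + 0.5 * rng.normal(size=300), index=X.index)
        cof = step2_sbc_cofactors(X, y)
        assert set(cof.markers) >= {"m2", "m6"}
        # adding pure-noise markers to a saturated model raises SBC
        n = 300
        A = np.column_stack([np.ones(n), xv[:, [2, 6]]])
        sse_true = float(((y - A @ np.linalg.lstsq(A, y, rcond=None)[0])**2).sum())
        worse = 0
        for s in range(10):
            noise = (np.random.default_rng(50 + s).random(n) < 0.3).astype(float)
            A2 = np.column_stack([A, noise])
            sse2 = float(((y - A2 @ np.linalg.lstsq(A2, y, rcond=None)[0])**2).sum())
            if sbc(n, sse2, 4) > sbc(n, sse_true, 3):
                worse += 1
        assert worse >= 8

    def test_collinear_candidate_skipped(self):
        X = binary_markers(100, 3, seed=5)
        X["m3"] = X["m0"]  # perfect duplicate
        y = pd.Series(3.0 * X["m0"].astype(float)
                      + 0.1 * np.random.default_rng(6).normal(size=100),
                      index=X.index)
        cof = step2_sbc_cofactors(X, y)
        assert not {"m0", "m3"} <= set(cof.markers)


class TestStep3:
    def test_empty_cofactors_reduces_to_univariate_ols(self):
        X = binary_markers(150, 40, seed=1)
        y = pd.Series(np.random.default_rng(2).normal(size=150), index=X.index)
        res = step3_scan(X, y, [])
        yv = y.to_numpy()
        for m in X.columns[:10]:
            x = X[m].to_numpy(float)
            slope, _, r, p, _ = sps.linregress(x, yv)
            assert res.loc[m, "effect"] == pytest.approx(slope, rel=1e-10)
            assert res.loc[m, "p_raw"] == pytest.approx(p, rel=1e-8)
            assert res.loc[m, "partial_R2"] == pytest.approx(r**2, rel=1e-10)

    def test_orthogonal_marker_effect_unchanged_by_cofactors(self):
        rng = np.random.default_rng(3)
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        z = np.repeat([0, 1], n // 2).astype(float)
        # force exact orthogonality (zero sample covariance)
        x = x - x.mean()
        z = z - z.mean()
        x = x - z * (x @ z) / (z @ z)
        X = pd.DataFrame({"mx": x, "mz": z}, index=[f"L{i}" for i in range(n)])
        y = pd.Series(1.0 * x + 2.0 * z + rng.normal(size=n), index=X.index)
        with_cof = step3_scan(X, y, ["mz"])
        without = step3_scan(X[["mx"]], y, [])
        assert with_cof.loc["mx", "effect"] == pytest.approx(
            without.loc["mx", "effect"], rel=1e-10)

    def test_cofactor_tested_without_itself(self):
        X = binary_markers(200, 5, seed=4)
        y = pd.Series(2.0 * X["m1"].astype(float)
                      + np.random.default_rng(5).normal(size=200), index=X.index)
        res = step3_scan(X, y, ["m1"])
        # m1 must get a real test (itself out of the background), not p=1
        assert res.loc["m1", "estimable"]
        assert res.loc["m1", "p_raw"] < 1e-6

    def test_collinear_marker_flagged(self):
        X = binary_markers(100, 3, seed=6)
        X["dup"] = X["m0"]
        y = pd.Series(np.random.default_rng(7).normal(size=100), index=X.index)
        res = step3_scan(X, y, ["m0"])
        assert not res.loc["dup", "estimable"]
        assert res.loc["dup", "p_raw"] == 1.0

    def test_planted_qtl_ranks_top_by_partial_r2(self):
        rng = np.random.default_rng(8)
        X = binary_markers(500, 300, seed=9)
        xv = X.to_numpy(float)
        y = pd.Series(1.5 * xv[:, 42] + rng.normal(size=500), index=X.index)
        res = step3_scan(X, y, [])
        assert res["partial_R2"].idxmax() == "m42"


class TestHolm:
    def test_textbook_example(self):
        adj = holm_adjust(np.array([0.01, 0.04]))
        np.testing.assert_allclose(adj, [0.02, 0.04])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(holm_adjust(np.array([0.3])), [0.3])
        np.testing.assert_allclose(holm_adjust(np.ones(5)), np.ones(5))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 3
        mine = holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_monotone_and_bounded(self):
        p = np.random.default_rng(1).uniform(size=50)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFounderEffects:
    def test_membership_mapping(self):
        memb = (False, False, False, False, False, True, True, False)
        eff = founder_effects(2.0, memb)
        np.testing.assert_allclose(eff, [0, 0, 0, 0, 0, 2.0, 2.0, 0])

    def test_all_carriers_degenerate(self):
        with pytest.raises(ValueError, match="all founders"):
            founder_effects(1.0, (True,) * 8)

    def test_planted_founder_ranking_recovered(self):
        from magicwas.haplo import (build_haploblocks, build_marker_matrix,
                                    call_haplotypes, filter_haplotypes)
        from magicwas.simulate import (PlantedQTL, TraitArchitecture,
                                       funnel_cross, plant_phenotypes)
        from magicwas.phenostats import lsmeans
        from .conftest import make_map, panel_from_strings
        # "ladder" panel: founder i carries the minor allele at the first i
        # SNPs -> one 7-SNP block with all 8 founder haplotypes distinct
        haplos = ["".join("G" if i > k else "A" for k in range(7))
                  for i in range(8)]
        panel = panel_from_strings(haplos, make_map(7, bp_len=200_000))
        blocks, singular = build_haploblocks(panel)
        assert len(blocks) == 1 and len(blocks[0].members) == 7
        planted = np.array([3.0, 2.0, 1.0, 0.5, 0.0, -0.5, -1.0, -2.0])
        rhos = []
        for seed in (61, 62, 63):
            pop = funnel_cross(panel, 500, 4, seed=seed)
            arch = TraitArchitecture(
                trait="T", qtl=[PlantedQTL(pop.map.markers[3], planted)],
                V_G=0.05, V_GE=0.05, V_GT=0.05, V_R=0.2, e=3, t=2)
            pheno = plant_phenotypes(pop, arch, seed=seed + 100)
            hts, assigns = call_haplotypes(blocks, pop, panel)
            matrix = build_marker_matrix(filter_haplotypes(hts), [], pop,
                                         panel, assigns, blocks)
            y = lsmeans(pheno, "T")
            res = step3_scan(matrix.values, y, [])
            est = np.full(8, np.nan)
            for m in matrix.values.columns:
                memb = np.asarray(matrix.founder_membership(m))
                if memb.sum() == 1:  # founder-unique haplotype
                    est[memb] = res.loc[m, "effect"]
            ok = ~np.isnan(est)
            rhos.append(sps.spearmanr(planted[ok], est[ok]).statistic)
        assert np.mean(rhos) >= 0.8


class TestExplainedVariance:
    def test_single_marker_equals_squared_correlation(self):
        X = binary_markers(200, 1, seed=1)
        y = pd.Series(X["m0"].astype(float) * 2
                      + np.random.default_rng(2).normal(size=200),
                      index=X.index)
        r2 = explained_variance(y, X)
        r = np.corrcoef(X["m0"], y)[0, 1]
        assert r2 == pytest.approx(r**2, rel=1e-10)

    def test_duplicated_column_does_not_change_r2(self):
        X = binary_markers(200, 3, seed=3)
        y = pd.Series(np.random.default_rng(4).normal(size=200), index=X.index)
        r2a = explained_variance(y, X)
        X2 = X.copy()
        X2["dup"] = X["m0"]
        assert explained_variance(y, X2) == pytest.approx(r2a, abs=1e-10)

    def test_no_markers_gives_zero(self):
        y = pd.Series([1.0, 2.0], index=["a", "b"])
        assert explained_variance(y, pd.DataFrame(index=["a", "b"])) == 0.0


class TestModelResults:
    def test_fit_summary_and_determinism(self):
        X = binary_markers(300, 200, seed=1)
        rng = np.random.default_rng(2)
        y = pd.Series(2.0 * X.to_numpy(float)[:, 10] + rng.normal(size=300),
                      index=X.index)
        res1 = HaplotypeGWAS(y, X, trait="YLD", scope="N1").fit(seed=5)
        res2 = HaplotypeGWAS(y, X, trait="YLD", scope="N1").fit(seed=5)
        pd.testing.assert_frame_equal(res1.mta, res2.mta)
        assert res1.mta.loc["m10", "significant"]
        assert (res1.mta["BON_p"] >= res1.mta["p_raw"] - 1e-15).all()
        s = res1.summary()
        assert "YLD" in s and "m10" in s
        assert 0 <= res1.explained_variance <= 1
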