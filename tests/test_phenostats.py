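"""LSMEANS, ANOVA, variance components, heritability, correlations, PCA."""

import numpy as np
import pandas as pd
import pytest

from magicwas.phenostats import (VarianceComponents, anova_fixed, descriptives,
                                 heritability, lsmeans, pearson_correlations,
                                 similarity_pca, simple_matching_similarity,
                                 variance_components)
from magicwas.simulate import TraitArchitecture, plant_phenotypes


def balanced_table(n_lines=6, e=2, t=2, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lines):
        for j in range(e):
            for k in range(t):
                rows.append({"line": f"L{i}", "env": f"E{j}",
                             "treatment": ["N0", "N1"][k], "replicate": 1,
                             "trait": "T",
                             "value": i + 0.5 * j + 2.0 * k
                             + sigma * rng.normal()})
    return pd.DataFrame(rows)


class TestLSMeans:
    def test_balanced_equals_plain_mean(self):
        df = balanced_table()
        got = lsmeans(df, "T", "across")
        want = df.groupby("line")["value"].mean()
        pd.testing.assert_series_equal(got, want, check_names=False)

    def test_constant_trait(self):
        df = balanced_table(sigma=0.0)
        df["value"] = 7.0
        got = lsmeans(df, "T", "N0")
        assert (got == 7.0).all()

    def test_unbalanced_matches_normal_equations_oracle(self):
        df = balanced_table(n_lines=4, seed=3)
        df = df.drop(df[(df["line"] == "L0") & (df["env"] == "E1")
                        & (df["treatment"] == "N1")].index)
        got = lsmeans(df, "T", "across")
        # oracle: solve the sum-coded normal equations directly and
        # average predictions over the full env x treatment grid
        lines = sorted(df["line"].unique())
        envs = sorted(df["env"].unique())
        trts = sorted(df["treatment"].unique())

        def row(line, env, trt):
            r = [1.0]
            for lv, levels in ((line, lines), (env, envs), (trt, trts)):
                for cand in levels[:-1]:
                    r.append(1.0 if lv == cand else
                             (-1.0 if lv == levels[-1] else 0.0))
            # env x treatment interaction (sum coded)
            e_code = [1.0 if env == c else (-1.0 if env == envs[-1] else 0.0)
                      for c in envs[:-1]]
            t_code = [1.0 if trt == c else (-1.0 if trt == trts[-1] else 0.0)
                      for c in trts[:-1]]
            for a in e_code:
                for b in t_code:
                    r.append(a * b)
            return r

        A = np.array([row(l, e, t) for l, e, t in
                      zip(df["line"], df["env"], df["treatment"])])
        beta = np.linalg.solve(A.T @ A, A.T @ df["value"].to_numpy())
        for line in lines:
            preds = [np.dot(row(line, e, t), beta)
                     for e in envs for t in trts]
            assert got[line] == pytest.approx(np.mean(preds), abs=1e-8)


class TestAnova:
    def test_large_treatment_shift_significant(self):
        df = balanced_table(n_lines=20, seed=1, sigma=0.5)
        tab = anova_fixed(df, "T")
        assert tab.loc["treatment", "p"] < 0.001

    def test_matches_statsmodels_on_balanced_fixture(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = balanced_table(n_lines=5, seed=2)
        tab = anova_fixed(df, "T")
        m = smf.ols("value ~ C(line) + C(env) + C(treatment) + C(line):C(env)"
                    " + C(line):C(treatment) + C(env):C(treatment)",
                    data=df).fit()
        ref = anova_lm(m, typ=1)
        assert tab.loc["line", "sum_sq"] == pytest.approx(
            ref.loc["C(line)", "sum_sq"])
        assert tab.loc["env:treatment", "sum_sq"] == pytest.approx(
            ref.loc["C(env):C(treatment)", "sum_sq"])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for s in range(60):
            df = balanced_table(n_lines=8, seed=100 + s, sigma=1.0)
            df["value"] = rng.normal(size=len(df))
            ps.append(anova_fixed(df, "T").loc["treatment", "p"])
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_residual_variance_handled(self):
        df = balanced_table(sigma=0.0)
        tab = anova_fixed(df, "T")
        assert np.isinf(tab.loc["line", "F"])
        assert tab.loc["line", "p"] <= np.nextafter(0, 1) * 10


class TestVarianceComponents:
    def test_recovery_on_simulated_design(self, small_panel):
        from magicwas.simulate import funnel_cross
        pop = funnel_cross(small_panel, 800, 4, seed=31)
        truth = {"V_G": 1.0, "V_GE": 0.5, "V_GT": 0.25, "V_R": 1.0}
        acc = {k: [] for k in truth}
        for s in range(5):
            arch = TraitArchitecture(trait="T", e=7, t=2, **truth)
            df = plant_phenotypes(pop, arch, seed=500 + s)
            vc = variance_components(df, "T")
            for k in truth:
                acc[k].append(getattr(vc, k))
        for k, v in truth.items():
            assert np.mean(acc[k]) == pytest.approx(v, rel=0.20)

    def test_label_permutation_destroys_vg(self, small_panel):
        from magicwas.simulate import funnel_cross
        pop = funnel_cross(small_panel, 300, 4, seed=32)
        arch = TraitArchitecture(trait="T", V_G=2.0, V_GE=0.1, V_GT=0.1,
                                 V_R=0.2, e=3, t=2)
        df = plant_phenotypes(pop, arch, seed=33)
        rng = np.random.default_rng(0)
        # permute genotype labels independently within each env x treatment
        df["value"] = df.groupby(["env", "treatment"])["value"].transform(
            lambda v: rng.permutation(v.to_numpy()))
        vc = variance_components(df, "T")
        assert vc.V_G < 0.15 * 2.0

    def test_zero_noise_genotype_only(self):
        df = balanced_table(n_lines=10, sigma=0.0)
        df["value"] = df["line"].str.slice(1).astype(float)
        vc = variance_components(df, "T")
        assert vc.V_G == pytest.approx(np.var(np.arange(10.0), ddof=1))
        assert vc.V_GE == vc.V_GT == vc.V_R == 0.0

    def test_reml_close_to_ems_on_random_effects_fixture(self):
        rng = np.random.default_rng(0)
        nl, e = 40, 3
        g = rng.normal(0, 2.0, nl)
        rows = [{"line": f"L{i}", "env": f"E{j}",
                 "treatment": ["N0", "N1"][k], "replicate": 1, "trait": "T",
                 "value": g[i] + rng.normal(0, 0.7)}
                for i in range(nl) for j in range(e) for k in range(2)]
        df = pd.DataFrame(rows)
        ems = variance_components(df, "T")
        # force the REML path by dropping one record
        reml = variance_components(df.iloc[:-1], "T")
        assert reml.V_G == pytest.approx(ems.V_G, rel=0.1)
        assert reml.V_R == pytest.approx(ems.V_R, rel=0.15)


class TestHeritability:
    def test_noise_free_limit(self):
        vc = VarianceComponents(V_G=3.0, V_GE=0, V_GT=0, V_R=0, e=2, t=2)
        assert heritability(vc) == 1.0

    def test_line_model_closed_form(self):
        vc = VarianceComponents(V_G=1, V_GE=1, V_GT=1, V_R=1, e=7, t=2)
        assert heritability(vc) == pytest.approx(1 / (1 + 1 / 7 + 1 / 2 + 1 / 14))
        assert heritability(vc) == pytest.approx(0.5833, abs=5e-4)

    def test_founder_model_includes_three_way_term(self):
        vc = VarianceComponents(V_G=1, V_GE=1, V_GT=1, V_R=1, V_GET=1,
                                e=7, t=2, r=4)
        want = 1 / (1 + 1 / 7 + 1 / 2 + 1 / 14 + 1 / 56)
        assert heritability(vc, "founder") == pytest.approx(want)

    def test_monotone_in_design_size(self):
        prev = 0.0
        for e in (1, 2, 5, 20, 100):
            vc = VarianceComponents(V_G=1, V_GE=1, V_GT=1, V_R=1, e=e, t=e)
            h = heritability(vc)
            assert h > prev
            prev = h
        assert prev < 1.0

    def test_monotone_in_components(self):
        base = dict(V_GE=1, V_GT=1, V_R=1, e=3, t=2)
        hs = [heritability(VarianceComponents(V_G=v, **base))
              for v in (0.5, 1.0, 2.0)]
        assert hs[0] < hs[1] < hs[2]
        hs = [heritability(VarianceComponents(V_G=1, V_GE=v, V_GT=1, V_R=1,
                                              e=3, t=2)) for v in (0.5, 1, 2)]
        assert hs[0] > hs[1] > hs[2]

    def test_all_zero_components_error(self):
        vc = VarianceComponents(V_G=0, V_GE=0, V_GT=0, V_R=0, e=2, t=2)
        with pytest.raises(ValueError, match="undefined"):
            heritability(vc)


class TestDescriptives:
    @pytest.mark.parametrize("mean, sd, cv", [(75.5, 5.3, 7.0),
                                              (42.1, 3.7, 8.8)])
    def test_cv_from_moments(self, mean, sd, cv):
        # construct a two-point sample with exactly this mean and SD
        x = pd.Series([mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)])
        d = descriptives(x)
        assert d["LSMEAN"] == pytest.approx(mean)
        assert d["SD"] == pytest.approx(sd)
        assert round(d["CV"], 1) == cv

    def test_constant_vector(self):
        d = descriptives(pd.Series([5.0, 5.0, 5.0]))
        assert d["SD"] == 0.0 and d["CV"] == 0.0

    def test_zero_mean_flagged(self):
        with pytest.warns(UserWarning, match="zero mean"):
            d = descriptives(pd.Series([-1.0, 1.0]))
        assert np.isnan(d["CV"])


class TestCorrelations:
    def test_self_and_sign(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"A": x, "B": -x, "C": rng.normal(size=50)})
        r, p = pearson_correlations(df)
        assert r.loc["A", "A"] == 1.0
        assert r.loc["A", "B"] == pytest.approx(-1.0)
        assert abs(r.loc["A", "C"]) < 0.5

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(4)
        n = 800
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        r, _ = pearson_correlations(pd.DataFrame({"X": x, "Y": y}))
        assert r.loc["X", "Y"] == pytest.approx(0.6, abs=0.07)


class TestSimilarityPCA:
    def test_identical_and_disjoint_lines(self):
        g = np.array([["AA", "GG", "CC"],
                      ["AA", "GG", "CC"],
                      ["GG", "AA", "TT"]], dtype="<U2")
        sim = simple_matching_similarity(g)
        assert sim[0, 1] == 1.0
        assert sim[0, 2] == 0.0

    def test_hand_count_oracle_and_eigen_pca(self):
        g = np.array([["AA", "GG", "CC", "TT"],
                      ["AA", "GG", "CT", "TT"],
                      ["AA", "AG", "CC", "NN"],
                      ["GG", "GG", "CC", "TT"],
                      ["AA", "GG", "CC", "TT"]], dtype="<U2")
        sim, coords, var_exp = similarity_pca(g, n_components=3)
        # hand-count: pair (0,1): 3/4; (0,2): 2/3 over shared non-missing
        assert sim[0, 1] == pytest.approx(3 / 4)
        assert sim[0, 2] == pytest.approx(2 / 3)
        assert sim[0, 4] == pytest.approx(1.0)
        # eigen-decomposition oracle for variance explained
        c = sim - sim.mean(axis=0)
        ev = np.linalg.eigvalsh(c.T @ c / (len(sim) - 1))[::-1]
        want = ev[:3] / ev.sum() * 100
        np.testing.assert_allclose(var_exp, want, atol=1e-8)
        assert var_exp.sum() <= 100 + 1e-9

    def test_missing_pair_flagged(self):
        g = np.array([["NN", "AA"], ["GG", "NN"]], dtype="<U2")
        sim = simple_matching_similarity(g)
        assert np.isnan(sim[0, 1])
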