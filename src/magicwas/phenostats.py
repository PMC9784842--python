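"""Trait summaries, LSMEANS, ANOVA, variance components and heritability.

Broad-sense heritability follows the plot-mean convention over ``e``
environments and ``t`` treatments (and ``r`` replicates for the founder
design):

    line model:    h2 = V_G / (V_G + V_GE/e + V_GT/t + V_R/(e t))
    founder model: h2 = V_G / (V_G + V_GE/e + V_GT/t + V_GET/(e t)
                               + V_R/(e t r))

Balanced designs use the expected-mean-squares decomposition in closed
form; unbalanced data fall back to REML (statsmodels MixedLM with
variance-component formulas), which is practical for small designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import MISSING

SCOPES = ("N0", "N1", "across")


@dataclass
class VarianceComponents:
    V_G: float
    V_GE: float
    V_GT: float
    V_R: float
    V_GET: float = 0.0
    e: int = 1
    t: int = 1
    r: int = 1
    truncated: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"V_G": self.V_G, "V_GE": self.V_GE, "V_GT": self.V_GT,
                "V_GET": self.V_GET, "V_R": self.V_R}


def _scope_filter(pheno: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "across":
        return pheno
    if scope not in set(pheno["treatment"]):
        raise ValueError(f"unknown treatment scope {scope!r}")
    return pheno[pheno["treatment"] == scope]


def _is_balanced(df: pd.DataFrame, factors: list[str]) -> bool:
    counts = df.groupby(factors, observed=True).size()
    full = np.prod([df[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


def lsmeans(pheno: pd.DataFrame, trait: str, scope: str = "across") -> pd.Series:
    """Least-squares mean of ``trait`` per line within ``scope``.

    Balanced data reduce to arithmetic cell means.  Unbalanced data are
    fitted with a fixed-effects model (line + environment + treatment +
    environment:treatment) and line means are predictions averaged with
    equal weight over the environment x treatment grid.
    """
    df = _scope_filter(pheno[pheno["trait"] == trait], scope)
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r} in scope {scope!r}")
    factors = ["line", "env"] + (["treatment"] if scope == "across" else [])
    if _is_balanced(df, factors):
        return df.groupby("line")["value"].mean().rename(trait)

    lines = pd.unique(df["line"])
    envs = pd.unique(df["env"])
    trts = pd.unique(df["treatment"])
    dm, cols = _design(df, lines, envs, trts, scope)
    beta, *_ = np.linalg.lstsq(dm, df["value"].to_numpy(float), rcond=None)
    # predict the full line x env (x treatment) grid and average per line
    grid = pd.MultiIndex.from_product(
        [lines, envs, trts] if scope == "across" else [lines, envs],
        names=["line", "env", "treatment"][: 2 + (scope == "across")],
    ).to_frame(index=False)
    if scope != "across":
        grid["treatment"] = scope
    gm, _ = _design(grid, lines, envs, trts, scope, cols)
    pred = gm @ beta
    out = pd.Series(pred, index=grid["line"]).groupby(level=0).mean()
    missing_lines = set(lines) - set(df["line"])
    if missing_lines:
        warnings.warn(f"lines with no data in scope {scope!r}: {sorted(missing_lines)[:5]}")
    return out.reindex(lines).rename(trait)


def _design(df, lines, envs, trts, scope, cols=None):
    """Sum-coded fixed-effects design: intercept + line + env (+ treatment
    + env:treatment in the across scope)."""
    def sum_code(values, levels):
        k = len(levels)
        pos = pd.Categorical(values, categories=levels).codes
        out = np.zeros((len(values), k - 1))
        for j in range(k - 1):
            out[pos == j, j] = 1.0
        out[pos == k - 1, :] = -1.0
        return out

    parts = [np.ones((len(df), 1)), sum_code(df["line"], lines),
             sum_code(df["env"], envs)]
    if scope == "across" and len(trts) > 1:
        t = sum_code(df["treatment"], trts)
        e = sum_code(df["env"], envs)
        parts.append(t)
        parts.append(np.einsum("ij,ik->ijk", e, t).reshape(len(df), -1))
    dm = np.hstack(parts)
    return dm, None


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_fixed(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Sequential (type-I) ANOVA with fixed genotype, environment and
    treatment main effects plus all two-way interactions.

    Balanced designs use the classical closed-form decomposition;
    unbalanced data go through statsmodels OLS + anova_lm.  Returns a
    table with df, sum_sq, F, p and significance stars.
    """
    df = pheno[pheno["trait"] == trait].copy()
    levels = {f: df[f].nunique() for f in ("line", "env", "treatment")}
    factors = [f for f, k in levels.items() if k >= 2]
    skipped = [f for f, k in levels.items() if k < 2]
    for f in skipped:
        warnings.warn(f"factor {f!r} has a single level; skipped in ANOVA")
    if len(factors) < 1:
        raise ValueError("no factor with >= 2 levels")

    if _is_balanced(df, factors):
        return _anova_balanced(df, factors)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    terms = [f"C({f})" for f in factors]
    terms += [f"C({a}):C({b})" for i, a in enumerate(factors)
              for b in factors[i + 1:]]
    model = smf.ols("value ~ " + " + ".join(terms), data=df).fit()
    tab = anova_lm(model, typ=1).rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    tab["stars"] = [_stars(p) if np.isfinite(p) else "" for p in tab["p"]]
    return tab


def _anova_balanced(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    y = df["value"].to_numpy(float)
    n = len(y)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    rows = {}
    ss_model = 0.0
    df_model = 0
    for f in factors:
        means = df.groupby(f)["value"].mean()
        counts = df.groupby(f)["value"].size()
        ss = float((counts * (means - grand) ** 2).sum())
        rows[f] = {"df": len(means) - 1, "sum_sq": ss}
        ss_model += ss
        df_model += len(means) - 1
    for i, a in enumerate(factors):
        for b in factors[i + 1:]:
            cell = df.groupby([a, b])["value"].agg(["mean", "size"])
            ma = df.groupby(a)["value"].mean()
            mb = df.groupby(b)["value"].mean()
            dev = (cell["mean"]
                   - cell.index.get_level_values(a).map(ma)
                   - cell.index.get_level_values(b).map(mb) + grand)
            ss = float((cell["size"] * dev**2).sum())
            d = (len(ma) - 1) * (len(mb) - 1)
            rows[f"{a}:{b}"] = {"df": d, "sum_sq": ss}
            ss_model += ss
            df_model += d
    df_res = n - 1 - df_model
    ss_res = max(sst - ss_model, 0.0)
    ms_res = ss_res / df_res if df_res > 0 else 0.0
    out = []
    for name, row in rows.items():
        ms = row["sum_sq"] / row["df"] if row["df"] else np.nan
        if ms_res > 0:
            F = ms / ms_res
            p = float(sps.f.sf(F, row["df"], df_res))
        else:  # zero residual variance: effect either absent or infinite
            F = np.inf if row["sum_sq"] > 0 else 0.0
            p = np.nextafter(0, 1) if row["sum_sq"] > 0 else 1.0
        out.append({"term": name, "df": row["df"], "sum_sq": row["sum_sq"],
                    "F": F, "p": p, "stars": _stars(p)})
    out.append({"term": "Residual", "df": df_res, "sum_sq": ss_res,
                "F": np.nan, "p": np.nan, "stars": ""})
    return pd.DataFrame(out).set_index("term")


def variance_components(
    pheno: pd.DataFrame, trait: str, model: str = "line"
) -> VarianceComponents:
    """Estimate V_G, V_GE, V_GT (V_GET, founder model) and V_R for one trait.

    ``model='line'`` assumes one observation per line x environment x
    treatment (the three-way interaction is confounded with the residual);
    ``model='founder'`` requires replicates and separates V_GET from V_R.
    Balanced data use expected mean squares; unbalanced use REML.
    Negative estimates are truncated to zero and flagged.
    """
    df = pheno[pheno["trait"] == trait]
    if df.empty:
        raise ValueError(f"no data for trait {trait!r}")
    e = df["env"].nunique()
    t = df["treatment"].nunique()
    r = int(df.groupby(["line", "env", "treatment"], observed=True).size().max())
    if model == "founder" and r < 2:
        raise ValueError("founder model needs replicates to separate V_GET")
    factors = ["line", "env", "treatment"]
    if _is_balanced(df, factors):
        comps = _ems_components(df, e, t, r, with_get=(model == "founder"))
    else:
        comps = _reml_components(df, with_get=(model == "founder"))
    truncated = tuple(k for k, v in comps.items() if v < 0)
    comps = {k: max(v, 0.0) for k, v in comps.items()}
    return VarianceComponents(V_G=comps["V_G"], V_GE=comps["V_GE"],
                              V_GT=comps["V_GT"], V_GET=comps.get("V_GET", 0.0),
                              V_R=comps["V_R"], e=e, t=t, r=r,
                              truncated=truncated)


def _mean_squares(df: pd.DataFrame) -> dict[str, float]:
    """Sequential mean squares of the balanced G x E x T classification
    computed on cell means."""
    cell = df.groupby(["line", "env", "treatment"], observed=True)["value"].mean()
    wide = cell.unstack(["env", "treatment"])
    a, bc = wide.shape
    y = wide.to_numpy(float)
    grand = y.mean()
    g_mean = y.mean(axis=1)
    env_levels = wide.columns.get_level_values("env")
    trt_levels = wide.columns.get_level_values("treatment")
    e = env_levels.nunique()
    t = trt_levels.nunique()
    e_mean = {lv: y[:, env_levels == lv].mean() for lv in env_levels.unique()}
    t_mean = {lv: y[:, trt_levels == lv].mean() for lv in trt_levels.unique()}
    ge_mean = {lv: y[:, env_levels == lv].mean(axis=1) for lv in e_mean}
    gt_mean = {lv: y[:, trt_levels == lv].mean(axis=1) for lv in t_mean}
    et_mean = y.mean(axis=0)

    ss_g = e * t * float(((g_mean - grand) ** 2).sum())
    ss_e = a * t * float(sum((m - grand) ** 2 for m in e_mean.values()))
    ss_t = a * e * float(sum((m - grand) ** 2 for m in t_mean.values()))
    ss_ge = t * float(sum(
        ((ge_mean[lv] - g_mean - e_mean[lv] + grand) ** 2).sum()
        for lv in e_mean))
    ss_gt = e * float(sum(
        ((gt_mean[lv] - g_mean - t_mean[lv] + grand) ** 2).sum()
        for lv in t_mean))
    ss_et = a * float(sum(
        (et_mean[k] - e_mean[env_levels[k]] - t_mean[trt_levels[k]] + grand) ** 2
        for k in range(bc)))
    ss_tot_cells = float(((y - grand) ** 2).sum())
    ss_get = ss_tot_cells - ss_g - ss_e - ss_t - ss_ge - ss_gt - ss_et
    return {
        "MS_G": ss_g / (a - 1),
        "MS_GE": ss_ge / ((a - 1) * (e - 1)) if e > 1 else np.nan,
        "MS_GT": ss_gt / ((a - 1) * (t - 1)) if t > 1 else np.nan,
        "MS_GET": (ss_get / ((a - 1) * (e - 1) * (t - 1))
                   if e > 1 and t > 1 else np.nan),
        "a": a, "e": e, "t": t,
    }


def _ems_components(df: pd.DataFrame, e: int, t: int, r: int,
                    with_get: bool) -> dict[str, float]:
    ms = _mean_squares(df)
    if r > 1:
        cell = df.groupby(["line", "env", "treatment"], observed=True)["value"]
        ss_within = float((cell.var(ddof=1) * (cell.size() - 1)).sum())
        df_within = int((cell.size() - 1).sum())
        ms_within = ss_within / df_within
    else:
        ms_within = np.nan
    if with_get:
        v_r = ms_within
        v_get = (ms["MS_GET"] - ms_within) / r
        v_gt = (ms["MS_GT"] - ms["MS_GET"]) / (e * r)
        v_ge = (ms["MS_GE"] - ms["MS_GET"]) / (t * r)
        v_g = (ms["MS_G"] - ms["MS_GE"] - ms["MS_GT"] + ms["MS_GET"]) / (e * t * r)
        return {"V_G": v_g, "V_GE": v_ge, "V_GT": v_gt, "V_GET": v_get, "V_R": v_r}
    # line model: GET confounded with residual (cell means, r handled upstream)
    v_r = ms["MS_GET"]
    v_ge = (ms["MS_GE"] - v_r) / t
    v_gt = (ms["MS_GT"] - v_r) / e
    v_g = (ms["MS_G"] - ms["MS_GE"] - ms["MS_GT"] + v_r) / (e * t)
    return {"V_G": v_g, "V_GE": v_ge, "V_GT": v_gt, "V_R": v_r}


def _reml_components(df: pd.DataFrame, with_get: bool) -> dict[str, float]:
    """REML variance components via MixedLM with one grouping super-level.
    Practical for small unbalanced designs only."""
    import statsmodels.formula.api as smf
    d = df.copy()
    d["_one"] = 1
    vcf = {"G": "0 + C(line)", "GE": "0 + C(line):C(env)",
           "GT": "0 + C(line):C(treatment)"}
    if with_get:
        vcf["GET"] = "0 + C(line):C(env):C(treatment)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = smf.mixedlm("value ~ C(env) + C(treatment)", data=d,
                        groups="_one", vc_formula=vcf).fit(reml=True)
    out = {"V_G": float(m.vcomp[list(vcf).index("G")]),
           "V_GE": float(m.vcomp[list(vcf).index("GE")]),
           "V_GT": float(m.vcomp[list(vcf).index("GT")]),
           "V_R": float(m.scale)}
    if with_get:
        out["V_GET"] = float(m.vcomp[list(vcf).index("GET")])
    return out


def heritability(vc: VarianceComponents, model: str = "line") -> float:
    """Broad-sense heritability on a genotype-mean basis; in [0, 1]."""
    e, t, r = vc.e, vc.t, vc.r
    if min(e, t) < 1 or (model == "founder" and r < 1):
        raise ValueError("design counts must be >= 1")
    if model == "founder":
        denom = vc.V_G + vc.V_GE / e + vc.V_GT / t + vc.V_GET / (e * t) \
            + vc.V_R / (e * t * r)
    else:
        denom = vc.V_G + vc.V_GE / e + vc.V_GT / t + vc.V_R / (e * t)
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return vc.V_G / denom


def descriptives(lsm: pd.Series) -> dict[str, float]:
    """Table-1-style summary of per-line LSMEANS: mean, SD, min, max, n
    and CV (%) = SD / mean x 100."""
    x = lsm.dropna().to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = np.nan if mean == 0 else sd / mean * 100
    if mean == 0:
        warnings.warn("zero mean: CV undefined")
    return {"LSMEAN": mean, "SD": sd, "min": float(x.min()),
            "max": float(x.max()), "n": len(x), "CV": cv}


def pearson_correlations(lsm_by_trait: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r between trait LSMEANS with two-sided p-values.

    Returns (r, p); zero-variance traits give NaN with a warning.
    """
    traits = list(lsm_by_trait.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            sub = lsm_by_trait[[traits[i], traits[j]]].dropna()
            if len(sub) < 3:
                raise ValueError("need >= 3 paired observations")
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero-variance trait in pair ({traits[i]}, {traits[j]})")
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def simple_matching_similarity(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise fraction of identical genotype calls over shared
    non-missing SNPs; symmetric with unit diagonal."""
    g = np.ascontiguousarray(genotypes)
    n, m = g.shape
    ok = (g != MISSING)
    codes = np.zeros((n, m), dtype=np.int32)
    for j in range(m):
        _, codes[:, j] = np.unique(g[:, j], return_inverse=True)
    n_codes = int(codes.max()) + 1
    onehot = np.zeros((n, m * n_codes), dtype=np.float32)
    rows = np.repeat(np.arange(n), m)
    cols = (np.arange(m)[None, :] * n_codes + codes).ravel()
    keep = ok.ravel()
    onehot[rows[keep], cols[keep]] = 1.0
    matches = onehot @ onehot.T
    shared = ok.astype(np.float32) @ ok.astype(np.float32).T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = matches / shared
    np.fill_diagonal(sim, 1.0)
    return sim.astype(float)


def similarity_pca(genotypes: np.ndarray, n_components: int = 10):
    """Simple-matching similarity matrix + PCA of its rows.

    Returns (similarity, coordinates, variance_explained_percent).
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    from sklearn.decomposition import PCA
    sim = simple_matching_similarity(genotypes)
    k = min(n_components, sim.shape[0] - 1)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(sim)
    return sim, coords, pca.explained_variance_ratio_ * 100
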