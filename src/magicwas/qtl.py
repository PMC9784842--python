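"""MTA-to-QTL merging, treatment classification, pleiotropy and yield
prediction.

Significant marker-trait associations of the same trait on the same
chromosome are merged into one QTL when they are in LD (r^2 >= 0.8) or
within 5 cM (single-linkage closure of the pairwise rule).  QTL are
classified by the treatment scopes (N0, N1, across) in which they are
significant; loci of different traits within a 5 cM window are reported
as pleiotropic.  Yield prediction pools significant yield-QTL marker
columns with component-trait LSMEANS through SBC-forward stepwise OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd

from .gwas import CofactorSet, _fit_ols, step2_sbc_cofactors

SCOPES = ("N0", "N1", "across")


def round1(x: float) -> float:
    """One-decimal, half-up rounding (table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class QTL:
    id: str
    trait: str
    chrom: str
    cm_span: tuple[float, float]
    members: list[str]                  # marker ids of merged MTAs
    scopes: tuple[str, ...]             # scopes with a significant member
    best_marker: str
    best_bon_p: float
    best_effect: float

    @property
    def unique_scope(self) -> str | None:
        return self.scopes[0] if len(self.scopes) == 1 else None

    @property
    def position(self) -> float:
        return 0.5 * (self.cm_span[0] + self.cm_span[1])


@dataclass
class PleiotropicLocus:
    chrom: str
    anchor_cm: float
    traits: tuple[str, ...]
    members: list[str]                  # QTL ids


def merge_mtas(
    mtas: pd.DataFrame,
    ld_r2: pd.DataFrame | None = None,
    r2_min: float = 0.8,
    cm_window: float = 5.0,
) -> list[QTL]:
    """Merge significant MTAs into QTL.

    ``mtas`` needs columns trait, scope, chrom, cM, effect, BON_p and is
    indexed by marker id (marker x scope rows share the index).  Two
    same-trait, same-chromosome markers link when LD r^2 >= ``r2_min``
    or |delta cM| < ``cm_window``; QTL are the single-linkage clusters.
    MTAs without a map position are reported unmerged (one QTL each).
    """
    if mtas.empty:
        return []
    qtls: list[QTL] = []
    name_counter: dict[tuple[str, str], list] = {}
    for (trait, chrom), sub in mtas.groupby(["trait", "chrom"], sort=True):
        markers = list(dict.fromkeys(sub.index))
        g = nx.Graph()
        g.add_nodes_from(markers)
        pos = {m: float(sub.loc[[m], "cM"].iloc[0]) for m in markers}
        for i, a in enumerate(markers):
            for b in markers[i + 1:]:
                linked = abs(pos[a] - pos[b]) < cm_window
                if not linked and ld_r2 is not None \
                        and a in ld_r2.index and b in ld_r2.columns:
                    linked = bool(ld_r2.loc[a, b] >= r2_min)
                if linked:
                    g.add_edge(a, b)
        clusters = sorted(
            (sorted(c, key=lambda m: (pos[m], m)) for c in nx.connected_components(g)),
            key=lambda c: pos[c[0]],
        )
        name_counter.setdefault((trait, chrom), [])
        for cluster in clusters:
            rows = sub.loc[sub.index.isin(cluster)]
            scopes = tuple(s for s in SCOPES if s in set(rows["scope"]))
            best = rows.sort_values("BON_p").iloc[0]
            cms = [pos[m] for m in cluster]
            name_counter[(trait, chrom)].append(cluster)
            k = len(name_counter[(trait, chrom)])
            suffix = "" if k == 1 else f".{chr(ord('a') + k - 2)}"
            qtls.append(QTL(
                id=f"Q{trait}_{chrom}{suffix}",
                trait=trait, chrom=str(chrom),
                cm_span=(min(cms), max(cms)),
                members=cluster, scopes=scopes,
                best_marker=str(best.name), best_bon_p=float(best["BON_p"]),
                best_effect=float(best["effect"]),
            ))
    return qtls


def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    rows = [{
        "qtl": q.id, "trait": q.trait, "chrom": q.chrom,
        "cm_start": q.cm_span[0], "cm_end": q.cm_span[1],
        "n_mta": len(q.members), "scopes": "+".join(q.scopes),
        "unique_scope": q.unique_scope or "",
        "best_marker": q.best_marker, "best_BON_p": q.best_bon_p,
        "best_effect": q.best_effect,
    } for q in qtls]
    return pd.DataFrame(rows)


def classify_scopes(qtls: list[QTL], mtas: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Per-trait accounting: MTA and QTL counts per scope, unique-scope
    counts and the percent of QTL unique to a single N treatment."""
    traits = sorted({q.trait for q in qtls})
    if not traits:
        cols = ["n_QTL"] + [f"{p}_{s}" for s in SCOPES
                            for p in ("QTL", "unique")]
        out = pd.DataFrame([[0] * len(cols)], index=pd.Index(["total"]),
                           columns=cols)
        return out
    rows = []
    for trait in traits:
        qs = [q for q in qtls if q.trait == trait]
        row = {"trait": trait, "n_QTL": len(qs)}
        for s in SCOPES:
            row[f"QTL_{s}"] = sum(1 for q in qs if s in q.scopes)
            row[f"unique_{s}"] = sum(1 for q in qs if q.scopes == (s,))
            if mtas is not None:
                sub = mtas[(mtas["trait"] == trait) & (mtas["scope"] == s)]
                row[f"MTA_{s}"] = len(sub)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("trait")
    total = out.sum(axis=0)
    total.name = "total"
    out = pd.concat([out, total.to_frame().T])
    n_qtl = int(out.loc["total", "n_QTL"])
    if n_qtl:
        uniq_nt = int(out.loc["total", "unique_N0"] + out.loc["total", "unique_N1"])
        out.loc["total", "pct_single_treatment_unique"] = round1(
            100.0 * uniq_nt / n_qtl)
    return out


def pleiotropy_scan(qtls: list[QTL], cm_window: float = 5.0
                    ) -> list[PleiotropicLocus]:
    """Group QTL of different traits within ``cm_window`` cM on the same
    chromosome into pleiotropic loci (single linkage; >= 2 traits)."""
    loci: list[PleiotropicLocus] = []
    by_chrom: dict[str, list[QTL]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom, qs in sorted(by_chrom.items()):
        g = nx.Graph()
        g.add_nodes_from(range(len(qs)))
        for i in range(len(qs)):
            for j in range(i + 1, len(qs)):
                if qs[i].trait != qs[j].trait \
                        and abs(qs[i].position - qs[j].position) < cm_window:
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            traits = sorted({qs[i].trait for i in comp})
            if len(traits) < 2:
                continue
            members = sorted(qs[i].id for i in comp)
            anchor = float(np.mean([qs[i].position for i in comp]))
            loci.append(PleiotropicLocus(chrom, anchor, tuple(traits), members))
    loci.sort(key=lambda p: (p.chrom, p.anchor_cm))
    return loci


@dataclass
class PredictionModel:
    """SBC-selected yield-prediction model plus a markers-only companion."""

    scope: str
    selected: list[str]
    coefficients: pd.Series
    r2: float
    markers_only_selected: list[str] = field(default_factory=list)
    markers_only_r2: float = 0.0
    fitted: pd.DataFrame | None = None   # actual vs predicted per line

    def summary(self) -> str:
        sel = ", ".join(self.selected) or "(intercept only)"
        return (f"Yield prediction [{self.scope}]: R2 = {self.r2:.3f} "
                f"({len(self.selected)} predictors: {sel}); "
                f"markers-only R2 = {self.markers_only_r2:.3f}")


def _sbc_ols(y: pd.Series, X: pd.DataFrame) -> tuple[list[str], pd.Series, float,
                                                     pd.DataFrame]:
    chosen = step2_sbc_cofactors(X, y).markers
    common = y.dropna().index.intersection(X.index)
    A = np.column_stack([np.ones(len(common)), X.loc[common, chosen].to_numpy(float)])
    yv = y.loc[common].to_numpy(float)
    beta = _fit_ols(A, yv)
    pred = A @ beta
    sst = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float(((yv - pred) ** 2).sum()) / sst if sst > 0 else 0.0
    coef = pd.Series(beta, index=["intercept"] + chosen)
    fitted = pd.DataFrame({"actual": yv, "predicted": pred}, index=common)
    return chosen, coef, r2, fitted


def predict_yield(
    y: pd.Series,
    qtl_markers: pd.DataFrame,
    components: pd.DataFrame | None = None,
    scope: str = "across",
) -> PredictionModel:
    """SBC-forward stepwise yield prediction from significant yield-QTL
    marker columns pooled with component-trait LSMEANS; also fits the
    markers-only model for comparison."""
    pool = qtl_markers if components is None else qtl_markers.join(components,
                                                                   how="inner")
    sel, coef, r2, fitted = _sbc_ols(y, pool)
    sel_m, _, r2_m, _ = _sbc_ols(y, qtl_markers)
    return PredictionModel(scope, sel, coef, r2, sel_m, r2_m, fitted)


def transgression_report(line_means: pd.Series, founder_means: pd.Series) -> dict:
    """Best line vs best founder: absolute and percent gain (one decimal)
    and the count of lines exceeding the best founder."""
    if line_means.dropna().empty or founder_means.dropna().empty:
        raise ValueError("empty input")
    best_line = line_means.idxmax()
    best_founder = founder_means.idxmax()
    gain = float(line_means.max() - founder_means.max())
    pct = round1(gain / float(founder_means.max()) * 100)
    return {
        "best_line": best_line,
        "best_line_value": float(line_means.max()),
        "best_founder": best_founder,
        "best_founder_value": float(founder_means.max()),
        "gain": gain,
        "gain_pct": pct,
        "n_lines_exceeding": int((line_means > founder_means.max()).sum()),
    }
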