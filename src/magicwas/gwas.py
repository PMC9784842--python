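"""Three-step cofactor-conditioned GWAS for presence/absence markers.

The procedure mirrors the cross-validated stepwise pipeline used for
multi-parent wheat populations:

1. *Screening*: 100 random 80/20 splits; on each, stepwise
   forward/backward OLS keeps a marker move only if it lowers the
   validation-set mean squared prediction error (ASE).  Markers
   appearing in more than one terminal model are "robust".
2. *Cofactor selection*: one forward-stepwise OLS on the full data over
   the robust set, minimizing the Schwarz Bayesian Criterion
   SBC = n ln(SSE/n) + k ln(n) (k counts the intercept).
3. *Scan*: every marker is tested by OLS with the selected cofactors in
   the background (a cofactor is tested with itself removed).  Effects,
   sequential (type-I) partial R^2 and p-values are reported and
   Bonferroni-Holm adjusted over all markers; significance at
   BON_p < 0.05.

Founder effects attach the carrier effect to each founder carrying the
marker allele (non-carriers at the zero baseline).

Exposed statsmodels-style: ``HaplotypeGWAS(y, markers).fit(seed=...)``
returns a :class:`GWASResults` with the MTA table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .haplo import MarkerMatrix

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# step 1: cross-validated screening


@dataclass
class SelectionTrace:
    """Audit trail of the screening step."""

    inclusion_count: pd.Series          # per marker, over n_reps
    selected_sets: list[list[str]]      # per repetition, terminal model
    ase_paths: list[list[float]]        # per repetition, accepted-move ASEs
    n_reps: int

    def robust(self, min_count: int = 2) -> list[str]:
        """Markers included in at least ``min_count`` of the terminal models
        ("more than one out of 100")."""
        s = self.inclusion_count
        return list(s.index[s >= min_count])


def _ase(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((y - pred) ** 2))


def _fit_ols(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _val_ase(Xtr: np.ndarray, ytr: np.ndarray, Xval: np.ndarray,
             yval: np.ndarray, cols: list[int]) -> float:
    A = np.column_stack([np.ones(len(ytr)), Xtr[:, cols]])
    beta = _fit_ols(A, ytr)
    Av = np.column_stack([np.ones(len(yval)), Xval[:, cols]])
    return _ase(Av @ beta, yval)


def _stepwise_split(
    Xtr: np.ndarray, ytr: np.ndarray, Xval: np.ndarray, yval: np.ndarray,
) -> tuple[list[int], list[float]]:
    """Forward/backward stepwise on one split.

    The candidate path is driven by the training fit (the marker with the
    largest residual sum-of-squares reduction enters; the weakest
    contributor is the removal candidate) and a move is accepted only if
    it decreases the validation-set ASE; the sweep stops at the first
    rejected move.  Ties break on the smaller column index.
    """
    n, M = Xtr.shape
    selected: list[int] = []
    best = _ase(np.full(len(yval), ytr.mean()), yval)
    path = [best]
    # residuals of markers and y against [1, X_selected], kept orthogonalized
    RX = Xtr - Xtr.mean(axis=0)
    r = ytr - ytr.mean()
    nx2 = (RX * RX).sum(axis=0)
    while True:
        moved = False
        # forward: best training-SS-reduction candidate
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (RX.T @ r) ** 2 / nx2
        score[nx2 < _RANK_TOL * n] = -np.inf
        if selected:
            score[np.asarray(selected)] = -np.inf
        j = int(np.argmax(score))
        if np.isfinite(score[j]) and score[j] > 0:
            trial = selected + [j]
            ase_new = _val_ase(Xtr, ytr, Xval, yval, trial)
            if ase_new < best:
                selected = trial
                best = ase_new
                path.append(best)
                q = RX[:, j] / np.sqrt(nx2[j])
                RX = RX - np.outer(q, q @ RX)
                r = r - q * (q @ r)
                nx2 = (RX * RX).sum(axis=0)
                moved = True
        # backward: weakest training contributor, accepted on ASE decrease
        while len(selected) > 1:
            A = np.column_stack([np.ones(n), Xtr[:, selected]])
            beta = _fit_ols(A, ytr)
            resid = ytr - A @ beta
            sse = float(resid @ resid)
            losses = []
            for pos in range(len(selected)):
                keep = selected[:pos] + selected[pos + 1:]
                Ak = np.column_stack([np.ones(n), Xtr[:, keep]])
                bk = _fit_ols(Ak, ytr)
                rk = ytr - Ak @ bk
                losses.append(float(rk @ rk) - sse)
            pos = int(np.argmin(losses))
            keep = selected[:pos] + selected[pos + 1:]
            ase_new = _val_ase(Xtr, ytr, Xval, yval, keep)
            if ase_new < best:
                selected = keep
                best = ase_new
                path.append(best)
                A1 = np.column_stack([np.ones(n), Xtr[:, selected]])
                Q, _ = np.linalg.qr(A1)
                RX = Xtr - Q @ (Q.T @ Xtr)
                r = ytr - Q @ (Q.T @ ytr)
                nx2 = (RX * RX).sum(axis=0)
                moved = True
            else:
                break
        if not moved:
            return selected, path


def step1_cv_screen(
    markers: pd.DataFrame,
    y: pd.Series,
    n_reps: int = 100,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> SelectionTrace:
    """Repeated cross-validated stepwise screening of markers.

    Each repetition assigns ``train_frac`` of lines to the prediction
    set and the rest to the validation set, then runs forward/backward
    stepwise OLS accepting only moves that decrease the validation ASE.
    """
    common = y.dropna().index.intersection(markers.index)
    X = markers.loc[common].to_numpy(float)
    yv = y.loc[common].to_numpy(float)
    n = len(common)
    n_val = n - int(round(n * train_frac))
    if n_val < 1:
        raise ValueError(
            f"too few lines ({n}) for a {1 - train_frac:.0%} validation split")
    rng = np.random.default_rng(seed)
    counts = np.zeros(markers.shape[1], dtype=int)
    sets, paths = [], []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        sel, path = _stepwise_split(X[tr_idx], yv[tr_idx], X[val_idx], yv[val_idx])
        counts[sel] += 1
        sets.append([markers.columns[j] for j in sorted(sel)])
        paths.append(path)
    inclusion = pd.Series(counts, index=markers.columns, name="inclusion_count")
    return SelectionTrace(inclusion, sets, paths, n_reps)


# ---------------------------------------------------------------------------
# step 2: SBC cofactor selection


def sbc(n: int, sse: float, k: int) -> float:
    """Schwarz Bayesian Criterion, n ln(SSE/n) + k ln(n); k includes the
    intercept."""
    if sse <= 0:
        return -np.inf
    return n * np.log(sse / n) + k * np.log(n)


@dataclass
class CofactorSet:
    markers: list[str]                  # entry order
    sbc_path: list[float]               # starts at the intercept-only SBC

    def __len__(self) -> int:
        return len(self.markers)


def step2_sbc_cofactors(robust: pd.DataFrame, y: pd.Series) -> CofactorSet:
    """Forward stepwise over the robust markers on the full data,
    entering the marker with the largest strict SBC decrease each round."""
    common = y.dropna().index.intersection(robust.index)
    X = robust.loc[common].to_numpy(float)
    yv = y.loc[common].to_numpy(float)
    n = len(common)
    selected: list[int] = []
    sse0 = float(((yv - yv.mean()) ** 2).sum())
    path = [sbc(n, sse0, 1)]
    while len(selected) < X.shape[1]:
        best_j, best_sbc = None, path[-1]
        for j in range(X.shape[1]):
            if j in selected:
                continue
            A = np.column_stack([np.ones(n), X[:, selected + [j]]])
            if np.linalg.matrix_rank(A, tol=_RANK_TOL * n) < A.shape[1]:
                continue  # perfectly redundant with the current model
            beta = _fit_ols(A, yv)
            sse = float(((yv - A @ beta) ** 2).sum())
            val = sbc(n, sse, A.shape[1])
            if val < best_sbc - 1e-12:  # strict decrease; ties keep smaller j
                best_j, best_sbc = j, val
        if best_j is None:
            break
        selected.append(best_j)
        path.append(best_sbc)
    return CofactorSet([robust.columns[j] for j in selected], path)


# ---------------------------------------------------------------------------
# step 3: conditioned scan + Holm


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


def _scan_background(
    X: np.ndarray, yv: np.ndarray, bg_cols: list[int], test_cols: np.ndarray,
) -> pd.DataFrame:
    """Test each column in ``test_cols`` conditioned on ``bg_cols``."""
    n = len(yv)
    A = np.column_stack([np.ones(n), X[:, bg_cols]])
    Q, _ = np.linalg.qr(A)
    rank = int(np.linalg.matrix_rank(A, tol=_RANK_TOL * n))
    ry = yv - Q @ (Q.T @ yv)
    sse_red = float(ry @ ry)
    sst = float(((yv - yv.mean()) ** 2).sum())
    Xc = X[:, test_cols]
    RX = Xc - Q @ (Q.T @ Xc)
    nx2 = (RX * RX).sum(axis=0)
    xy = RX.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = xy / nx2
    ss_marker = slope * xy
    df_full = n - rank - 1
    sse_full = np.maximum(sse_red - ss_marker, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_marker / (sse_full / df_full)
    p = sps.f.sf(F, 1, df_full)
    bad = nx2 < _RANK_TOL * n
    slope = np.where(bad, np.nan, slope)
    p = np.where(bad, 1.0, p)
    ss_marker = np.where(bad, 0.0, ss_marker)
    return pd.DataFrame({
        "effect": slope,
        "partial_R2": ss_marker / sst if sst > 0 else 0.0,
        "p_raw": np.clip(p, 0.0, 1.0),
        "estimable": ~bad,
    })


def step3_scan(
    markers: pd.DataFrame, y: pd.Series, cofactors: CofactorSet | list[str],
) -> pd.DataFrame:
    """Per-marker OLS with the cofactors in the background.

    The marker's effect is its coefficient in [intercept, cofactors,
    marker]; partial R^2 is the sequential (type-I) share of the total
    sum of squares; p is the sequential F-test.  A marker that is itself
    a cofactor takes its sequential term test: it is conditioned only on
    the cofactors that entered the model before it (its own entry rank),
    never on itself or on later entries.  Markers collinear with the
    background get effect = NaN, p = 1, estimable = False.
    """
    cof = cofactors.markers if isinstance(cofactors, CofactorSet) else list(cofactors)
    common = y.dropna().index.intersection(markers.index)
    X = markers.loc[common].to_numpy(float)
    yv = y.loc[common].to_numpy(float)
    col_of = {m: j for j, m in enumerate(markers.columns)}
    cof_idx = [col_of[m] for m in cof]
    non_cof = np.array([j for j in range(X.shape[1]) if j not in set(cof_idx)],
                       dtype=int)
    frames = []
    if len(non_cof):
        res = _scan_background(X, yv, cof_idx, non_cof)
        res.index = markers.columns[non_cof]
        frames.append(res)
    for rank, m in enumerate(cof):
        bg = [col_of[c] for c in cof[:rank]]
        res = _scan_background(X, yv, bg, np.array([col_of[m]]))
        res.index = pd.Index([m])
        frames.append(res)
    out = pd.concat(frames).loc[markers.columns]
    out.index.name = "marker"
    return out


def founder_effects(effect: float, membership: tuple[bool, ...]) -> np.ndarray:
    """Per-founder effect vector: carriers get the marker effect,
    non-carriers the zero baseline."""
    memb = np.asarray(membership, bool)
    if memb.all():
        raise ValueError("marker carried by all founders: contrast undefined")
    return np.where(memb, float(effect), 0.0)


def explained_variance(y: pd.Series, significant: pd.DataFrame) -> float:
    """R^2 of the joint OLS of the trait on all significant markers."""
    if significant.shape[1] == 0:
        return 0.0
    common = y.dropna().index.intersection(significant.index)
    X = np.column_stack([np.ones(len(common)),
                         significant.loc[common].to_numpy(float)])
    yv = y.loc[common].to_numpy(float)
    beta = _fit_ols(X, yv)
    sse = float(((yv - X @ beta) ** 2).sum())
    sst = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0


# ---------------------------------------------------------------------------
# model / results


class HaplotypeGWAS:
    """Three-step haplotype GWAS model for one trait and scope.

    Parameters
    ----------
    y : per-line trait LSMEANS (index = line names).
    markers : MarkerMatrix or a 0/1 DataFrame (lines x markers).
    trait, scope : labels carried into the results.
    """

    def __init__(self, y: pd.Series, markers: MarkerMatrix | pd.DataFrame,
                 trait: str = "trait", scope: str = "across"):
        if isinstance(markers, MarkerMatrix):
            self._matrix = markers
            self.exog = markers.values
        else:
            self._matrix = None
            self.exog = markers
        self.endog = y
        self.trait = trait
        self.scope = scope

    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, markers, trait: str,
                       scope: str = "across") -> "HaplotypeGWAS":
        """Build from a long-format phenotype table by computing LSMEANS."""
        from .phenostats import lsmeans
        return cls(lsmeans(pheno, trait, scope), markers, trait, scope)

    def fit(self, n_reps: int = 100, train_frac: float = 0.8,
            seed: int | None = None, inclusion_min: int = 2,
            alpha: float = 0.05) -> "GWASResults":
        trace = step1_cv_screen(self.exog, self.endog, n_reps=n_reps,
                                train_frac=train_frac, seed=seed)
        robust = trace.robust(inclusion_min)
        cof = step2_sbc_cofactors(self.exog[robust], self.endog)
        mta = step3_scan(self.exog, self.endog, cof)
        mta["BON_p"] = holm_adjust(mta["p_raw"].to_numpy())
        mta["significant"] = mta["BON_p"] < alpha
        mta.insert(0, "trait", self.trait)
        mta.insert(1, "scope", self.scope)
        return GWASResults(self, mta, trace, cof, alpha)


@dataclass
class GWASResults:
    """Fitted GWAS: MTA table, screening trace and cofactor set."""

    model: HaplotypeGWAS
    mta: pd.DataFrame
    trace: SelectionTrace
    cofactors: CofactorSet
    alpha: float = 0.05
    _founder_names: tuple[str, ...] = field(default=())

    @property
    def significant(self) -> pd.DataFrame:
        return self.mta[self.mta["significant"]]

    @property
    def explained_variance(self) -> float:
        """R^2 of the trait on all significant markers jointly."""
        sig = self.significant.index
        return explained_variance(self.model.endog, self.model.exog[list(sig)])

    def founder_effect_table(self, founder_names: tuple[str, ...] | None = None
                             ) -> pd.DataFrame:
        """Per-founder effects of each significant marker (carrier effect,
        non-carriers at zero).  Needs a MarkerMatrix with membership."""
        if self.model._matrix is None:
            raise ValueError("founder membership requires a MarkerMatrix")
        names = founder_names or [f"F{i + 1}" for i in range(8)]
        rows = {}
        for m in self.significant.index:
            memb = self.model._matrix.founder_membership(m)
            eff = self.mta.loc[m, "effect"]
            if all(memb):
                rows[m] = np.full(len(memb), np.nan)
            else:
                rows[m] = founder_effects(eff, memb)
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))

    def manhattan_frame(self) -> pd.DataFrame:
        """Per-marker chrom/bp/cM and -log10 BON_p, with the 0.05
        threshold line value attached."""
        if self.model._matrix is None:
            raise ValueError("map positions require a MarkerMatrix")
        meta = self.model._matrix.meta
        out = meta[["chrom", "bp", "cM"]].copy()
        out["neglog10_BON_p"] = -np.log10(
            np.clip(self.mta.loc[out.index, "BON_p"], 1e-300, None))
        out["threshold"] = -np.log10(self.alpha)
        out["trait"] = self.model.trait
        out["scope"] = self.model.scope
        return out

    def summary(self) -> str:
        lines = [
            f"Haplotype GWAS: trait={self.model.trait} scope={self.model.scope}",
            f"  lines: {len(self.model.endog.dropna())}, "
            f"markers: {self.model.exog.shape[1]}",
            f"  screening: {self.trace.n_reps} repetitions, "
            f"robust markers: {len(self.trace.robust())}",
            f"  cofactors (SBC): {len(self.cofactors)} "
            f"{self.cofactors.markers}",
            f"  significant MTAs (BON_p < {self.alpha}): "
            f"{int(self.mta['significant'].sum())}",
            f"  explained variance R2 = {self.explained_variance:.3f}",
        ]
        sig = self.significant.sort_values("BON_p")
        for m, row in sig.head(15).iterrows():
            lines.append(
                f"    {m}: effect={row['effect']:+.3f} "
                f"R2={row['partial_R2']:.3f} BON_p={row['BON_p']:.3g}")
        return "\n".join(lines)
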