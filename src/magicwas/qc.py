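"""SNP quality control and numeric recoding.

Filters SNPs on missingness, minor allele frequency and map anchoring,
recodes ACGT genotypes to 0/1/2 dosages of a reference founder's allele,
mean-imputes missing dosages and interpolates genetic positions for
markers with only a physical position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING, FounderPanel, GeneticMap, RILPopulation


@dataclass
class SNPStats:
    """Per-SNP QC statistics: missing rate, MAF in the population, map flag."""

    table: pd.DataFrame  # index = marker; missing_rate, maf, has_position, retained


@dataclass
class NumericGenotypeMatrix:
    """N x M dosage matrix of the reference founder's allele.

    Pre-imputation entries are 0/1/2 or NaN; after mean imputation all
    entries lie in [0, 2] with no NaN.
    """

    values: np.ndarray           # (N, M) float
    line_names: list[str]
    markers: pd.Index
    reference: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_names, columns=self.markers)


def _split_alleles(genotypes: np.ndarray) -> np.ndarray:
    """(N, M) two-character strings -> (N, M, 2) single characters."""
    g = np.ascontiguousarray(genotypes)
    return g.view("<U1").reshape(*g.shape, 2)


def snp_stats(pop: RILPopulation) -> pd.DataFrame:
    """Missing rate and population MAF per SNP.

    MAF is computed from allele counts over non-missing diploid calls in
    the RIL population (not the founders).
    """
    chars = _split_alleles(pop.genotypes)
    miss = pop.genotypes == MISSING
    missing_rate = miss.mean(axis=0)
    M = pop.n_markers
    maf = np.zeros(M)
    for j in range(M):
        col = chars[~miss[:, j], j, :].ravel()
        if col.size == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        if len(counts) > 1:
            maf[j] = counts.min() / counts.sum()
    has_pos = np.ones(M, dtype=bool)  # simulated maps are fully anchored
    return pd.DataFrame(
        {"missing_rate": missing_rate, "maf": maf, "has_position": has_pos},
        index=pop.map.markers,
    )


def filter_snps(
    pop: RILPopulation,
    panel: FounderPanel | None = None,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    require_position: bool = True,
) -> tuple[np.ndarray, SNPStats]:
    """Retain SNPs with missing rate < ``max_missing``, MAF > ``min_maf``
    and (optionally) a known map position; founders must be called at
    every retained SNP."""
    if pop.n_lines == 0 or pop.n_markers == 0:
        raise ValueError("empty population")
    stats = snp_stats(pop)
    keep = (stats["missing_rate"] < max_missing) & (stats["maf"] > min_maf)
    if require_position:
        keep &= stats["has_position"]
    if panel is not None:
        founder_called = ~(panel.genotypes() == MISSING).any(axis=0)
        keep &= pd.Series(founder_called, index=stats.index)
    stats["retained"] = keep
    idx = np.flatnonzero(keep.to_numpy())
    if idx.size == 0:
        raise ValueError("all SNPs removed by QC filters")
    return idx, SNPStats(stats)


def recode_reference(
    pop: RILPopulation, panel: FounderPanel, reference: str
) -> NumericGenotypeMatrix:
    """Dosage of the reference founder's allele: hom-ref 2, het 1, hom-alt 0."""
    try:
        f = panel.founder_names.index(reference)
    except ValueError:
        raise ValueError(f"unknown reference founder {reference!r}") from None
    ref_allele = panel.gametes[f]          # (M,)
    if (ref_allele == "N").any():
        raise ValueError("reference founder has missing calls")
    chars = _split_alleles(pop.genotypes)
    dose = (chars == ref_allele[None, :, None]).sum(axis=2).astype(float)
    dose[pop.genotypes == MISSING] = np.nan
    return NumericGenotypeMatrix(dose, list(pop.line_names), pop.map.markers, reference)


def impute_mni(mat: NumericGenotypeMatrix) -> NumericGenotypeMatrix:
    """Mean imputation: each missing dosage becomes its SNP's mean over
    non-missing lines; observed values untouched."""
    v = mat.values
    n_obs = np.sum(~np.isnan(v), axis=0)
    if (n_obs == 0).any():
        bad = list(mat.markers[n_obs == 0])
        raise ValueError(f"SNP columns entirely missing: {bad[:5]}")
    col_mean = np.nanmean(v, axis=0)
    out = np.where(np.isnan(v), col_mean[None, :], v)
    return NumericGenotypeMatrix(out, mat.line_names, mat.markers, mat.reference)


def interpolate_map(
    query: pd.DataFrame,      # index = marker; columns chrom, bp
    anchored: GeneticMap,
) -> pd.Series:
    """cM for physically placed markers by linear interpolation in bp
    between the nearest flanking anchored markers; queries beyond the
    terminal anchor take the terminal anchor's cM (clamped)."""
    out = pd.Series(np.nan, index=query.index, name="cM")
    anchors = anchored.table
    for chrom, sub in query.groupby("chrom", sort=False):
        a = anchors[anchors["chrom"] == chrom]
        if len(a) == 0:
            raise ValueError(
                f"no anchored markers on {chrom}; cannot place: "
                f"{list(sub.index)[:5]}"
            )
        # np.interp clamps beyond the terminal anchors by construction
        out.loc[sub.index] = np.interp(
            sub["bp"].to_numpy(float), a["bp"].to_numpy(float), a["cM"].to_numpy(float)
        )
    return out
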