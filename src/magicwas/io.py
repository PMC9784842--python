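"""Plain-text I/O: genotype/map/phenotype TSV dialects and a GT-only VCF.

Genotypes are written as a lines x SNPs matrix of two-character allele
pairs ("AG", missing "NN"); founders as a founders x SNPs matrix of
single gamete alleles; the map as (marker, chrom, bp, cM); phenotypes
long-format (line, env, treatment, replicate, trait, value).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .haplo import MarkerMatrix
from .simulate import FounderPanel, GeneticMap, RILPopulation


def write_map(gmap: GeneticMap, path: str) -> None:
    df = gmap.table.copy()
    df.index.name = "marker"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_map(path: str) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", index_col="marker",
                     dtype={"chrom": str, "bp": int, "cM": float})
    return GeneticMap(df)


def write_founders(panel: FounderPanel, path: str) -> None:
    df = pd.DataFrame(panel.gametes, index=list(panel.founder_names),
                      columns=panel.map.markers)
    df.index.name = "founder"
    df.to_csv(path, sep="\t")


def read_founders(path: str, gmap: GeneticMap) -> FounderPanel:
    df = pd.read_csv(path, sep="\t", index_col="founder", dtype=str)
    df = df[list(gmap.markers)]
    return FounderPanel(tuple(df.index), df.to_numpy(dtype="<U1"), gmap)


def write_genotypes(pop: RILPopulation, path: str) -> None:
    df = pd.DataFrame(pop.genotypes, index=pop.line_names,
                      columns=pop.map.markers)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str, gmap: GeneticMap) -> RILPopulation:
    df = pd.read_csv(path, sep="\t", index_col="line", dtype=str)
    df = df[list(gmap.markers)]
    return RILPopulation(list(df.index), df.to_numpy(dtype="<U2"), gmap)


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"line": str, "env": str, "treatment": str})


def write_marker_matrix(matrix: MarkerMatrix, values_path: str,
                        meta_path: str) -> None:
    v = matrix.values.copy()
    v.index.name = "line"
    v.to_csv(values_path, sep="\t")
    m = matrix.meta.copy()
    m.index.name = "marker"
    m.to_csv(meta_path, sep="\t", float_format="%.6f")


def read_marker_matrix(values_path: str, meta_path: str) -> MarkerMatrix:
    v = pd.read_csv(values_path, sep="\t", index_col="line")
    v.index = v.index.astype(str)
    m = pd.read_csv(meta_path, sep="\t", index_col="marker",
                    dtype={"chrom": str, "allele": str},
                    converters={"founders": str, "block": str})
    return MarkerMatrix(v.astype(np.int8), m.loc[v.columns])


# ---------------------------------------------------------------------------
# VCF (GT-only, uncompressed)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=magicwas
##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in cM">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(pop: RILPopulation, panel: FounderPanel, path: str) -> None:
    """Write the population as a minimal GT-only VCF; REF is the first
    panel allele at each SNP, cM stored in INFO/CM."""
    t = pop.map.table
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pop.line_names) + "\n")
        for j, marker in enumerate(pop.map.markers):
            alleles = list(panel.alleles_at(j))
            ref = alleles[0]
            alt = alleles[1] if len(alleles) > 1 else "."
            code = {ref: "0"}
            if alt != ".":
                code[alt] = "1"
            gts = []
            for g in pop.genotypes[:, j]:
                if g == "NN":
                    gts.append("./.")
                else:
                    gts.append(f"{code.get(g[0], '.')}/{code.get(g[1], '.')}")
            fh.write(
                f"{t['chrom'].iloc[j]}\t{t['bp'].iloc[j]}\t{marker}\t{ref}\t"
                f"{alt}\t.\t.\tCM={t['cM'].iloc[j]:.6f}\tGT\t" + "\t".join(gts)
                + "\n")


def read_vcf(path: str) -> RILPopulation:
    """Read a GT-only VCF back into a population (no mosaic)."""
    from cyvcf2 import VCF
    vcf = VCF(path)
    lines = list(vcf.samples)
    rows, geno_cols = [], []
    for var in vcf:
        cm = float(var.INFO.get("CM", 0.0))
        rows.append((var.ID, var.CHROM, var.POS, cm))
        alleles = [var.REF] + list(var.ALT)
        col = np.empty(len(lines), dtype="<U2")
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = "NN"
            else:
                pair = sorted((alleles[a], alleles[b]))
                col[i] = pair[0] + pair[1]
        geno_cols.append(col)
    tab = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]
                       ).set_index("marker")
    gmap = GeneticMap(tab)
    geno = np.column_stack(geno_cols)
    return RILPopulation(lines, geno, gmap)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
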