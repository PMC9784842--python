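"""Founder-gamete LD, four-gamete haploblocks and the GWAS marker matrix.

Blocks are built from the eight founder gametes only (the population
never changes the partition): a greedy left-to-right scan per
chromosome joins consecutive SNPs while the pair is closer than 500 kb,
shows at most three of the four possible gametes (the fourth at
frequency < 0.01 -- with eight gametes, absent) and is in complete LD
(D' = 1).  SNPs in no block are "singular".  Population haplotypes are
read off each line's genotype over a block's SNPs, filtered at >5%
frequency and no missing nucleotides, and coded 0/1 (absent/present)
alongside two per-allele presence columns for every singular SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MISSING, FounderPanel, RILPopulation
from .qc import _split_alleles

MISSING_NT = "N"


@dataclass
class LDStats:
    """Two-locus gametic disequilibrium summaries.

    ``gamete_freqs`` holds f(AB), f(Ab), f(aB), f(ab) where A/a are the
    alphabetically first/second alleles at the first SNP (same for B/b).
    """

    D: float
    Dprime: float
    r2: float
    gamete_freqs: tuple[float, float, float, float]


def ld_from_gametes(g1: np.ndarray, g2: np.ndarray) -> LDStats:
    """LD statistics from paired haploid allele calls.

    D = f(AB) - f(A) f(B); D' = |D| / Dmax with Dmax = min(f(A) f(b),
    f(a) f(B)) for D > 0 and min(f(A) f(B), f(a) f(b)) for D < 0;
    r^2 = D^2 / (f(A) f(a) f(B) f(b)).
    """
    al1, al2 = np.unique(g1), np.unique(g2)
    if len(al1) != 2 or len(al2) != 2:
        raise ValueError("both SNPs must be biallelic in the gamete set")
    A, B = al1[0], al2[0]
    x = (g1 == A).astype(float)
    y = (g2 == B).astype(float)
    n = len(g1)
    fAB = float(np.sum(x * y) / n)
    pA, pB = float(x.mean()), float(y.mean())
    fAb = pA - fAB
    faB = pB - fAB
    fab = 1.0 - fAB - fAb - faB
    D = fAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    return LDStats(D, dprime, r2, (fAB, fAb, faB, fab))


def ld_pair(snp_a: int, snp_b: int, panel: FounderPanel) -> LDStats:
    """LD between two SNPs over the 8 founder gametes (one per inbred founder)."""
    return ld_from_gametes(panel.gametes[:, snp_a], panel.gametes[:, snp_b])


@dataclass
class Haploblock:
    id: str
    chrom: str
    members: list[int]            # marker indices, consecutive in map order
    bp_span: tuple[int, int]
    cm_span: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a haploblock needs at least 2 SNPs")


@dataclass
class Haplotype:
    block_id: str
    alleles: str                  # one character per member SNP
    frequency: float
    founder_membership: tuple[bool, ...] = field(default=())

    @property
    def has_missing(self) -> bool:
        return MISSING_NT in self.alleles


def founder_maf(panel: FounderPanel) -> np.ndarray:
    """Minor allele frequency of each SNP over the 8 founder gametes."""
    g = panel.gametes
    n = g.shape[0]
    maf = np.zeros(g.shape[1])
    for j in range(g.shape[1]):
        _, counts = np.unique(g[:, j], return_counts=True)
        if len(counts) > 1:
            maf[j] = counts.min() / n
    return maf


def _pair_qualifies(panel: FounderPanel, a: int, b: int, max_pair_bp: int,
                    fourth_gamete_max: float, dprime_required: float) -> bool:
    bp = panel.map.table["bp"].to_numpy()
    if abs(int(bp[b]) - int(bp[a])) >= max_pair_bp:
        return False
    ld = ld_pair(a, b, panel)
    n_common = sum(f >= fourth_gamete_max for f in ld.gamete_freqs)
    return n_common <= 3 and ld.Dprime >= dprime_required


def build_haploblocks(
    panel: FounderPanel,
    max_pair_bp: int = 500_000,
    fourth_gamete_max: float = 0.01,
    dprime_required: float = 1.0,
    maf_min: float = 0.05,
) -> tuple[list[Haploblock], list[int]]:
    """Four-gamete-rule block partition of the founder panel.

    Greedy left-to-right per chromosome: a block starts at the first
    qualifying adjacent pair and extends while the next consecutive SNP
    qualifies against the previous member.  Returns the blocks and the
    indices of singular SNPs (those in no block).  SNPs below ``maf_min``
    in the founder panel are excluded from the scan and reported singular.
    """
    maf = founder_maf(panel)
    gmap = panel.map
    blocks: list[Haploblock] = []
    singular: list[int] = []
    counter: dict[str, int] = {}
    for chrom in gmap.chromosomes():
        idx = [j for j in gmap.chrom_slice(chrom) if maf[j] > maf_min]
        low_maf = [j for j in gmap.chrom_slice(chrom) if maf[j] <= maf_min]
        singular.extend(low_maf)
        current: list[int] = []
        for j in idx:
            if not current:
                current = [j]
                continue
            if _pair_qualifies(panel, current[-1], j, max_pair_bp,
                               fourth_gamete_max, dprime_required):
                current.append(j)
            else:
                if len(current) >= 2:
                    blocks.append(_make_block(panel, chrom, current, counter))
                else:
                    singular.extend(current)
                current = [j]
        if len(current) >= 2:
            blocks.append(_make_block(panel, chrom, current, counter))
        else:
            singular.extend(current)
    return blocks, sorted(singular)


def _make_block(panel: FounderPanel, chrom: str, members: list[int],
                counter: dict[str, int]) -> Haploblock:
    counter[chrom] = counter.get(chrom, 0) + 1
    t = panel.map.table
    bp = t["bp"].to_numpy()
    cm = t["cM"].to_numpy()
    return Haploblock(
        id=f"Chr{chrom}_HB{counter[chrom]:03d}",
        chrom=chrom,
        members=list(members),
        bp_span=(int(bp[members[0]]), int(bp[members[-1]])),
        cm_span=(float(cm[members[0]]), float(cm[members[-1]])),
    )


def founder_block_haplotypes(panel: FounderPanel, block: Haploblock) -> list[str]:
    """The 8 founder allele strings over the block's member SNPs."""
    sub = panel.gametes[:, block.members]
    return ["".join(row) for row in sub]


def call_haplotypes(
    blocks: list[Haploblock],
    pop: RILPopulation,
    panel: FounderPanel,
) -> tuple[list[Haplotype], dict[str, list[tuple[str, ...]]]]:
    """Read each line's haplotype(s) per block off its genotype.

    Homozygous, fully called blocks give one haplotype carried by the
    line.  A block containing heterozygous calls is resolved against the
    founder haplotypes: if exactly one unordered pair of founder strings
    explains the unphased genotype the line carries both; otherwise the
    block call is missing for that line.  Missing SNP calls propagate an
    'N' into the string (such haplotypes are later filtered out).
    Frequencies distribute each line's unit weight over its carried
    haplotypes, so block frequencies sum to 1 when every line is called.

    Returns the haplotype list and, per block, the per-line tuple of
    carried allele strings (empty tuple = missing call).
    """
    chars = _split_alleles(pop.genotypes)
    n = pop.n_lines
    haplotypes: list[Haplotype] = []
    assignments: dict[str, list[tuple[str, ...]]] = {}
    for block in blocks:
        fh = founder_block_haplotypes(panel, block)
        founder_set = list(dict.fromkeys(fh))
        sub = chars[:, block.members, :]             # (N, m, 2)
        geno = pop.genotypes[:, block.members]
        weights: dict[str, float] = {}
        calls: list[tuple[str, ...]] = []
        for i in range(n):
            missing = geno[i] == MISSING
            het = (sub[i, :, 0] != sub[i, :, 1]) & ~missing
            if missing.any():
                s = "".join(
                    MISSING_NT if m else a
                    for a, m in zip(sub[i, :, 0], missing)
                )
                if het.any():
                    calls.append(())
                    continue
                calls.append((s,))
                weights[s] = weights.get(s, 0.0) + 1.0
            elif not het.any():
                s = "".join(sub[i, :, 0])
                calls.append((s,))
                weights[s] = weights.get(s, 0.0) + 1.0
            else:
                pair = _resolve_het(sub[i], founder_set)
                if pair is None:
                    calls.append(())
                else:
                    calls.append(pair)
                    for s in pair:
                        weights[s] = weights.get(s, 0.0) + 0.5
        assignments[block.id] = calls
        for s in sorted(weights):
            membership = tuple(h == s for h in fh)
            haplotypes.append(Haplotype(block.id, s, weights[s] / n, membership))
    return haplotypes, assignments


def _resolve_het(chars_i: np.ndarray, founder_set: list[str]) -> tuple[str, str] | None:
    """Unique unordered founder-haplotype pair explaining an unphased block
    genotype, or None."""
    m = chars_i.shape[0]
    matches = []
    for p in range(len(founder_set)):
        for q in range(p, len(founder_set)):
            h1, h2 = founder_set[p], founder_set[q]
            ok = all(
                {h1[k], h2[k]} == {chars_i[k, 0], chars_i[k, 1]}
                for k in range(m)
            )
            if ok:
                matches.append((h1, h2))
    if len(matches) == 1:
        return matches[0]
    return None


def filter_haplotypes(hts: list[Haplotype], min_freq: float = 0.05) -> list[Haplotype]:
    """Retain haplotypes with frequency > ``min_freq`` and no missing
    nucleotides in the allele string."""
    return [h for h in hts if h.frequency > min_freq and not h.has_missing]


@dataclass
class MarkerMatrix:
    """N lines x K presence markers (0/1) with per-marker metadata.

    ``meta`` is indexed by marker id with columns ``type`` (haplotype |
    snp_allele), ``chrom``, ``bp``, ``cM``, ``block``, ``allele`` and
    ``founders`` (8-character 0/1 membership string, input founder order).
    """

    values: pd.DataFrame          # lines x markers, int8
    meta: pd.DataFrame

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def founder_membership(self, marker: str) -> tuple[bool, ...]:
        return tuple(c == "1" for c in self.meta.loc[marker, "founders"])


def build_marker_matrix(
    retained: list[Haplotype],
    singular_snps: list[int],
    pop: RILPopulation,
    panel: FounderPanel,
    assignments: dict[str, list[tuple[str, ...]]] | None = None,
    blocks: list[Haploblock] | None = None,
) -> MarkerMatrix:
    """Assemble the 0/1 GWAS design: one presence column per retained
    haplotype plus two per-allele columns per singular SNP.

    Column count K = |retained haplotypes| + 2 x |singular SNPs|; markers
    are ordered by chromosome, bp, then allele label.
    """
    if assignments is None or blocks is None:
        raise ValueError("haplotype assignments and blocks are required")
    block_by_id = {b.id: b for b in blocks}
    t = pop.map.table
    bp_arr = t["bp"].to_numpy()
    cm_arr = t["cM"].to_numpy()
    chrom_arr = t["chrom"].to_numpy()
    cols: list[np.ndarray] = []
    meta_rows: list[dict] = []

    for h in retained:
        blk = block_by_id[h.block_id]
        carried = assignments[h.block_id]
        col = np.fromiter(
            (1 if h.alleles in c else 0 for c in carried), dtype=np.int8,
            count=pop.n_lines,
        )
        cols.append(col)
        meta_rows.append({
            "marker": f"{h.block_id}_{h.alleles}",
            "type": "haplotype",
            "chrom": blk.chrom,
            "bp": blk.bp_span[0],
            "cM": 0.5 * (blk.cm_span[0] + blk.cm_span[1]),
            "block": h.block_id,
            "allele": h.alleles,
            "founders": "".join("1" if f else "0" for f in h.founder_membership),
        })

    chars = _split_alleles(pop.genotypes)
    for j in singular_snps:
        alleles = panel.alleles_at(j)
        marker_name = pop.map.markers[j]
        for a in alleles:
            present = ((chars[:, j, :] == a).any(axis=1)
                       & (pop.genotypes[:, j] != MISSING))
            membership = panel.gametes[:, j] == a
            cols.append(present.astype(np.int8))
            meta_rows.append({
                "marker": f"Chr{chrom_arr[j]}_SNP_{marker_name}_{a}",
                "type": "snp_allele",
                "chrom": chrom_arr[j],
                "bp": int(bp_arr[j]),
                "cM": float(cm_arr[j]),
                "block": "",
                "allele": a,
                "founders": "".join("1" if f else "0" for f in membership),
            })

    meta = pd.DataFrame(meta_rows).set_index("marker")
    values = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((pop.n_lines, 0), np.int8),
        index=list(pop.line_names), columns=meta.index,
    )
    order = meta.sort_values(["chrom", "bp", "allele"]).index
    return MarkerMatrix(values[order], meta.loc[order])


def marker_r2(matrix: MarkerMatrix) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between marker columns."""
    v = matrix.values.to_numpy(float)
    sd = v.std(axis=0)
    sd[sd == 0] = np.nan
    z = (v - v.mean(axis=0)) / sd
    r = (z.T @ z) / v.shape[0]
    return pd.DataFrame(r**2, index=matrix.values.columns,
                        columns=matrix.values.columns)
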