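"""Synthetic eight-way MAGIC population generator.

Emulates the design of an 800-line winter-wheat multi-parent population:
eight fully inbred founders crossed through a balanced funnel
((1x2)x(3x4)) x ((5x6)x(7x8)), the eight-way F1 then selfed for ``g``
generations with map-driven recombination (Haldane model, no
interference).  Phenotypes are built from founder-specific QTL effects
plus variance components for genotype, genotype-by-environment,
genotype-by-treatment (and their three-way term when replicates are
simulated) over ``e`` environments x ``t`` nitrogen treatments.

The generator records the true founder mosaic of every line so that
downstream haplotype calls and founder-effect estimates can be checked
against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

MISSING = "NN"

# Two-founder-panel allele pairs cycled across SNPs; purely cosmetic.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))

N_FOUNDERS = 8

#: Default founder names, mirroring the elite-cultivar panel structure.
DEFAULT_FOUNDERS = (
    "Patras", "Meister", "Linus", "JBAsano",
    "Bernstein", "Tobak", "Safari", "Julius",
)

#: Default genome: five chromosomes, lengths in (cM, bp).
DEFAULT_MAP_SPEC = {
    "1A": (150.0, 590_000_000),
    "2B": (180.0, 780_000_000),
    "3A": (160.0, 750_000_000),
    "4D": (120.0, 510_000_000),
    "7B": (170.0, 730_000_000),
}


@dataclass
class GeneticMap:
    """Marker map: chromosome, physical bp and genetic cM per marker.

    ``table`` is indexed by marker name with columns ``chrom``, ``bp``,
    ``cM``.  Within a chromosome markers are sorted by bp, cM is
    non-decreasing in bp and bp positions are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for chrom, sub in t.groupby("chrom", sort=False):
            if not sub["bp"].is_monotonic_increasing:
                raise ValueError(f"markers on {chrom} not sorted by bp")
            if sub["bp"].duplicated().any():
                raise ValueError(f"duplicate bp positions on {chrom}")
            if not sub["cM"].is_monotonic_increasing:
                raise ValueError(f"cM not non-decreasing with bp on {chrom}")
        if (t["cM"] < 0).any():
            raise ValueError("negative cM position")

    @property
    def markers(self) -> pd.Index:
        return self.table.index

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Integer marker indices belonging to ``chrom`` (map order)."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())


@dataclass
class FounderPanel:
    """Eight inbred founders: one gamete each, plus the marker map."""

    founder_names: tuple[str, ...]
    gametes: np.ndarray  # (n_founders, M) single-character alleles
    map: GeneticMap

    def __post_init__(self) -> None:
        if self.gametes.shape != (len(self.founder_names), self.map.n_markers):
            raise ValueError("gamete matrix shape does not match names/map")

    @property
    def n_founders(self) -> int:
        return len(self.founder_names)

    def genotypes(self) -> np.ndarray:
        """Diploid genotype strings (founders are fully inbred)."""
        return np.char.add(self.gametes, self.gametes)

    def alleles_at(self, j: int) -> np.ndarray:
        return np.unique(self.gametes[:, j])


@dataclass
class RILPopulation:
    """Recombinant inbred lines with optional true founder mosaic."""

    line_names: list[str]
    genotypes: np.ndarray         # (N, M) two-character strings, "NN" missing
    map: GeneticMap
    mosaic: np.ndarray | None = None   # (N, M, 2) founder indices per strand
    selfing_gens: int = 0

    @property
    def n_lines(self) -> int:
        return len(self.line_names)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def heterozygosity(self) -> float:
        """Fraction of non-missing calls with two distinct alleles."""
        g = np.ascontiguousarray(self.genotypes)
        chars = g.view("<U1").reshape(*g.shape, 2)
        ok = g != MISSING
        het = chars[..., 0] != chars[..., 1]
        return float((het & ok).sum() / ok.sum())


@dataclass
class PlantedQTL:
    """A causal locus: a marker plus one additive effect per founder."""

    marker: str
    founder_effects: np.ndarray  # length 8, trait units

    def __post_init__(self) -> None:
        self.founder_effects = np.asarray(self.founder_effects, float)
        if self.founder_effects.shape != (N_FOUNDERS,):
            raise ValueError("founder effect vector must have length 8")


@dataclass
class TraitArchitecture:
    """Variance-component architecture of one simulated trait.

    ``V_G`` is the polygenic (background) genotypic variance drawn per
    line; planted QTL add their founder-specific effects on top of it.
    ``V_GE``, ``V_GT``, ``V_GET`` and ``V_R`` are the interaction and
    residual variances of the multi-environment design with ``e``
    environments, ``t`` treatments and ``r`` replicates.
    """

    trait: str = "YLD"
    qtl: list[PlantedQTL] = field(default_factory=list)
    V_G: float = 1.0
    V_GE: float = 0.5
    V_GT: float = 0.25
    V_GET: float = 0.0
    V_R: float = 1.0
    e: int = 7
    t: int = 2
    r: int = 1
    mean: float = 0.0
    treatment_shift: float = 1.0   # N1 minus N0 main effect
    env_spread: float = 1.0        # fixed env offsets span +-env_spread/2

    def __post_init__(self) -> None:
        for name in ("V_G", "V_GE", "V_GT", "V_GET", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.e, self.t, self.r) < 1:
            raise ValueError("design sizes must be >= 1")


# ---------------------------------------------------------------------------
# founders


def _similarity_by_minor_count(n: int = N_FOUNDERS) -> dict[int, float]:
    pairs = comb(n, 2)
    return {k: (comb(k, 2) + comb(n - k, 2)) / pairs for k in range(1, n // 2 + 1)}


def random_map(n_snps: int, map_spec: dict | None, rng: np.random.Generator) -> GeneticMap:
    """Random marker map with uniform bp placement and linear cM."""
    map_spec = dict(map_spec or DEFAULT_MAP_SPEC)
    for chrom, (cm_len, bp_len) in map_spec.items():
        if cm_len <= 0 or bp_len <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
    total_bp = sum(bp for _, bp in map_spec.values())
    rows = []
    remaining = n_snps
    items = list(map_spec.items())
    for i, (chrom, (cm_len, bp_len)) in enumerate(items):
        m = remaining if i == len(items) - 1 else max(1, round(n_snps * bp_len / total_bp))
        m = min(m, remaining)
        remaining -= m
        bp = np.sort(rng.choice(bp_len, size=m, replace=False)) + 1
        cm = bp / bp_len * cm_len
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), float(c)))
    df = pd.DataFrame(rows, columns=["chrom", "bp", "cM"])
    df.index = [f"S{i:05d}" for i in range(len(df))]
    return GeneticMap(df)


def simulate_founders(
    n_snps: int,
    map_spec: dict | None = None,
    diversity: float = 0.59,
    seed: int | None = None,
    founder_names: tuple[str, ...] = DEFAULT_FOUNDERS,
) -> FounderPanel:
    """Simulate 8 inbred founders with a target mean pairwise similarity.

    Each SNP is biallelic and polymorphic in the panel; the minor-allele
    carrier count per SNP is drawn so that the expected simple-matching
    similarity over founder pairs equals ``diversity``.  Achievable
    targets lie between 3/7 (minor count 4) and 3/4 (minor count 1);
    anything outside raises ``ValueError``.
    """
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    if not 0 < diversity < 1:
        raise ValueError("diversity must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gmap = random_map(n_snps, map_spec, rng)

    sims = _similarity_by_minor_count()
    ks = sorted(sims, key=sims.get)  # ascending similarity: 4,3,2,1
    vals = [sims[k] for k in ks]
    if not vals[0] <= diversity <= vals[-1]:
        raise ValueError(
            f"target similarity {diversity} infeasible for an all-polymorphic "
            f"8-founder panel (achievable range [{vals[0]:.4f}, {vals[-1]:.4f}])"
        )
    hi = int(np.searchsorted(vals, diversity))
    if vals[hi] == diversity:
        k_choices, probs = [ks[hi]], [1.0]
    else:
        lo = hi - 1
        p_hi = (diversity - vals[lo]) / (vals[hi] - vals[lo])
        k_choices, probs = [ks[lo], ks[hi]], [1 - p_hi, p_hi]

    minor_counts = rng.choice(k_choices, size=n_snps, p=probs)
    gametes = np.empty((N_FOUNDERS, n_snps), dtype="<U1")
    for j in range(n_snps):
        a_major, a_minor = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        gametes[:, j] = a_major
        carriers = rng.choice(N_FOUNDERS, size=minor_counts[j], replace=False)
        gametes[carriers, j] = a_minor
    return FounderPanel(tuple(founder_names), gametes, gmap)


def mean_pairwise_similarity(gametes: np.ndarray) -> float:
    """Mean simple-matching similarity over all founder pairs."""
    n = gametes.shape[0]
    acc = [
        float((gametes[i] == gametes[j]).mean())
        for i in range(n) for j in range(i + 1, n)
    ]
    return float(np.mean(acc))


# ---------------------------------------------------------------------------
# funnel cross


def _meiosis(
    rng: np.random.Generator,
    strands: np.ndarray,          # (2, M) founder labels
    chrom_index: list[np.ndarray],
    chrom_cm: list[np.ndarray],
) -> np.ndarray:
    """One gamete: Haldane crossovers, count ~ Poisson(length in Morgans),
    positions uniform on the cM scale, no interference."""
    gamete = np.empty(strands.shape[1], dtype=strands.dtype)
    for idx, cm in zip(chrom_index, chrom_cm):
        length_m = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
        n_xo = rng.poisson(length_m) if length_m > 0 else 0
        start = rng.integers(2)
        if n_xo == 0:
            strand = np.full(len(idx), start)
        else:
            pos = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
            strand = (start + np.searchsorted(pos, cm, side="right")) % 2
        gamete[idx] = strands[strand, idx]
    return gamete


def funnel_cross(
    panel: FounderPanel,
    n_lines: int,
    selfing_gens: int = 4,
    seed: int | None = None,
    shared_funnel: bool = False,
) -> RILPopulation:
    """Cross 8 founders through a balanced funnel and self to RILs.

    Pairing follows input order ((1x2)x(3x4)) x ((5x6)x(7x8)); each line
    descends from its own funnel with independent meioses unless
    ``shared_funnel`` is set, in which case a single eight-way F1 plant
    is the common ancestor.  After ``selfing_gens`` generations of
    single-seed selfing the expected per-locus heterozygosity is
    (1/2)^g of the eight-way F1 value.
    """
    if panel.n_founders != N_FOUNDERS:
        raise ValueError("the funnel scheme requires exactly 8 founders")
    if selfing_gens < 0:
        raise ValueError("selfing_gens must be >= 0")
    rng = np.random.default_rng(seed)
    gmap = panel.map
    M = gmap.n_markers
    chroms = gmap.chromosomes()
    chrom_index = [gmap.chrom_slice(c) for c in chroms]
    cm_all = gmap.table["cM"].to_numpy()
    chrom_cm = [cm_all[idx] for idx in chrom_index]

    def f1(a: int, b: int) -> np.ndarray:
        out = np.empty((2, M), dtype=np.int8)
        out[0], out[1] = a, b
        return out

    def eight_way() -> np.ndarray:
        four_1 = np.stack([
            _meiosis(rng, f1(0, 1), chrom_index, chrom_cm),
            _meiosis(rng, f1(2, 3), chrom_index, chrom_cm),
        ])
        four_2 = np.stack([
            _meiosis(rng, f1(4, 5), chrom_index, chrom_cm),
            _meiosis(rng, f1(6, 7), chrom_index, chrom_cm),
        ])
        return np.stack([
            _meiosis(rng, four_1, chrom_index, chrom_cm),
            _meiosis(rng, four_2, chrom_index, chrom_cm),
        ])

    common = eight_way() if shared_funnel else None
    mosaic = np.empty((n_lines, M, 2), dtype=np.int8)
    for i in range(n_lines):
        plant = common if common is not None else eight_way()
        for _ in range(selfing_gens):
            plant = np.stack([
                _meiosis(rng, plant, chrom_index, chrom_cm),
                _meiosis(rng, plant, chrom_index, chrom_cm),
            ])
        mosaic[i, :, 0] = plant[0]
        mosaic[i, :, 1] = plant[1]

    cols = np.arange(M)
    a1 = panel.gametes[mosaic[:, :, 0], cols]
    a2 = panel.gametes[mosaic[:, :, 1], cols]
    swap = a1 > a2
    lo = np.where(swap, a2, a1)
    hi = np.where(swap, a1, a2)
    genotypes = np.char.add(lo, hi)
    names = [f"WM_{i + 1:03d}" for i in range(n_lines)]
    return RILPopulation(names, genotypes, gmap, mosaic, selfing_gens)


# ---------------------------------------------------------------------------
# phenotypes


def genotypic_values(pop: RILPopulation, arch: TraitArchitecture,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-line genetic value: planted QTL contributions + N(0, V_G) polygene."""
    g = rng.normal(0.0, np.sqrt(arch.V_G), size=pop.n_lines)
    if arch.qtl and pop.mosaic is None:
        raise ValueError("founder-effect QTL need the true mosaic")
    marker_pos = {m: j for j, m in enumerate(pop.map.markers)}
    for q in arch.qtl:
        if q.marker not in marker_pos:
            raise ValueError(f"QTL marker {q.marker!r} not on the map")
        j = marker_pos[q.marker]
        lab = pop.mosaic[:, j, :]                      # (N, 2)
        g += q.founder_effects[lab].mean(axis=1)
    return g


def plant_phenotypes(
    pop: RILPopulation,
    arch: TraitArchitecture,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the long-format phenotype table for one trait.

    One observation per line x environment x treatment (x replicate when
    ``arch.r > 1``): genetic value + fixed environment/treatment offsets
    + independent G x E, G x T (and G x E x T with replicates) draws at
    the architecture's variances + residual noise.
    """
    rng = np.random.default_rng(seed)
    n, e, t, r = pop.n_lines, arch.e, arch.t, arch.r
    g = genotypic_values(pop, arch, rng)

    env_names = [f"E{j + 1}" for j in range(e)]
    trt_names = ["N0", "N1"][:t] if t <= 2 else [f"T{k}" for k in range(t)]
    env_off = (np.linspace(-0.5, 0.5, e) if e > 1 else np.zeros(1)) * arch.env_spread
    trt_off = np.arange(t) * arch.treatment_shift - (t - 1) * arch.treatment_shift / 2

    ge = rng.normal(0, np.sqrt(arch.V_GE), size=(n, e))
    gt = rng.normal(0, np.sqrt(arch.V_GT), size=(n, t))
    if r > 1:
        get = rng.normal(0, np.sqrt(arch.V_GET), size=(n, e, t))
        resid = rng.normal(0, np.sqrt(arch.V_R), size=(n, e, t, r))
        value = (arch.mean + g[:, None, None, None]
                 + env_off[None, :, None, None] + trt_off[None, None, :, None]
                 + ge[:, :, None, None] + gt[:, None, :, None]
                 + get[:, :, :, None] + resid)
        idx = pd.MultiIndex.from_product(
            [pop.line_names, env_names, trt_names, range(1, r + 1)],
            names=["line", "env", "treatment", "replicate"])
        df = pd.DataFrame({"value": value.ravel()}, index=idx).reset_index()
    else:
        resid = rng.normal(0, np.sqrt(arch.V_R), size=(n, e, t))
        value = (arch.mean + g[:, None, None]
                 + env_off[None, :, None] + trt_off[None, None, :]
                 + ge[:, :, None] + gt[:, None, :] + resid)
        idx = pd.MultiIndex.from_product(
            [pop.line_names, env_names, trt_names],
            names=["line", "env", "treatment"])
        df = pd.DataFrame({"value": value.ravel()}, index=idx).reset_index()
        df["replicate"] = 1
    df["trait"] = arch.trait
    return df[["line", "env", "treatment", "replicate", "trait", "value"]]


def inject_missingness(
    pop: RILPopulation, rate: float, seed: int | None = None
) -> RILPopulation:
    """Mask each genotype call independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return pop
    rng = np.random.default_rng(seed)
    mask = rng.random(pop.genotypes.shape) < rate
    geno = pop.genotypes.copy()
    geno[mask] = MISSING
    return RILPopulation(list(pop.line_names), geno, pop.map,
                         pop.mosaic, pop.selfing_gens)
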