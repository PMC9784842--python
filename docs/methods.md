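# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `magicwas`.

## The population model the simulator emulates

The synthetic data generator reproduces the structure of an eight-way
MAGIC winter-wheat panel: eight fully inbred elite founders, a balanced
funnel ((1×2)×(3×4)) × ((5×6)×(7×8)) producing an eight-way F1, and
four generations of single-seed selfing so that lines retain a little
residual heterozygosity (F6-like; expected per-locus heterozygosity is
(1/2)⁴ of the eight-way F1 value, ≈ 6% of loci).

*Founders.* Each SNP is biallelic and polymorphic in the panel; the
minor-allele carrier count k ∈ {1..4} is drawn so that the expected
pairwise simple-matching similarity equals the target (default 0.59,
the realistic value for a modern elite panel). Achievable targets lie
in [3/7, 3/4]; anything outside raises an error rather than silently
clipping.

*Recombination.* Haldane model: crossover count per chromosome ~
Poisson(map length in Morgans), positions uniform on the cM scale, no
interference. Each line descends from its own funnel with independent
meioses (a shared-funnel mode exists for sensitivity analyses). The
default genome is five chromosomes totalling ≈ 780 cM / 3.4 Gbp with
markers placed uniformly at random in bp and cM linear in bp; real
wheat coordinates are deliberately not modelled.

*Phenotypes.* An observation for line i in environment j under
treatment k (replicate l) is

    y_ijkl = μ + g_i + E_j + T_k + (gE)_ij + (gT)_ik [+ (gET)_ijk] + ε

with fixed environment offsets (evenly spaced over ±env_spread/2) and a
fixed N1−N0 treatment shift, and independent normal draws at variances
V_GE, V_GT (V_GET with replicates) and V_R. The genetic value g_i is
the sum of planted-QTL contributions — each QTL carries one additive
effect per founder, read off the line's true founder mosaic (the mean
of its two strands) — plus a polygenic background ~ N(0, V_G). V_G is
therefore the *background* genotypic variance; planted QTL add variance
on top of it. Defaults (V_G = 1, V_GE = 0.5, V_GT = 0.25, V_R = 1,
e = 7, t = 2) give a genotype-mean heritability ≈ 0.79, in the range
reported for yield-type traits in multi-environment wheat trials.

What the generator does **not** emulate: genotyping error, segregation
distortion, selection during line development, population structure
beyond the funnel, spatial field trends, and real LD decay profiles.
Tests passing on this generator therefore show that the algorithms are
implemented correctly and calibrated under idealized Mendelian
conditions, not that the pipeline's real-data operating characteristics
are reproduced.

## Quality control and recoding

SNPs are kept when missingness < 5%, population MAF > 5% (computed in
the RIL population, where the filter actually matters, not in the
founders), a map position is known, and all eight founders are called.
Genotypes are recoded as the dosage (0/1/2) of a reference founder's
allele; heterozygous calls stay valid (dosage 1) because residual
heterozygosity is real at F6. Missing dosages are mean-imputed per SNP.
Markers with only physical positions get genetic positions by linear
interpolation in bp between the flanking anchored markers, clamped to
the terminal anchor's cM beyond the ends of the anchored map (the
least-surprising convention for chromosome extremes; interpolation
preserves the monotonicity of cM in bp).

## Haploblocks and the marker matrix

Blocks are a function of the founder panel only. The greedy
left-to-right scan starts a block at the first qualifying adjacent SNP
pair and extends it one SNP at a time; a pair qualifies when the two
SNPs are < 500 kb apart, at most three of the four possible gametes
appear among the 8 founder gametes at frequency ≥ 0.01 (with eight
gametes this means the fourth gamete is absent), and D' = 1. Testing
only the adjacent pair (not all pairs in the block) matches the
pairwise-consecutive behaviour of the standard four-gamete block
builder. SNPs in no block are *singular*.

Population haplotypes are read off each line's genotype over a block's
SNPs. Heterozygous blocks are resolved against the founder haplotypes:
if exactly one unordered founder pair explains the unphased genotype
the line carries both haplotypes (each weighted 1/2 in the frequency
count so block frequencies sum to 1 when every line is called);
otherwise the block call is missing. Recombinant haplotypes absent from
all founders are legal and counted. Haplotypes are retained at
frequency > 5% with no missing nucleotide. The design matrix has one
0/1 presence column per retained haplotype plus two per-allele columns
per singular SNP (K = retained HTs + 2·singular SNPs), each column
annotated with the set of founders carrying it; columns are ordered by
chromosome, bp, allele for deterministic output.

## The three-step association scan

Step 1 (screening) runs 100 independent 80/20 splits. Within a split,
stepwise selection is driven by the training fit — the entry candidate
is the marker with the largest training-SSE reduction, the removal
candidate the weakest contributor — and a move is accepted only if it
decreases the validation-set mean squared prediction error (ASE),
stopping at the first rejected move. Driving the *path* by the
training criterion and the *stopping* by validation is essential: if
the entry candidate were itself chosen to minimize validation ASE,
with thousands of candidates some marker would almost always lower it,
the terminal models would grow without bound and the screen would lose
its meaning. Ties break on the smaller column index so a fixed seed
fixes everything. Markers appearing in ≥ 2 of the 100 terminal models
are "robust".

Step 2 enters robust markers forward, one per round, requiring a strict
decrease of SBC = n·ln(SSE/n) + k·ln(n) (k counts the intercept);
perfectly redundant candidates are skipped deterministically.

Step 3 tests every marker by OLS with the cofactors in the background.
Non-cofactor markers are conditioned on the full cofactor set; a
cofactor takes its *sequential* term test, i.e. it is conditioned only
on the cofactors that entered before it. This matters for error
control: cofactors are co-selected by the same stepwise run, and
conditioning one on the others inflates its t-statistic under the null
(measured family-wise error ≈ 0.10–0.13 in a global-null simulation at
400 lines × 2000 markers), whereas sequential conditioning keeps the
realized family-wise error within the Holm bound (≈ 0.04–0.07 in the
same simulation). Reported per marker: the conditional effect (trait
units per presence 0→1), the sequential type-I R² share of the total
sum of squares, the sequential F-test p-value, and its Bonferroni–Holm
adjustment over all markers; significance at BON_p < 0.05. Markers
collinear with their background are flagged (effect NaN, p = 1).

Founder effects attach the carrier effect to every founder carrying the
marker allele, non-carriers at the zero baseline; a marker carried by
all eight founders has no contrast and is refused. Explained variance
per trait/scope is the R² of the joint OLS on all significant markers.

## QTL merging, pleiotropy, prediction

Significant same-trait, same-chromosome associations are merged by
single linkage, linking two markers when LD r² ≥ 0.8 *or* they are
< 5 cM apart — the union of the two published readings of the merge
rule, with each link's justification recoverable from the LD matrix and
map. Single linkage is the simplest closure of a pairwise rule; the
merge is order-independent by construction. QTL are named
Q<TRAIT>_<chromosome> with letter suffixes on collision. Scope
accounting counts, per trait, QTL significant under N0, N1 and across,
and QTL unique to a single scope; percentages are reported at one
decimal, half-up. Pleiotropic loci group QTL of *different* traits
within 5 cM (midpoint distance, single linkage, ≥ 2 traits). Yield
prediction pools significant yield-marker columns with component-trait
LSMEANS and selects predictors by the same SBC-forward routine,
reporting the full and the markers-only model.

## Phenotype statistics

LSMEANS reduce to arithmetic means on balanced data; unbalanced data
are fitted with a sum-coded fixed-effects model (line + environment +
treatment + environment:treatment) and line means are predictions
averaged with equal weight over the environment × treatment grid.
Interactions involving genotype are excluded from the LSMEANS model:
with one observation per line × environment × treatment cell they
absorb the residual degrees of freedom and cannot improve the marginal
means. ANOVA uses the sequential (type-I) decomposition with all
two-way interactions — closed form on balanced data, statsmodels OLS +
anova_lm otherwise — with the usual */**/*** stars at 0.05/0.01/0.001.

Variance components come from expected mean squares on balanced data
(the three-way interaction is the residual when there are no
replicates; with replicates V_GET is separated) and from REML
(MixedLM with variance-component formulas) on unbalanced data, which
is practical for small designs only. Negative estimates are truncated
to zero and flagged. Heritability uses the genotype-mean formulas
above; it is undefined (error) when all components vanish.

Genetic similarity is simple matching over shared non-missing calls
(pairs with no shared calls are flagged missing); the PCA is run on the
similarity matrix and reports percent variance explained per axis.

## Numerical choices

Rank decisions use a tolerance of 1e-9·n; stepwise ties break on the
smaller marker index; Holm is the standard step-down max-accumulation;
zero-residual ANOVA reports F = ∞ with p at the machine floor; CV is
undefined (flagged) at zero mean. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical seeds give
byte-identical output bundles (verified via the MD5 manifest).

## Calibration scales

The Monte-Carlo suites run at: family-wise error — 200 null runs of
400 lines × 2000 Bernoulli presence markers in the test suite (100 runs
in the acceptance script); power — a presence marker explaining 10% of
phenotypic variance in 800 lines, 30 seeds (15 in the script);
variance-component and heritability recovery — 5 replicate simulations
of 800 lines × 7 environments × 2 treatments; funnel genetics — 400–800
lines. Null designs use independent Bernoulli columns because the Holm
guarantee is conditional on any fixed design; the power and recovery
suites use the funnel-cross simulator itself.

## Known limitations

REML on large unbalanced designs is slow (the MixedLM formulation
builds one indicator column per variance-component level). The LD
matrix for QTL merging is computed densely and is skipped above 4000
markers (merging then falls back to the cM rule alone). The simulator's
uniform marker placement understates the centromeric marker sparsity of
real wheat arrays, and simple-matching similarity treats heterozygotes
as full mismatches against either homozygote, as the standard
implementation does.
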