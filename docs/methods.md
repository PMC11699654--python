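# Methods

This note documents the statistical models, defaults and design choices
behind `epinteg`, and what the synthetic-data tests do and do not show
about real data.

## Coordinate conventions

All intervals are 0-based, half-open `[start, end)` internally. GTF
input (1-based, inclusive) is converted at the reader: the TSS of a
plus-strand gene is `start − 1`, of a minus-strand gene `end − 1`.
Variant tables may be declared 1-based at load, in which case positions
are shifted by −1. No other module reinterprets coordinates.

The promoter window is −1500/+500 bp around the TSS, measured along the
direction of transcription. On the plus strand this is the genomic
interval `[tss − 1500, tss + 500)`. On the minus strand the window is
the exact base-level mirror, `[tss − 499, tss + 1501)`: it covers
precisely the same 2000 bases relative to the TSS, so mirroring a
genome and flipping every strand leaves all category assignments
unchanged. Peak overlap requires ≥ 1 bp; there is no minimum-fraction
rule. A peak overlapping any promoter window is a promoter peak
(assigned to every overlapped gene); otherwise a peak overlapping a
catalogued enhancer is an enhancer peak (assigned to the enhancer's
linked genes); otherwise distal. Promoter precedence is deliberate:
enhancer catalogues routinely overlap promoters, and the enhancer class
is meant to capture non-promoter regulation. An alternative convention
assigns a promoter peak only to the nearest TSS; the all-overlaps
choice is broader and resolved per gene downstream, not per peak.

## Differential testing

Counts are normalized with the trimmed mean of M-values: pairwise
log-ratios M and average log-abundances A against a reference sample
(the one whose upper-quartile count fraction is closest to the mean),
genes with a zero in either member of the pair excluded, 30% trimming
on M, 5% on A, and an inverse-variance weighted mean of the surviving
M-values. Factors are rescaled to geometric mean 1. Testing operates on
`log2((count + 0.5) / (lib × factor) × 1e6)`.

Low-expression filtering keeps features with ≥ 10 counts (scaled by
each sample's library relative to the median library) in at least as
many samples as the smallest group.

The two-group test is a moderated t: per-feature residual variance s²g
on dg degrees of freedom is shrunk toward a prior (d₀, s₀²) estimated
by moment-matching the mean and variance of log s²g to a scaled-F
reference (digamma/trigamma identities; trigamma inverted by Newton
iteration). The statistic uses the posterior variance on d₀ + dg df;
when the observed spread of log-variances does not exceed chi-square
sampling noise, d₀ = ∞ and every feature shares s₀². Confidence
intervals use the same t reference at level 1 − α with α equal to the
FDR level (0.05), which is also the level behind msd. The test is
unweighted: no mean–variance precision weights and no sample quality
weights. This sacrifices some power on real RNA-seq, where variance
depends strongly on abundance, but preserves the effect/CI/p machinery
the integration needs and keeps the null exactly calibrated on the
shared-dispersion simulation.

**Confident effect sizes.** For a bound c ≥ 0 the interval null
H₀: |β| ≤ c has the two-sided p-value `P(T > τ − δ) + P(T > τ + δ)`
with τ = |β̂|/se and δ = c/se on the moderated df. The confect of a
feature is the largest c at which the feature is still rejected by BH
at the FDR level applied across all features; it is found by monotone
bisection to 10⁻⁴ log2 units (the brute-force grid search is kept in
the test suite as the oracle). Features with q ≥ FDR get a null
confect. Confects are conservative signed effect bounds: ranking by
|confect| orders genes by how large an effect is confidently supported,
not by how small a p-value is attained.

**Rankings.** msd = `ci_low` for positive effects, `−ci_high` for
negative ones; it is negative when the CI crosses zero and ranks
features for CERNO. The TF-activity stage instead consumes
`z = sign(log2FC) × Φ⁻¹(1 − q/2)`; q must be floored (the pipeline uses
10⁻¹²) since q = 0 maps to infinity. Ranking ties break by feature id
so outputs are deterministic.

## Enrichment

CERNO combines the relative ranks of a set's members,
`S = −2 Σ ln(Rg/N)`, referred to χ² with 2k df — Fisher's combination
applied to ranks treated as uniform under the null. The effect size is
the rank AUC computed from the Mann–Whitney U. The test depends only on
ranks, never on the scores behind them. Sets smaller than 5 members
after intersection with the ranked universe are dropped; BH is applied
within each call, with no cross-call correction.

Hypergeometric over-representation uses an explicit background
universe; both the selection and each set are intersected with it
first. The reported effect is the enrichment ratio (k/n)/(K/N).

RRHO uses the four-quadrant construction: features are split by score
sign in each list, each quadrant's two sign classes are ordered by
decreasing |score|, and a step grid of top-list thresholds is scanned;
each cell is a signed −log10 hypergeometric p (positive for
over-representation of the overlap, negative for depletion). The step
defaults to N/50 — fine enough to localize signal, coarse enough to
keep the map small. The universe for each quadrant's test is the union
of the two sign classes involved.

## TF activity

A regulon is a TF's weighted, mode-signed target set. Its activity is
the analytic NES `Σ wᵢsᵢzᵢ / √Σ wᵢ²` over the targets present in the
score universe (minimum 3); under independent N(0,1) scores this is
exactly N(0,1), which the suite verifies by KS test. This replaces
rank-based regulon enrichment with shadow analysis; the analytic form
is deterministic, linear in the scores, and odd under mode flips.

The directional motif z-score multiplies a motif activity magnitude by
the sign of the motif–target correlation and by the direction of the
targets' expression change. The direction is taken as the sign of the
mean target log2FC (not a per-target sum); a zero correlation leaves
the TF undetermined. The motif z and correlation are inputs, not
inferred here: motif-activity inference itself (ridge regression of
expression on motif counts) is out of scope.

Activator/repressor classification Pearson-correlates a TF's
per-sample expression with the mean accessibility change over its
motif-bearing peaks (≥ 4 paired samples) and thresholds at |r| ≥ 0.3;
below that the mode is undetermined. The fixed threshold trades the
permutation machinery of footprint-based methods for determinism; 0.3
is the conventional boundary for a weak-to-moderate correlation.

## Integration

Genes with RNA q < 0.05 and at least one assigned promoter or enhancer
peak with ATAC q < 0.05 form the intersect. Peaks without a non-null
confect are dropped; among the rest, promoter peaks are preferred
categorically, then the peak with the largest |confect| wins (ties by
peak id). RNA confects and chosen-peak confects are z-scored across the
intersect genes of that one comparison — not across comparisons — and
multiplied. Confects are already log2 quantities and receive no further
transformation. The z-scoring population choice makes scores comparable
within a comparison's table; a gene's score therefore changes if the
intersect changes, which is intended (the score measures deviation
relative to the cohort of double-significant genes).

Pareto ranking takes up to three objectives per gene: a promoter
accessibility z, an enhancer accessibility z (each from the
largest-|log2FC| significant peak of that category) and the expression
z, all standardized across the participating genes. Domination is
pairwise on shared objectives, so a gene lacking an enhancer competes
on the other two; a two-objective mode collapses accessibility to a
single column (promoter preferred). Non-dominated sorting is the plain
O(n²) peeling; the up-orientation maximizes all objectives, the
down-orientation minimizes them, and negating every objective swaps
the two exactly. The final ranking orders by front, then objective sum,
then gene id, and feeds CERNO directly.

Drug-target overlap keys each intersect gene by its chosen peak's
category and accessibility direction (promoter-up/down,
enhancer-up/down) and intersects each of the four sets with the target
side of a drug–gene edge list.

GWAS overlap removes variants with reported association p > 0.05, then
tests `start ≤ pos < end` against each significant peak.

## Synthetic data

The generator emulates a small case/control multiomics design: one
control (NDC) plus three case conditions, three replicates each. Genes
are laid out on two synthetic chromosomes at 20 kb spacing with
alternating strands; each gene gets a 500 bp peak template centred on
its TSS, half the genes (configurable) get a linked enhancer 7 kb
downstream (≥ 5 kb from every TSS), and a quarter get an unlinked
distal peak 13 kb downstream.

Counts are negative binomial with mean `lib_s × q_g × 2^{x_gc}` and
variance `μ + φμ²`: `q_g` is a relative abundance drawn log2-normal
(mean 5, sd 2 in log2 units — wide enough to exercise the expression
filter), `lib_s` a log-normal library size (default mean 10⁶, CV 0.2),
and φ a single shared dispersion (default 0.1, a typical bulk-tissue
value; no abundance trend). The planted effect `x_gc` is 0 in the
control and, in every case condition, ±Δ (default 2) for the 10% of
genes chosen as differential, plus coherent shifts of
`activity × mode_sign` for each planted TF's targets (TF targets are
drawn from non-differential genes so the two signals do not confound).
A differential gene is concordant with probability 0.8, in which case
its promoter peak — and its linked enhancer, if any — receives an
accessibility shift of identical sign and magnitude; discordant genes
receive no accessibility shift at all. ATAC peak counts use the same
negative-binomial machinery with their own baselines. Variants are
placed at the midpoints of known differential peaks and, in equal
number, in inter-peak gaps, with a configurable fraction given
association p > 0.05 to exercise the filter.

Randomness comes from one seeded generator per component (layout,
planting, RNA counts, ATAC counts, TF assignment, variants), with
fixed spawn keys, so outputs are reproducible bit-for-bit across runs
and platforms.

What the generator does **not** model: abundance-dependent dispersion,
sample quality differences, batch effects, correlated genes,
fragment-level or insertion-bias structure, peak-width variation,
anti-correlated promoter/expression pairs, or overlapping gene loci.
Passing the recovery tests therefore shows that the chain of statistics
is implemented correctly and calibrated under its stated model, not
that the pipeline attains any particular power on real sequencing data,
where the unweighted moderated t in particular will be conservative or
anticonservative depending on the mean–variance relationship.

## Problem sizes and numerical choices

The test suite and the acceptance script use the default design (2000
genes, 3 vs 3 replicates, Δ = 2, 10% differential, 80% concordance,
dispersion 0.1) over 10 seeds for recovery measurements, 10 000
features or sets for null calibrations, and universes of ≤ 20 for exact
hypergeometric enumeration; these sizes put every Monte-Carlo bound
well inside its binomial error while keeping a full run to a few
minutes on one CPU. Confect bisection tolerance is 10⁻⁴ log2 units
(test oracle grid: 10⁻³). BH is the standard step-up, capped at 1 —
note it is monotone and order-preserving but not idempotent on
re-adjusted vectors. All TSV output is written with fixed `%.10g`
float formatting so repeated runs are byte-identical.

## Known limitations

- Single-factor, two-group contrasts only; no paired designs,
  covariates or interaction terms.
- Confect computation assumes a common df across features (true for
  the complete-data two-group design it serves).
- The enhancer objective in Pareto ranking depends on the enhancer
  catalogue's link quality; unlinked enhancers never contribute.
- GWAS variant coordinates are assumed to be on the same genome build
  as the peaks; no liftover is attempted.
- The CLI's `run` command processes each case condition independently;
  there is no joint multi-condition model.
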