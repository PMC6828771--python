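# Methods

This note documents the models, estimators and design choices behind
`woundchrom`, in the spirit of the methods documentation of statsmodels or
msprime: enough detail to re-derive every number the package prints.

## Coordinates, windows and marking calls

All intervals are 0-based half-open (BED convention); GFF3 gene records are
converted on read. A gene's *analysis window* is its body extended by a
1-kb promoter on the strand-appropriate side, clamped at position 0 (no
chromosome-length clamp, since lengths are unknown from BED input). Peak →
gene assignment follows BEDTools-`closest` semantics: the gap in bp between
nearest interval edges (0 on overlap), with exact ties assigning the peak
to *all* tied genes — harmless downstream because marking is per-gene.
Under half-open arithmetic a book-ended peak has gap 0 and counts as
overlapping. A gene is **marked** for a mark at a time point only if a peak
with −log₁₀(Q) ≥ 3 (Q < 0.001) overlaps its window in *both* replicates;
the replicate-intersection rule trades sensitivity for a very low false
marking rate. The maximum assignment distance is exposed
(`max_distance_bp`, default 0 = overlap only), since "closest" by itself
imposes no cap.

## Relative enrichment

A gene's enrichment level for a mark is

    level = (mean mark depth + 0.5) / (mean H3 depth + 0.5)

over the analysis window, replicates averaged before the ratio. The 0.5
pseudo-depth bounds the ratio for empty windows and cancels when depths are
equal; per-replicate ratios averaged instead is available as an option.
Normalizing to H3 (rather than an exogenous spike-in epigenome) assumes
overall mark levels do not change drastically across the time course — the
regime this design targets. The pseudo-count makes the ratio only
approximately scale-invariant: rescaling both depths by c drifts the ratio
by < 2% for moderate c at depths ≥ 10 (worst case ≈ 2.4% as c → ∞ at
depth 10).

## Differential expression

**Normalization.** Trimmed-mean-of-M-values factors: M and A computed from
library-scaled proportions against a reference sample (the one whose 75th
percentile of scaled counts is closest to the mean), genes trimmed at 30%
on M and 5% on A, and the factor taken as the *plain* (unweighted) mean of
the surviving M values, normalized to geometric mean 1. The unweighted mean
is deliberate: it depends on proportions only, so a pure depth change in
any sample (e.g. resequencing one library deeper) leaves every factor — and
every downstream p-value — exactly unchanged. For the same reason the
common adjustment scale (to which counts are rescaled before testing) is
the geometric mean of effective library sizes *quantized to the nearest
power of two*: exactly stable under modest library-size perturbations,
while staying within √2 of the geometric mean so calibration is unaffected.

**Dispersion.** NB variance Var = μ + φμ². Per-gene φ is estimated by
method of moments pooled across the time groups (so real induction does not
inflate φ), using the unbiased moment ȳ² − s²/n for μ² in the denominator —
without that correction the estimator is ~20% low at triplicate sample
sizes and the exact test becomes anti-conservative. The common dispersion
pools the same moments across all expressed genes (the *median* of
per-gene estimates is badly biased low at 2 df and is not used). Per-gene
estimates are shrunk toward the common value with prior weight 20 against
the per-gene residual df.

**Test.** Counts are rescaled to the common library scale and summed per
group. Group sums of n iid NB(μ, φ) variables are NB with size n/φ;
conditioning on the total s, the first group's sum follows a beta-binomial
BB(s, n₁/φ, n₂/φ) — binomial(s, n₁/(n₁+n₂)) in the Poisson limit φ → 0.
The two-sided p sums all outcome probabilities not exceeding the observed
one (enumeration for s ≤ 5000; a continuity-corrected normal approximation
to the beta-binomial above that). Genes with zero counts everywhere get
p = 1 and an `untestable` flag. log₂FC uses normalized group means with
pseudo-count 0.5. BH FDR is applied within each contrast separately (the
convention of time-course DE tools); responsive sets take the union over
time points: induced = log₂FC > log₂ 1.5 and FDR < 0.001 at ≥ 1 time,
repressed symmetric; a gene passing both directions at different times is
double-listed with a warning.

**Calibration** (verified by the acceptance checks): on a 2000-gene null
at φ = 0.1 the test yields P[p < 0.05] ≈ 0.05; with the default generator,
> 90% of genes with planted fold ≥ 4 are recovered at FDR < 0.001 while
< 0.5% of stable genes are called.

## Timing clusters

Induced-gene profiles are log₂(normalized count + 1), averaged over
replicates per time and mean-centered per gene; k-means (k = 8, k-means++,
best of 50 starts, fixed seed) partitions them. Clusters are relabelled
1…k by a timing score: the earliest time at which the centroid reaches 50%
of its maximum positive deviation, ties broken by the positive-mass-
weighted mean time; centroids with no positive deviation sort last, with a
warning. The half-max statistic is an artifact decision — any monotone
"earliness" functional would do — and is recorded with the outputs.

## Differential marking (MA rescaling)

For each mark and contrast (time t vs 0 h, or treated vs control at one
time), M = log₂(level_t/level₀) and A = (log₂ level_t + log₂ level₀)/2. A
robust line M = a + b·A is fitted by IRLS with the Tukey bisquare
(c = 4.685, MAD scale, 20 iterations, tolerance 1e-8, OLS start) on
**anchor genes** — genes marked (both-replicate peaks) at *both* contrasted
conditions, where no systematic change is expected; at least 20 anchors are
required, else the caller is advised to pool anchors across times. The
rescaled M′ = M − (a + b·A) recenters all genes; the operation is
idempotent to numerical precision. Calls use strict inequalities at the
deliberately liberal threshold 0.15: gain if M′ > 0.15, loss if
M′ < −0.15. Both directions are always computed and reported; which
direction is biologically salient (loss for H3K27me3, gain for permissive
marks) is a *view* on the output, not a computation. Rescaling on
gene-level summaries (rather than peak units) keeps every downstream
analysis in the same gene space; this is the one place where the
translation from peak-based normalization is a genuine modelling choice,
and it is surfaced in the output schema.

## Enrichment statistics

Representation factor RF = (k/n)/(K/N): observed overlap over the overlap
expected under independence in a stated universe. Both one-sided
hypergeometric tails are computed exactly (they share P[X = k], so
p_over + p_under − P[X = k] = 1); star annotations follow the tail RF
points to. **The universe is always an explicit argument** — all genes for
mark enrichment, genes bearing ≥ 1 mark for co-marking enrichment, all
induced genes for per-cluster category enrichment — because collapsing
these distinct universes into one default would corrupt the others. No
multiple-testing correction is applied to per-mark star annotations; BH is
applied in generic term enrichment only, where the number of categories is
open-ended. Wilcoxon rank-sum comparisons use the exact distribution for
combined n ≤ 20 and the tie-corrected normal approximation otherwise.

## Timing integration

*Rank-LOESS*: induced genes are ranked by pre-wound level (ties broken by
stable input order) and the numeric cluster label (1 = earliest) is
smoothed against rank with a tricube-weighted local linear fit (span 0.3 of
the points, evaluated at every rank) — statsmodels' lowess, which
implements exactly this estimator. Being rank-based, the curve is invariant
to any strictly monotone transform of the levels. Spearman rho between
level and label accompanies the curve (0, flagged, for constant input).
*PCA* standardizes per-mark level ranks, the numeric timing label and the
0 h expression rank, and eigendecomposes their correlation matrix; the
sign convention fixes the first variable's PC1 loading ≥ 0. *Acetylation
categories* partition induced genes into pre-acetylated without gain /
pre-acetylated plus gain / gain only / no acetylation, with an independent
H3K4me3-gain flag. *Precedence* compares first-gain times: `ac_first`
and `me3_first` require both marks to gain within the observation window
(the strict reading); single-mark gainers are kept separate, and an
inclusive tally folding them into the corresponding `*_first` group is
emitted alongside so either reading is recoverable. *Fractions* are
rendered one-decimal below 10% and to the nearest integer (half away from
zero) above — a reporting convention, not science.

## Synthetic data generator

The generator emulates the study design: NB counts, 3 replicates,
times {0, 1, 3, 6, 12} h; ChIP coverage and peaks, 2 replicates,
times {0, 1, 3, 6} h. Six planted classes (proportions 0.10 / 0.15 / 0.05 /
0.15 / 0.15 / 0.40):

| class | pre-wound marks | planted dynamics | t* |
|---|---|---|---|
| rapid_preacetylated | K9/14ac, K27ac, K4me3 | none | 1 h |
| slow_gain_ac_then_me3 | K27ac (poised) | gain K9/14ac at 1 h, K4me3 at 3 h | 3 h |
| prc2_bivalent_induced | K27me3 + K4me3 | gain K9/14ac at 3 h, lose K27me3 at 6 h | 6 h |
| prc2_only_silent | K27me3 | none | ∞ |
| repressed_lose_ac | all four active | lose K9/14ac, K27ac at 3 h | repressed from 3 h |
| stable | drawn per gene | none | ∞ |

The acetylation-before-H3K4me3 lag is one sampling step, the profile of
rapidly reprogrammed loci. Stable genes draw realistic mixed states
(P[K27me3] = 0.10; active marks at 0.65 each, 0.15 under K27me3).
Expression: counts ~ NB(μ_g · f(t) · L_r, φ = 0.1) with μ_g log-normal
(median 100, log-sd 0.8), library factors log-normal (sd 0.1), planted
folds 2^U(1,3) ∈ [2, 8] as a pulse at t* decaying geometrically, or a
sustained 1/fold drop for the repressed class. ChIP: H3 depth ~
Gamma(shape 20, mean 30) per gene/time/replicate; mark depth = H3 × state
ratio (2.5 marked / 0.4 unmarked, × or ÷ the gain fold 2.0 after a planted
gain/loss) × three multiplicative factors: a per-(gene, mark) level spread
(log-normal sd 0.4; real marking is graded, and a two-valued ratio would
leave the anchor M~A fit without leverage on A), a per-(gene, mark,
replicate) IP-efficiency factor (log-normal sd 0.15), and per-observation
measurement noise (log-normal sd 0.05). The first two factors are
persistent across time and cancel exactly in any time contrast, so the
null M′ spread (~0.07 log₂ units) is set by the measurement noise — this
decomposition is what keeps a liberal 0.15 threshold compatible with a low
false-call rate, and it mirrors real ChIP, where between-sample efficiency
varies far more than a locus's within-series reproducibility. Peaks are
emitted in the gene-body interior wherever the mark is present, dropped
per replicate with probability 0.05, with −log₁₀(Q) ~ U(5, 50); decoy
sub-threshold peaks (Q filter removes them) are sprinkled per file. The
inhibitor arm flattens induction trajectories, suppresses
acetylation/H3K4me3 gains and halves the acetylation ratio of
induced-class genes. Identical config + seed gives byte-identical files
(sha256 manifest).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level artefacts (mappability, GC,
fragment-size effects), peak-shape heterogeneity, cell-population
heterogeneity in enrichment levels (levels here are clean per-gene means),
correlated gene programs, and batch effects between time points.

## Problem sizes and determinism

Default analyses and the acceptance script run at 2000 genes — a size at
which every statistical property of interest (calibration, power,
recovery) is measurable with comfortable margins while a full double
pipeline run completes in seconds. Unit tests use 600 genes. All
randomness flows from explicit integer seeds through numpy Generators;
k-means uses a fixed `random_state`; two pipeline runs at the same
config + seed produce byte-identical outputs, which the acceptance suite
verifies file by file.

## Known limitations

- The NB exact test assumes a common dispersion model per gene with
  moment-based estimation; very-low-count genes have little power and
  genes with zero counts are flagged rather than tested.
- Anchor-based MA rescaling extrapolates the robust line to unmarked
  genes; with few anchors or anchors confined to a narrow A range the
  rescaled values for distant genes are less reliable (the 20-anchor floor
  is a guard, not a guarantee).
- Precedence timing is resolved only to the ChIP sampling grid; a lag
  smaller than one sampling step is indistinguishable from simultaneity.
- No GO DAG propagation, no chromatin-state segmentation, no
  deconvolution of cell-population mixtures.
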