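# Methods

## Study design the package models

A triad RNA-seq design: one F1 hybrid and its two parents, each with
biological replicates, summarized as a gene × sample matrix of integer
counts. The three pairwise contrasts — F1 vs parent 1 (`F1vsP1`), F1 vs
parent 2 (`F1vsP2`), and parent 1 vs parent 2 (`P1vsP2`) — carry all the
information needed to place the hybrid's expression level relative to its
parents. Sign conventions: `F1vsP1`/`F1vsP2` log2 fold changes are positive
when the hybrid is higher; `P1vsP2` is positive when parent 1 is higher.

Alongside the transcriptome, replicated trait tables (leaf dry-weight
biomass, photosynthetic parameters) for a panel of parents and hybrids
measured over a time course support the mid-parent heterosis statistics.

## Differential expression

Counts are normalized with median-of-ratios size factors: for each sample,
the median over genes (restricted to genes with nonzero counts in every
sample) of the ratio of its count to the gene's across-sample geometric
mean, rescaled so the factors have geometric mean 1. If no gene is
expressed everywhere, total-count factors are used with a warning.

Per-gene NB dispersion is estimated by the method of moments on normalized
counts: within each genotype group, φ̂_g = (s² − m)/m²; groups are pooled
with weights n_g − 1 and the result floored at 1e-8 (genes whose variance
does not exceed their mean get the floor). A single global mean–dispersion
trend is deliberately not fitted: the per-gene moment estimator keeps the
test's behaviour analytically predictable, and a trend is a config
extension point.

The contrast test is a Wald test on the log of the fitted group means:
Δ = log μ̂_B − log μ̂_A, SE² = (1/μ̂_A + φ̂)/n_A + (1/μ̂_B + φ̂)/n_B (delta
method on the NB variance μ + φμ²). With three replicates per group the
plug-in dispersion carries very few degrees of freedom, so a normal
reference is badly anti-conservative; p-values therefore use a *t*
reference with the pooled residual degrees of freedom used for dispersion
estimation (6 for a 3 × 3-replicate triad). Under the simulated null
(φ = 0.05, n = 3) this puts the empirical type-I rate at ≈ 0.04–0.05; the
test suite asserts the [0.03, 0.08] band. Genes with both group means zero
are assigned p = 1 and log2FC = 0; a group mean of exactly zero is floored
at 0.5 for the Wald statistic. The *displayed* fold change is
log2((μ̂_B + c)/(μ̂_A + c)) with pseudocount c = 1, which is intentionally
shrunk (and mildly depth-dependent) at very low counts; the test itself
uses the fitted means.

A gene is a DEG when p < 0.05 (strict) **and** |log2FC| ≥ 2 (inclusive).
Screening uses raw p by default; `DEConfig.use_adjusted` switches the
screen to BH-adjusted p. Genes are pre-filtered to those with nonzero mean
in all three genotypes (the triad detection intersection) before testing,
and size factors/dispersions are shared across the three contrasts.

The package implements this test itself rather than wrapping an external
DE tool; on simulated triads the significant sets agree with a DESeq2-style
reference (pydeseq2) with Jaccard ≈ 1 at these effect sizes, which the test
suite checks as an independent cross-validation.

## Expression-pattern classification

Each DEG (by default the union of the three contrasts' DEG sets; a flag
restricts to hybrid-vs-parent DEGs) is classified from its three
significance calls, their directions, and the genotype means:

| category | codes | rule |
|---|---|---|
| up-overdominant | P10–P12 | F1 significantly above both parents |
| down-overdominant | P7–P9 | F1 significantly below both parents |
| dominant | P3–P6 | parents differ; F1 indistinguishable from exactly one parent |
| additive | P1–P2 | parents differ; F1 differs from both and lies strictly between the parental means |
| unclassified | — | anything else |

"Indistinguishable" is significance-based — the corresponding contrast
fails the DE screen — not tolerance-based, so classification uses exactly
the machinery that produced the DEG calls. Sub-codes record the parental
relationship (parent 1 below / indistinguishable from / above parent 2 for
overdominance; which parent is matched and whether it is the high or low
parent for dominance). The sub-code numbering is this package's convention;
its only structural commitment is the parent-swap symmetry (P1↔P2, P3↔P4,
P5↔P6, P7↔P9, P10↔P12, P8 and P11 fixed), which is property-tested against
an exhaustive enumeration oracle.

A structural consequence of the |log2FC| ≥ 2 screen worth knowing: a
mid-parent expression level can differ from the *high* parent by at most
one log2 unit (the mid-parent of means μ and μ·2^d is within 2× of the high
parent for every d), so additive genes can essentially never satisfy the
fold-change screen against both parents. Under these thresholds the
additive share among classified DEGs is structurally driven toward zero —
which is exactly the regime the default simulation encodes (0.13% additive
among designed DEGs).

Percentages in pattern summaries are over classified (non-unclassified)
genes, so the category shares sum to 100%; the unclassified count is
reported separately.

## Mid-parent heterosis

MPH(%) = (F1 − MP)/MP × 100, with F1 the hybrid's replicate-mean trait
value and MP the mean of the two parents' replicate means, per hybrid and
timepoint. Consecutive-interval deltas MPH(t+1) − MPH(t) identify the *key
period*: the interval of maximum MPH increase, with exact ties broken to
the earliest interval and no key period flagged when no interval rises.
Both per-hybrid deltas and across-hybrid means of the MPH curve are
reported.

Duncan's new multiple range test supplies compact letter displays at a
timepoint: one-way ANOVA gives the pooled error mean square MSE with
df = N − k; means are sorted descending and a stretch of p means is
homogeneous when its range ≤ LSR_p = q(α_p; p, df)·√(MSE/ñ), where
α_p = 1 − (1 − α)^(p−1) is Duncan's protection level, q the studentized
range quantile, and ñ the harmonic mean of group sizes (the usual
convention for unbalanced data). Once a stretch is declared homogeneous no
inner stretch is split. With two groups the procedure reduces exactly to
the pooled-variance LSD/t-test, which the suite verifies on random
instances. Zero within-group variance degenerates gracefully: LSR = 0, so
only exactly equal means share a letter. The largest mean always holds
letter "a".

## Enrichment

Over-representation of a query gene set against a background universe and
flat term maps: p = P(X ≥ k), X ~ Hypergeometric(N, K, n), computed via the
survival function in log space (scipy), exact against brute-force
combinatorial summation to 1e-12 relative error on all instances with
N ≤ 60. BH adjustment across terms; rich factor k/K. Significance is
flagged at raw p ≤ α (inclusive) by default with a padj option. The
recommended background is the set of genes passing the triad detection
filter, not the whole annotation; term maps are flat — ontology-graph
ancestor propagation, if wanted, must be done upstream.

## qPCR

2^−ΔΔCt with amplification efficiency fixed at 2 and no efficiency
correction. Replicate Cts are averaged per (gene, genotype) before
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator genotype's
ΔCt, so the calibrator maps to exactly 1.0. The reference gene and
calibrator are required inputs. Concordance against RNA-seq is the fraction
of shared genes with matching log2-fold sign plus the Spearman correlation
of log2 folds (≥ 3 shared genes required).

## Synthetic data: what it emulates and what it does not

`simulate_triad` draws NB counts (single global dispersion, default
φ = 0.05; default 3 replicates) around designed genotype means. Baseline
abundances are log-uniform over [50, 5000]; "different" states are
separated by `effect_log2fc` (default 3) on the log2 scale. Dominant F1
means equal the matched parent exactly; additive F1 means are the
arithmetic mid-parent; overdominant F1 means exceed (or undercut) both
parents by the full effect. Default pattern proportions put 30% of genes
in the DEG compartment with category shares 0.13% additive / 23.18%
dominant / 76.69% overdominant (split evenly within categories), matching
the regime the pipeline targets; the default gene count is 13,587, a
typical triad detection-intersection size for a plant transcriptome.
Library-size factors default to 1.0; `lognormal_libsize_factors` provides
log-normal(0, 0.1) factors to exercise normalization.

Not modeled: zero inflation, a mean–dispersion trend, batch effects,
isoform-level signal, correlated genes. Passing recovery tests on this
generator therefore demonstrates the pipeline's correctness under a clean
NB triad — not robustness to those real-data complications.

`simulate_biomass` gives parents logistic growth curves (asymptote, rate,
midpoint; defaults span 65–95 g dry weight, rates 0.10–0.13/day, midpoints
52–56 days) and sets each hybrid mean to MP·(1 + MPH/100) from a designed
schedule, with multiplicative log-normal replicate noise of mean exactly 1
and CV `noise_cv` (default 0.05 — a realistic replicate CV for dry-weight
measurements; the replicate dispersion is a free parameter of the design).
Zero noise makes `mph_series` the exact inverse of the schedule (machine
precision); at 5% CV the recovered MPH is unbiased to well under one
percentage point over seed replicates. The default panel crosses five
parents into six hybrids over days 38–66 at 7-day intervals; the flagship
hybrid's schedule rises 14.99 points over days 45–52 (its designed key
period), falls 12.90 points to day 59 and rises 5.68 points to day 66,
with 22.50% MPH at day 45.

`simulate_term_map` plants overdominant-up/-down genes into designated
terms at 60% membership against uniform null terms, giving the enrichment
stage a designed positive and a calibrated null.

## Numerical choices and degenerate inputs

- Dispersion floor 1e-8; zero group means floored at 0.5 inside the Wald
  statistic only.
- t reference with pooled residual df for DE p-values (see above).
- Key-period ties break to the earliest interval; constant MPH flags none.
- Duncan with MSE = 0 treats distinct means as significantly different.
- BH adjustment is statsmodels' step-up; values validated to [0, 1].
- Largest-remainder apportionment assigns gene counts to pattern
  proportions, so truth shares match configs up to integer rounding.
- All generators take explicit integer seeds; identical seeds give
  byte-identical outputs.

## Problem sizes used by the test suite and acceptance script

The suite's recovery checks run at 2000–5000 genes; null calibration at
2000 genes; DE power at 200 single-gene Monte-Carlo seeds; MPH bias at
200–500 seed replicates of the 11-variety panel; the hypergeometric oracle
enumerates every instance with N ≤ 60; the permutation null uses 100 terms
× up to 1000 uniform queries. The acceptance script runs the full pipeline
once at the default 13,587-gene study conditions and averages heterosis
recovery over 200 panel replicates. These sizes were chosen to make the
Monte-Carlo bands tight relative to the asserted tolerances.

## Known limitations

- The NB Wald test with moment dispersions is minimal by design: no
  shrinkage, no covariates, no outlier handling. Exact numerical agreement
  with DESeq2/edgeR is not a goal; threshold semantics and calibration are.
- Classification inherits the DE screen's discreteness: genes near the
  fold-change threshold can flip sub-codes between seeds.
- Flat term maps only; no GO DAG propagation.
- Better-parent (high-parent) heterosis is not computed, only MPH.
- The CLI's `run` report is deterministic given the seed, but stage TSVs
  embed a config hash, so byte-identity across runs requires identical
  configs including the output directory.
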