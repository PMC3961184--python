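# Methods

`resistscope` implements the statistical chain used to dissect a strong
carbamate-resistance phenotype in *Anopheles gambiae*: candidate-gene
discovery from two-colour expression microarrays, qPCR confirmation of
over-expression and of *ACE-1* copy-number variation, TaqMan G119S
genotype calling with dye-balance analysis, and organism-level
phenotype statistics (synergist bioassays, dose-response LC50s,
discriminating-dose tests, in-vitro substrate depletion). Every stage
is paired with a synthetic-data generator that plants known truth, so
the whole chain is testable without access to the original arrays.

## Differential expression

Two-colour arrays are modelled at the normalized log-ratio (M) level.
Each array contributes one linear equation

    M_probe = offset[cy5 group] − offset[cy3 group] + ε,

and per-probe group offsets are estimated by ordinary least squares
with one group's offset fixed at zero. The same estimator serves both
designs in scope — the pairwise full dye-swap layout (two resistant
Tiassalé groups, selected and unexposed, against three susceptible
populations) and the 18-array fully interwoven loop over three field
populations. A requested resistant-vs-susceptible comparison is a
linear contrast of the fitted offsets, with standard errors from the
per-probe residual variance. Disconnected designs are rejected with
the offending group components named; probes observed on a subset of
arrays are fitted on their available equations and flagged untestable
when no residual degrees of freedom remain.

Because any per-probe dye preference enters M with a fixed sign (it is
a cy5-vs-cy3 effect), it cancels exactly in the normal equations of a
dye-swap pair; the simulator plants such biases specifically so tests
can confirm the cancellation.

Variance moderation shrinks per-probe residual variances s² toward the
across-probe mean s0² with posterior variance
(d0·s0² + d·s²)/(d0 + d) and t tests on d0 + d degrees of freedom.
The prior df d0 is set by a method-of-moments match: spread of the s²
beyond the chi-square scatter expected at the probes' residual df is
attributed to true variance heterogeneity v, and d0 = 2·s0⁴/v (infinite
— complete pooling — when no excess spread is observed). This is a
deliberate simplification of the log-scale empirical-Bayes fit used by
limma-style packages; it reproduces the two limits that matter for the
pipeline (per-probe testing as d0 → 0, pooled-variance z tests as
d0 → ∞) and calibrates well in null simulations (Kolmogorov–Smirnov
distance of p-values from Uniform(0,1) below 0.02 at 10,000 probes).
Benjamini–Hochberg q-values are computed within each pairwise
comparison, each comparison being its own multiple-testing family.

## Consensus filtering

A probe passes an experiment only if (i) its fold-changes share one
sign in every resistant-vs-susceptible comparison, (ii) every
comparison has q < α (strictly; default α = 0.05, boundary ties fail),
and (iii) — in the design with a bendiocarb-selected group — for every
(selected, unexposed) comparison pair sharing a susceptible partner the
selected fold-change has the same sign and strictly larger magnitude.
Criterion (iii) is the escalation rule: expression differences should
track the resistance gradient, which filters out genes associated with
some other exposure. "More extreme" is formalised as same-sign larger
absolute log2 fold-change so that consistent under-expression is
admissible. Probes missing any planned comparison are marked
unevaluable rather than failed. Overall significance requires
significance in both experiments; probes present in only one are
"untested" and excluded. Genes are summarised by significant/total
probe counts with the representative fold-change taken as the median
over significant probes.

## qPCR quantitation

Relative expression follows the comparative-Ct method with per-amplicon
efficiency correction. Technical replicates are averaged on the Ct
scale, each amplicon's relative quantity is (1+E)^(−Ct), the target is
normalised by the geometric mean of the reference-gene quantities
(the combination rule for multiple stable references), and group
fold-changes are taken against the calibrator-group mean. With all
E = 1 this is exactly the textbook 2^(−ΔΔCt) form. Per-group
over-expression is tested on log2 normalised expression with a pooled
or Welch two-sample t chosen by a two-sided F test for equality of
variances at α = 0.05.

Copy number uses the same arithmetic on genomic DNA: three target-gene
amplicons, each normalised against two single-copy reference genes and
against the geometric mean of two calibrator-strain pools (calibrators
averaged on the ΔCt scale, matching subtraction of mean normalised
calibrator values). The six amplicon-by-reference contributions are
averaged on the ratio scale by default (`scale="ddct"` averages on the
log scale instead; the choice is unidentified from the protocol
description and the difference is second-order). A ratio strictly
above 1.5 — one extra allele against a two-copy calibrator — flags a
duplication carrier; a ratio of exactly 1.5 is below threshold, with a
1e-9 relative guard so floating-point round-trip error cannot flip a
boundary call. Survivor-vs-dead copy-number contrasts use an unequal-
variance (Welch) t test.

## TaqMan genotyping

Endpoint FAM (serine, resistant) and VIC (glycine, wild-type)
fluorescence is reduced to an angle atan2(FAM, VIC). Homozygote
reference angles are anchored on the plate's SS and GG control wells;
the heterozygote reference is fixed at 45° (the 1:1 allele-balance
line) rather than estimated, because *ACE-1* duplication skews the
empirical heterozygote cluster toward FAM. Samples are assigned to the
nearest reference angle and no-called when total fluorescence falls
below 20% of the mean control total or the nearest reference is more
than 15° away. Both guards are exposed as parameters; the original
calls were made qualitatively, so explicit rules had to be chosen, and
these two make the caller scale-invariant and conservatively abstain on
ambiguous wells. Heterozygote dye balance (FAM/VIC) is compared
between bioassay survivors and dead with a Welch t test on raw ratios
(a log-ratio option exists); an excess serine:glycine balance in
survivors is the signature of extra serine copies.

Population statistics: serine-allele and heterozygote frequencies with
Wilson 95% intervals; a 1-df chi-square goodness of fit to
Hardy–Weinberg proportions; Pearson 2×2 association chi-square without
continuity correction plus an odds ratio with Woolf (log-scale) 95%
interval, Haldane–Anscombe +0.5 on all cells when any cell is empty;
and Woolf's test for homogeneity of odds ratios across strata
(inverse-variance weights on log odds ratios, chi-square on k−1 df).
Woolf's method was chosen for the unnamed homogeneity statistic;
Breslow–Day is available through `statsmodels.stats.contingency_tables`
for cross-checking.

## Phenotype statistics

WHO-bioassay replicates are pooled per condition with Wilson 95%
binomial intervals (Clopper–Pearson behind a flag). Synergism is the
odds ratio of mortality with PBO pre-exposure versus insecticide alone
on season-pooled counts, with Woolf interval and Pearson chi-square.

Dose-response fitting regresses survival proportion on log10 dose over
the partial-response range (0 < survival < 1) and inverts at 0.5:
LC50 = 10^((0.5 − intercept)/slope), with a 95% interval from
Fieller's theorem on the log10-dose scale. The linear-in-log-dose form
matches how these assays are plotted and fitted in practice; a probit
link is not used. Profiles with fewer than three partial-response
doses (sharp inflection) are refused with a pointer to the
discriminating-dose test, which reports the ratio of mean per-vial
survival between lines and an exact two-sided Mann–Whitney p. The
exact test enumerates the permutation distribution of U over all
assignments of the pooled observations (average ranks, so ties are
handled exactly) whenever n1 + n2 ≤ 20 — the smallest achievable
two-sided p for two groups of eight is 2/12870 ≈ 0.000155 — and falls
back to the tie-corrected normal approximation above that.

Substrate depletion is 100·(1 − mean(test)/mean(control)) from HPLC
peak areas against no-NADPH controls, with the standard deviation taken
over per-replicate ratios; negative point estimates are clamped to 0%
with the raw value retained and flagged.

## Synthetic data and what it does (not) show

The generators plant truth for every stage: group expression offsets
on the M scale with per-array effects, per-probe dye bias and Gaussian
noise; TaqMan clusters on rays from the origin with truncated-normal
signal and Gaussian angular scatter, including duplication-shifted
heterozygotes at a 1.5:1 dye ratio (56.31°); Ct tables via
Ct = base − log(quantity)/log(1+E), which invert exactly through the
quantitation closed forms at zero noise; binomial bioassay counts; and
dose-response survival from the same linear-in-log10-dose model the
fitter assumes (a logistic alternative exists for robustness checks).
All randomness flows from explicit seeds; fixed seed means
bit-identical output.

Default study conditions mirror the designs being emulated: 2–3
biological replicates per group on the arrays with noise sd 0.25 log2
units; 3 technical qPCR replicates at Ct noise sd 0.15; two calibrator
pools; four bioassay replicates of 25; eight vials per line at the
0.1 µg discriminating dose. The bundled full-study simulation plants
seven consensus resistance genes plus decoys perturbed in only one
experiment, duplication carriers at four copies (three copies sits
exactly on the strict 1.5 threshold and would be a coin flip under
noise), and a 15/16 vs 5/16 carrier split between survivors and dead.

What passing tests do not show: the generators draw independent
Gaussian noise per probe and array — no spatial artefacts, intensity-
dependent dye effects, cross-hybridisation, or qPCR inhibition — so
recovery results bound what the estimators can do under their own
assumptions, not under real-array pathology. The dose-response
generator shares the fitter's mean model, so noise-free recovery is an
inversion identity rather than evidence about model misspecification.
Duplication-shifted heterozygotes lying near the SS/GS angular midline
can be called homozygous-resistant by the fixed-reference caller; real
analyses resolve these by eye, and the no-call guard only partially
substitutes.

## Numerical choices and edge cases

* Strict inequalities at every threshold (q < α, ratio > 1.5); ties
  fail, read conservatively.
* Probes with zero residual df carry NaN t and p and a `tested = False`
  flag rather than being dropped; testing errors only when no probe has
  residual df.
* Two-sided p throughout; direction is handled by the consensus
  filter, not by one-sided tests.
* The 2×2 association chi-square uses raw counts even when the odds
  ratio needs the Haldane correction; a zero margin is an error, not a
  degenerate value.
* Identical groups short-circuit to p = 1 in the t-based contrasts
  (zero variance in both groups with equal means).
* Null-calibration checks for the discrete 2×2 test are run at group
  sizes where the asymptotic chi-square null applies (1000 per arm);
  at a few hundred per arm the attainable p-value lattice alone holds
  the KS distance near 0.04 regardless of implementation.

## Known limitations

The per-probe least-squares model intentionally replaces the two
different proprietary analysis engines used on the original data with
one well-specified estimator; numerical agreement with those engines'
output is out of scope, as are annotation clustering, raw-scan
normalisation, standard-curve efficiency estimation and multi-factor
mortality models. Integer copy number beyond the binary 1.5-threshold
call is reported as an estimate (2 × ratio) but only the binary call is
claimed. Reported problem sizes in the bundled simulations (hundreds
of genes, thousands of probes) are chosen to keep the full test suite
fast while leaving every estimator in its asymptotic operating regime;
all scale linearly if enlarged.
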