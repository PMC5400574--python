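# Methods

## Data model

The unit of analysis is a case-control cohort genotyped at one
biallelic SNP with effect allele C: six non-negative counts (TT/TC/CC
in cases and controls) plus stratification metadata (ethnicity from the
closed set {Caucasian, Asian, African, other}; source of controls HB =
hospital-based or PB = population-based; arbitrary extra labels).
`study_id` values may repeat — a single publication can contribute
several independent cohorts, and each row is pooled as its own unit. A
reported Hardy-Weinberg flag, when present in the input, is carried
through but never used: the pipeline always recomputes HWE from the
counts (the packaged fixture contains reported flags that the Pearson
test provably cannot produce, e.g. a "fail" on a monomorphic cohort).

## Genetic-model contrasts and informativeness

Each contrast collapses the 3-genotype table to a 2×2 with cells
a/b (case events/non-events) and c/d (controls). The allele contrast
counts the 2N alleles of N subjects as independent observations — the
standard approximation in this literature, slightly anti-conservative
under Hardy-Weinberg departure. The homozygote and heterozygote
contrasts drop the excluded genotype's carriers entirely, so their
margins are smaller than the cohort.

A 2×2 is *informative* when events occur in at least one arm and
non-events in at least one arm, judged **before** any continuity
correction. Non-informative cohorts are excluded from pooling for that
contrast only (a fully monomorphic cohort therefore never contributes;
a cohort with a couple of heterozygotes contributes to heterozygote,
dominant and allele contrasts but not to the CC-event contrasts). This
exclusion rule, rather than imputation, is what makes per-contrast
study counts differ.

## Continuity correction

Default policy: if any of the four cells of an informative table is
zero, add 0.5 to **all four cells** of that study (only). This is the
convention of the mainstream meta-analysis packages and keeps every
per-study log OR and its Woolf variance finite. The policy is a
configuration knob (`ContinuityPolicy.NONE` disables it) so its
influence can be probed; with correction off, a remaining zero cell
raises rather than silently propagating ±inf.

## Pooling

Per-study effect: log OR with SE `sqrt(1/a+1/b+1/c+1/d)`; 95% CIs are
Wald intervals on the log scale with z = 1.959964 throughout, so a CI
excluding 1 is equivalent to two-sided p < 0.05 by construction.

Fixed effects default to Mantel–Haenszel (point estimate
`sum(a_i d_i/n_i)/sum(b_i c_i/n_i)`, variance of the log by
Robins–Breslow–Greenland), which is robust with sparse cells;
inverse-variance fixed pooling is available and the two agree well
within rounding on large-count data. Cochran's Q is always computed
with inverse-variance weights around the inverse-variance fixed
estimate, so heterogeneity (and hence I² and τ²) does not depend on
the MH/IV choice. I² = max(0, (Q−df)/Q)·100, defined as 0 when Q = 0.
Random effects use the DerSimonian–Laird moment estimator
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), truncated at zero; no iterative
(REML / Paule–Mandel) estimators are offered. With τ² = 0 the
random-effects result coincides exactly with inverse-variance fixed
pooling.

Model selection follows the conventional heterogeneity rule: random
effects iff p_Q < 0.1 or I² > 50% (both strict), else fixed.

## Subgroups and sensitivity

`subgroup_analysis` re-runs the entire contingency → pooling pipeline
inside each category of a grouping label, including per-stratum
informativeness and, by default, per-stratum fixed/random selection.
A `force_method` option instead pins one method across strata; the
report layer uses it to apply the method selected on the overall
analysis of each contrast, which is how a single subgroup
meta-analysis command in the standard packages behaves and is the
convention the packaged fixture's published analysis follows (its
hospital-based strata are only reproduced under the overall method).
Heterogeneity p-values per stratum are unaffected by this choice.

`leave_one_out` re-pools k times, each omitting one informative cohort,
re-selecting the method per subset. The pooled estimate of any subset
necessarily lies within the range of the remaining per-study log ORs.

## Publication bias

Egger: OLS of θ_i/SE_i on 1/SE_i, two-sided t test of the intercept
with k−2 df. Degenerate when all SEs are equal (constant regressor).
Begg–Mazumdar: Kendall correlation between v_i and the standardized
deviations (θ_i − θ̂_IV)/√(v_i − v̂_IV); when v_i ≤ v̂ (a study more
precise than the pooled estimate cannot occur, but equality can
numerically) the difference is floored at 1e-10 with a logged warning.
z uses var(S) = k(k−1)(2k+5)/18 with a continuity correction
(|S| − 1). Both tests require k ≥ 3 and are order-invariant. Under a
null simulation both hold their size, Begg conservatively — its
empirical rejection at α = 0.05 sits below nominal at k = 15.

## Hardy-Weinberg and power

HWE: plain Pearson χ² with 1 df (one estimated allele frequency), no
continuity correction; expected counts n(1−q)², 2nq(1−q), nq² at the
observed control allele frequency q. Monomorphic samples (q ∈ {0,1})
are "not assessable" — the test statistic would be identically zero.

Power: allele-contrast normal approximation. The case allele frequency
is solved from odds(q′) = OR·odds(q); the SE of the log OR comes from
the expected 2×2 allele table at the design's sample sizes (2 alleles
per subject); power = Φ(|ln OR|/SE − z_{1−α/2}) + Φ(−|ln OR|/SE −
z_{1−α/2}), which equals α exactly at OR = 1. This is a design-stage
approximation: it ignores between-study heterogeneity and treats the
pooled data as one stratum, so it should be read as an upper-bound
style summary of the evidence base's size, and the pipeline's
lower-bound check (power ≥ 0.99 for the fixture at OR 0.76) reflects
that reading.

## Synthetic data generator

Defaults mirror the structure of the packaged fixture: k = 16 cohorts,
a protective true allele OR of 0.76, control MAF uniform on
(0.05, 0.45), per-arm sizes uniform on 200–2500, and τ = 0 unless
heterogeneity is being studied. Controls are multinomial under HWE at
the drawn frequency; each study's log OR is ln(OR) + N(0, τ²); cases
are multinomial under HWE at the frequency implied by the study OR.
Generating cases under HWE at the case frequency matches the
allele-contrast analysis the recovery experiments target; it does not
encode genotype-specific penetrance, dominance at the genotype level,
linkage disequilibrium, or selective publication, so passing
calibration says nothing about robustness to those features of real
data. Metadata is assigned round-robin over
{Caucasian, Asian, African} × {HB, PB}, guaranteeing non-empty strata
for k ≥ 6. All randomness flows through one `numpy` Generator seeded
from the config, so a fixed seed reproduces tables bit-for-bit;
replicate seeds are spawned from a `SeedSequence` and kept below 2³¹.

Calibration and recovery experiments use 500 null replicates (k = 15)
for type-I error and 200 replicates of k = 50 cohorts at 500–1500
subjects per arm for parameter recovery — sizes at which Monte-Carlo
error is small relative to the bands being checked while the full run
stays in the tens of seconds.

## Numerical and degenerate-input choices

* All pooling is on the log-OR scale; exponentiation happens only at
  the reporting boundary.
* k = 1 pooling is the identity (Q = 0, I² = 0, p_Q undefined → NaN);
  DL requires k ≥ 2 because τ² has no degrees of freedom otherwise.
* Rounded `*_2dp` columns are emitted next to full-precision values in
  every TSV so comparisons with two-decimal published tables are
  explicit; rounding is Python's round-half-to-even.
* Empty strata report as absent (`None`) rather than erroring; an
  entirely empty analysis (no informative model) is an error.

## Known limitations

Odds ratios only (no risk ratio/difference, no Peto), no
Hartung-Knapp small-k adjustment, no meta-regression, no trim-and-fill
or selection models, no exact HWE test, no multi-allelic or
X-chromosome support. The allele-contrast independence approximation
and the design-stage power formula are the two places where the
classical machinery is knowingly approximate.
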