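# Methods

This note documents the statistical procedures implemented in `reosig`,
the assumptions behind the synthetic-data generator, and the design
choices made where the procedure left room for interpretation.

## The REO model

The unit of information is the within-sample comparison of two genes'
expression values: the indicator `E_i > E_j`. Because the indicator
depends only on the ordering of two values measured in the same sample, it
is invariant to any strictly increasing transform of that sample's values.
Everything downstream of pair orientation — votes, confusion counts,
accuracy, the binomial screen, signature scores, classifications and the
rank-based AUC — is a function of these indicators and therefore inherits
the invariance. Two quantities are *not* invariant and are documented as
such: the ED statistic (it averages raw differences) and the Wilcoxon
screen p-value (it ranks raw differences across samples). Both are used
only to orient and pre-filter pairs on the training set, never to score a
new sample.

Ties `E_i = E_j` vote non-responder: the responder-indicating pattern is
the strict ordering. On continuous expression data ties have probability
zero; on heavily rounded data this choice makes votes conservative.

## Screening statistics

**Response genes.** For each gene, Spearman's ρ against the continuous
lesion-size measure, average ranks for ties, two-sided p-value from the t
approximation `t = ρ √((n−2)/(1−ρ²))` with n−2 degrees of freedom. A full
permutation enumeration is available (`method="exact"`) for n ≤ 10, where
the t approximation is least reliable. Retention requires `p < 0.05` and
`|ρ| > 0.3` (both configurable). No multiple-testing correction is applied
at this stage by design: the screen is a permissive pre-filter whose false
positives are removed by the later, stricter pair screens.

**Pair orientation.** `ED_ij` is the responder-group mean of `E_i − E_j`
minus the non-responder-group mean. The orientation with `ED > 0` is kept;
`ED = 0` (no orientation signal) drops the pair. Swapping the genes negates
ED, so each unordered pair yields at most one oriented record.

**Wilcoxon screen.** Two-sided rank-sum test on the per-sample differences
`E_i − E_j` between response groups. The difference view is used rather
than the binary vote because a rank-sum test on a 0/1 variable degenerates
into a proportion test, while the differences retain the ordering-strength
information and keep the test's null exactness. The exact null
distribution is used when the pooled size is ≤ 25 with no ties, the normal
approximation with tie correction otherwise (the scipy implementation of
both).

**Binomial screen.** Each pair votes every labeled training sample; the
number of correct votes is compared against Binomial(n, p₀) with a
one-sided exact upper-tail p-value, where p₀ defaults to the majority-class
proportion (the no-information rate; 36/47 for the canonical training
split). A pair passes at `p < 0.05`. Null proportion and sidedness are
package choices: the no-information rate is the weakest classifier one
should have to beat, and only better-than-null accuracy is of interest.

**Power.** `power_spearman` implements the critical-r construction used by
standard correlation power calculators: the critical correlation from the
t distribution with n−2 df, then a normal comparison on the Fisher-z scale
with standard deviation `1/√(n−3)` and small-sample mean correction
`r/(2(n−1))`. At the screening design (n=21, r=0.3, α=0.05) it gives
0.268. The test suite cross-checks it against a Monte-Carlo simulation of
the actual Spearman test; the simulation is compared at the rank-scale
correlation `(6/π)·asin(r/2)` of a bivariate normal, since the analytic
formula is on the Pearson scale. `power_wilcoxon_mc` is a plain
Monte-Carlo under a normal location-shift alternative; no analytic form is
claimed because rank-sum power depends on the full alternative
distribution, and the suite cross-checks it against the Lehmann normal
approximation.

## Forward selection

Candidates (pairs surviving both screens) are ordered by descending
accuracy, then ascending Wilcoxon p, then gene ids — a fully deterministic
ordering — and capped at 10,000. The 20 best candidates each seed a greedy
growth; at every step all remaining candidates are scanned and the one
giving the largest strict increase in training accuracy is added (first in
candidate order on ties); growth stops when no addition strictly improves
accuracy, or at a safety cap of 11 pairs. The best seeded signature wins,
with ties broken toward fewer pairs, then seed order.

**The responder call during the search uses a fixed score cutoff of 2**
(`call_threshold`), not a size-adaptive majority. This is the one place
where the package had to commit to an interpretation, and the fixed cutoff
is chosen for two reasons. First, it is the only classification rule the
source procedure ever states ("responder if the score reaches 2"), applied
uniformly. Second, a size-adaptive majority makes the search degenerate:
a single accurate pair under a 1-of-1 rule often fits a small training set
almost perfectly, so no second pair can *strictly* improve accuracy and
the search can never reach a multi-pair signature; conversely an AND rule
at size 2 almost always loses accuracy relative to the seed. With a fixed
cutoff of 2, one pair alone classifies (almost) everyone non-responder,
two pairs form an AND, three pairs form the 2-of-3 vote — the trajectory
1 → 2 → 3 strictly improves whenever complementary informative pairs
exist, and stops when they are exhausted. The returned signature's vote
threshold is `min(call_threshold, size)`; `default_threshold` (strict
majority, `⌊k/2⌋+1`) remains the default for user-assembled signatures and
coincides with the fixed cutoff at the canonical size of three.

No internal cross-validation is performed during selection: reported
training F-scores are apparent accuracies and should be read as such.

## Survival validation

Kaplan–Meier estimates per predicted group; Cox proportional-hazards fits
(lifelines, Efron tie handling) with the responder indicator coded 1, so
HR < 1 means predicted responders progress later. The multivariate fit
adds user-named clinical covariates, one-hot encoding categorical columns
(first level dropped). CIs are 95% Wald intervals on the log-HR scale.
With a single predicted group or zero events the survival part is flagged
not estimable instead of raising: a degenerate prediction is a result, not
a programming error.

## The synthetic-data generator

The generator emulates the data structure the pipeline consumes, with
known ground truth:

- **Background genes**: i.i.d. Normal(7, 1.5) on a log2-like intensity
  scale, matching the location/spread of RMA-style microarray data.
- **Labels**: a fixed number of responders assigned to a random subset of
  samples (default 36 of 47, the canonical training split).
- **Lesion size**: a latent Gaussian with a +1.5 SD shift for
  non-responders, standardized; reported on a mm-like scale. Tying the
  continuous measure to the labels means the Spearman screen and the
  label-based pair screens see consistent signal, mirroring how both views
  of "response" derive from the same tumor behavior.
- **Response genes** (default 50): correlation `lesion_corr` (default 0.5,
  comfortably above the 0.3 screening cutoff) with the standardized lesion
  latent, random sign, unit residual variance.
- **Planted pairs** (default 3): both genes share a lesion-correlated
  center (anti-correlated with lesion: the responder-indicating gene runs
  high in responders, who have smaller residual lesions) and are split by
  an oriented half-gap of 0.25 + |Normal(0, 0.75)|; the orientation
  encodes the responder-indicating ordering and flips independently per
  sample with probability `planted_flip_prob` (default 0.05, putting
  single-pair training accuracy near the canonical 0.95). The
  center-sharing construction keeps each planted pair discoverable by the
  lesion screen, as the candidate-pair rule requires, at the cost of
  slightly non-background marginals for pair genes.
- **Survival**: exponential event times, responder hazard log(2)/10 per
  month (10-month median PFS), non-responder hazard scaled by
  `hazard_ratio_true` (default 2.0, i.e. responder-coded HR 0.5);
  independent exponential censoring with its rate solved from the target
  censoring fraction (default 0.2).
- **Covariates** (age, gender, stage, location): drawn independently of
  survival; they exist to exercise the multivariate fit's encoding, not to
  confound.

`apply_monotone_distortion` perturbs each sample by an independent
strictly increasing map (a monotone cubic interpolant through strictly
increasing random knots plus a small linear term), preserving within-sample
ranks exactly. It is the generator's model of batch/platform effects and
the instrument for testing the invariance claim.

What the generator does **not** model: probe-level data, RMA
preprocessing, realistic gene–gene correlation networks, correlated vote
errors across planted pairs (flips are independent), dependent censoring,
or covariates that actually confound survival. Passing tests therefore
demonstrate the pipeline's correctness and its claimed invariances, not
clinical performance on real cohorts.

## Determinism and numerics

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`; per-sample child streams via `SeedSequence`
for the distortion), and identical configurations are bit-reproducible.
Greedy comparisons use integer correct-vote counts, never floating-point
accuracies, so "strict improvement" has no epsilon. Constant genes are
skipped (and counted) by the Spearman screen, where the correlation is
undefined. Test problem sizes are scaled to desk scale — hundreds to a few
thousand genes, tens of samples, hundreds of Monte-Carlo replicates —
which is sufficient to pin each statistic against its brute-force oracle;
the pair engine streams candidate pairs in chunks and supports the full
~14.6M-pair enumeration of a 20k-gene universe when given one.

## Known limitations

- Training accuracy from forward selection is optimistically biased; the
  package deliberately reports it as the procedure defines it. A proper
  error estimate requires external validation, as in the survival
  validation stage.
- The Wilcoxon screen's p-values are not corrected for the millions of
  pairs tested; the raw threshold is part of the procedure's definition.
- With very small groups the exact binomial screen is conservative
  (discrete), and with `p₀ = 1` it can never pass.
- The fixed responder-call cutoff of 2 is tuned to signatures of roughly
  3–5 pairs; for much larger signatures a user should set
  `call_threshold` (or the final vote threshold) deliberately.
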