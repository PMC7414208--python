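# Methods

## The problem

A randomized, double-blind, single-sample taste test asks whether people
can tell two water varieties apart. Each participant is assigned to one
of two arms — tap water or filtered water — tastes a single 200 ml
sample, and guesses which variety it was. The design question is
equivalence, not difference: a non-significant conventional test of
"no ability" proves nothing, so the analysis must be able to *conclude*
indistinguishability with controlled error.

## Measures of distinguishability

With the tap arm as the positive class, the arm-by-response table
(a, b | c, d) gives

- sensitivity Se = a / n1 — probability of answering "tap" in the tap arm,
- specificity Sp = d / n2 — probability of answering "filtered" in the
  filtered arm,
- odds ratio OR = Se/(1−Se) × Sp/(1−Sp) = (a·d)/(b·c),
- AUC = (Se + Sp)/2, the area under the single-point ROC.

OR = 1 and AUC = 0.5 both mean responses are independent of the served
variety; OR > 1 iff AUC > 0.5 (both identities are property-tested). The
OR is invariant to a marginal response bias (e.g. most tasters answering
"tap" regardless of arm), which is why it is the primary measure. The
log-OR standard error is the Woolf form √(1/a + 1/b + 1/c + 1/d).

Se and Sp are always computed on raw counts. The Haldane–Anscombe
correction (0.5 added to all four cells) is applied to the OR machinery
only when a cell is zero and only under `correction="haldane"` (the
default), and is flagged in the result; tables with all-positive cells
are never altered, and `correction="none"` raises an explicit
`ZeroCellError` instead of returning an infinity.

## Five-region inference

The OR axis is partitioned into five labelled regions: OR > 2
(recognizable ability; lenient variant OR > 1.5), 1 < OR ≤ 2 (negligible
ability), OR = 1 (no ability), 0.5 ≤ OR < 1 (weak tendency to guess
incorrectly), OR < 0.5 (strong tendency to guess incorrectly).

Each composite outer region is tested one-sided at its boundary with the
Wald z-statistic z = (ln OR̂ − ln B)/SE: for H: OR ≥ B, p = Φ(z); for
H: OR ≤ B, p = 1 − Φ(z). Because the statistic is monotone in B, the
supremum of the p-value over the composite region is attained at the
boundary, so the boundary test is the region test. Default α = 0.05
one-sided per boundary.

The **five-region confidence interval** is the level-0.95 Wald interval
with each end truncated at the region boundary whose outer region was
rejected. Truncation only ever shrinks the interval and guarantees
coherence: a rejected outer region can never intersect the reported
interval (property-tested over simulated studies). Inner regions receive
verdicts by intersection with this interval, not by separate tests.
Whether the original region procedure defines its interval this way or
by test inversion is not published; truncation is this package's
reconstruction, chosen because it is the unique simple rule consistent
with the reported interval for the reference study (the untruncated Wald
lower bound is 0.48, the reported bound 0.5).

Two reference-study values resist any standard reconstruction and are
deliberately *not* reproduced: the one-sided p for OR ≥ 2 computes to
0.0015 where 0.01 was printed (the same machinery reproduces the other
two printed p-values at 2 dp exactly), and the printed bootstrap AUC
interval (0.42, 0.56) is ≈40 % wider than both the delta-method oracle
and any resampling of the full 278-participant study. The package
reports its computed values and tests them against the analytic oracles.

## Bootstrap interval for the AUC

Percentile bootstrap, default B = 10,000 replicates, seeded and
bit-reproducible. The default `within_arm` scheme resamples each arm's
binary outcomes as a binomial draw with the arm size held fixed — the
arm sizes were set by the randomization and are not sampling variation.
A `pooled` scheme (resampling whole (arm, response) pairs, arm sizes
multinomial) is available for sensitivity analysis; replicates that
empty an arm are redrawn and the redraw count reported. Endpoints are
plain empirical quantiles; no BCa or studentization. Calibration is
simulation-tested: over 500 simulated studies of n = 278 at
Se = 0.76 / Sp = 0.21 the 95 % interval covers the true AUC 0.4856
within ±3 percentage points of nominal.

## Design power and sample size

To conclude "no recognizable ability (OR ≤ 2)" the design needs the
boundary test of H: OR ≥ 2 to reject with high probability when tasters
truly cannot discriminate. Under the normal approximation,
Var(ln OR̂) = 1/(n1·Se(1−Se)) + 1/(n2·Sp(1−Sp)), which is 16/n at
Se = Sp = ½ with equal arms, giving

    power(n) = Φ( (ln B − ln OR_true)/√Var − z_{1−α} )

(exactly α when the true OR sits on the boundary) and the closed-form
requirement n = 16 (z₀.₉₅ + z₀.₈₀)² / (ln 2)² = 205.9 → **206**
participants at 1:1 allocation for 80 % power; a monotone search around
the closed form enforces power(n) ≥ target > power(n−2). The reference
study states "at least 207"; the exact origin of the extra participant
is unpublished (possibly a continuity correction or the Bernoulli
allocation), so the analytic 206 is reported and checked as a
not-exceeding bound. A Monte-Carlo method simulates whole studies
(including per-participant Bernoulli(½) allocation if requested) and
applies the actual Wald boundary test; at n = 278 it agrees with the
analytic 0.8933 within 3 Monte-Carlo standard errors at 20,000
replicates.

The default design spec (Se = Sp = 0.5, i.e. true OR = 1) is the natural
"cannot distinguish" alternative; the reference design does not state
its assumed truth, and this choice reproduces its sample-size result.

## Synthetic data

`simulate_study` emulates the experiment: arm assignment by the
"uniform decimal ≥ 0.5" rule (Bernoulli(½) per participant; a balanced
`fixed_equal` option exists for design work), response "tap" with
probability Se in the tap arm and 1 − Sp in the filtered arm, and four
categorical covariates drawn independently with the observed margins
(male 118/278, student 247/278, dispenser user 189/278, fountain
experience 26/278). Defaults are the observed study conditions
(n = 278, Se = 0.76, Sp = 0.21); these already imply the observed ≈78:22
marginal bias toward answering "tap", so no separate bias parameter
exists. What the generator does **not** model: any covariate–response
association (none is published), taster-level heterogeneity, and water
chemistry. Passing simulation tests therefore validate the inferential
machinery under independence, not subgroup effects in real data.

Subgroup tables are instead recovered by `reconstruct_subgroup_table`,
an exhaustive integer back-solver: given arm sizes and the printed 2-dp
OR and AUC it enumerates all (a, d) pairs whose statistics round
(half away from zero) to the targets. Candidate sets can be non-unique
or empty (empty signals inconsistent targets); for the
"no dispenser use" subgroup (n1 = 46, n2 = 43, OR 0.52, AUC 0.42) the
solver returns the unique table (25, 21, 30, 13).

## Baseline balance tests

Arm-balance p-values for the four covariates use the Yates
continuity-corrected chi-square by default (Fisher's exact test
optional). On the reference margins Yates reproduces the printed
position (1.00) and dispenser (0.80) values; for gender it gives 0.1147
(printed 0.12) and for fountain experience 0.303 (printed 0.34) — no
standard 2×2 test reproduces those two printed values, and they are
reported as computed.

## Numerical conventions

- Full precision everywhere internally; rounding (half away from zero,
  2 dp for estimates and p-values, 1 dp for percentages, 4 dp for SEs)
  happens only in reports, where each rounded value sits beside its
  full-precision twin.
- All randomness flows through `numpy.random.default_rng` seeds;
  per-stratum bootstrap seeds are spawned deterministically from the
  report seed via `SeedSequence`, so a report is bit-reproducible from
  its settings block (the committed reproduction report is tested
  byte-for-byte).
- Degenerate inputs: an empty arm is an error for every estimator; a
  design spec whose true OR is (numerically) on the boundary has no
  finite sample size and raises.

## Problem sizes used in the test suite

Simulation-based checks run at the study's own scale: 500 simulated
studies of n = 278 for bootstrap coverage (10,000 resamples each),
10,000 simulated studies for the size-at-boundary check, 20,000
replicates for Monte-Carlo/analytic power agreement, and n = 27,800 for
large-sample consistency of (Se, Sp). The whole suite completes in a few
seconds on one CPU.

## Known limitations

- All OR inference is Wald-based; no exact conditional (Fisher-type)
  boundary tests or Bayesian region posteriors.
- The bootstrap is percentile-only; BCa is out of scope.
- Two arms, two response categories, no missing-data handling: the data
  model assumes the analyzed participants are post-exclusion.
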