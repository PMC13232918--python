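# Methods

This note documents the statistical models behind `bpqc`, the parameters
that matter, the synthetic generator's assumptions, and the numerical and
design choices that were genuinely open.

## The measurement protocol and averaging

Each visit records at least two device readings. The triage rule: if
readings 1 and 2 differ by **more than** 10 mm Hg (strict inequality; a
difference of exactly 10 does not trigger) a third reading is requested,
and the visit value is the mean of readings 2 and 3; otherwise the mean of
readings 1 and 2. Two open points were resolved as package defaults, both
configurable:

* **Which component triggers the third reading.** The rule is applied to
  *either* component (sBP or dBP) by default (`either`), the most
  conservative reading of "more than 10 mm Hg different"; `sbp_only` and
  `both` are available.
* **Rounding of half-integer averages.** Averages of two integers are
  multiples of 0.5 mm Hg and are *not* rounded by default, because the
  digit audits depend on it; `half_up` and `half_even` modes exist because
  deployed data platforms differ and their behaviour is rarely documented.

Visits with two discordant readings but no third (a protocol violation
seen in real field data) are kept, averaged over readings 1–2, and counted
separately — dropping them would silently bias the audits.

Difference summaries (BP1−BP2, BP1−BP3, BP2−BP3, per measure) report
median and IQR using numpy's linear-interpolation quantile convention; the
test oracles use the same convention. Differences involving reading 3 are
computed over triplicate visits only and reported as undefined (never 0)
when there are none.

## Terminal digit preference

The terminal digit of an integer mm Hg value is its last decimal digit;
half-integer averages form a separate `HALF` class. Under a smooth BP
distribution each digit occurs with probability ≈ 0.10, so the audit tests
H₀: p = 0.10 for terminal 0 and terminal 5 with the one-sample score test
without continuity correction,

    z = (p̂ − p₀) / sqrt(p₀(1−p₀)/n),   two-sided normal p,

the conventional choice when only "a 1-sample test for proportion" is
specified; an exact binomial variant is available (`exact=True`). The
global significance level is α = .01 everywhere in the package (a blanket
multiple-comparison adjustment).

`HALF` values stay in the denominator but can never count as a 0 or 5:
they are genuinely neither, and this choice makes the averaged-stage audit
reflect what averaging actually does to exact-digit heaping. The
consequence — averaged terminal-0 proportions can fall *below* 10% — is
visible in the worked example and is a property of the protocol, not a
bug; a `drop` policy excludes halves entirely for sensitivity analysis.

## The single-value spike

Counts of values exactly equal to an integer target (default dBP = 62) are
compared between raw readings and protocol-averaged values. Exact equality
is deliberate: a 62.5 average never matches, which is precisely why
averaging suppresses a device artifact that always displays the same
integer.

* **Fisher exact test**, two-sided by the "sum of all tables with
  probability ≤ the observed table's" convention (the common
  statistical-package default; conventions differ, so it is stated here).
  Hypergeometric probabilities are computed in log space (gammaln), so
  tables with counts in the hundreds of thousands are handled exactly; a
  relative guard of 1e-7 protects probability ties against rounding error.
* **Risk ratio** p̂_raw/p̂_avg with the **Koopman asymptotic-score CI**:
  the interval {ρ : X²(ρ) ≤ χ²₁(level)} where X²(ρ) is the Pearson
  chi-square evaluated at the constrained MLE under H₀: p₁ = ρp₂ (the
  constrained p₁ is the closed-form smaller root of a quadratic). Bounds
  are found by monotone root-finding (brentq, absolute tolerance 1e-8)
  on each side of the point estimate, with geometric bracket expansion.
  k₁ = 0 pins the lower bound at 0; k₂ = 0 leaves the upper bound
  unbounded (reported as null in the JSON). The plain Koopman statistic is
  the default; the Miettinen–Nurminen small-sample variance factor
  N/(N−1) is available behind `mn_correction=True` and always widens the
  interval.

One reproducibility caveat for the motivating audits: the published pooled
spike counts (28,929/437,446 raw vs 9,310/195,349 averaged) give a direct
risk ratio of ≈ 1.39, not the ≈ 1.09 printed alongside them; the package
always reports the ratio computed from the counts it is given.

## Segmented Poisson threshold model

Counts per 1-mm Hg level L in a window T ± w around the cut-off follow

    log μ(L) = β₀ + β₁x + β₂z + β₃xz,   x = L − T,  z = 1[L ≥ T],

so β₂ is the log-scale discontinuity exactly at the cut-off (the indicator
uses ≥, matching the "at least 140 mm Hg" clinical definition). Counts are
pooled readings per stratum; zero-count levels are included (excluding
them biases the fit). Half-integer averaged values fall between levels and
are excluded with an audit count.

Fitting is Newton–Raphson on the Poisson log-likelihood with step halving,
initialised at the intercept-only solution, converging on relative
log-likelihood change < 1e-10 (max 100 iterations); non-convergence or a
singular information matrix is flagged and suppresses the downstream test.
The segmentation is tested by the 2-df LRT against the reduced model
(β₀, β₁); `step_only=True` gives the 1-df step test. Classification:
significant at α with β₂ > 0 → `preference`, β₂ < 0 → `avoidance`, else
`none`.

**Window choice matters.** The default w = 20 mm Hg is a modelling choice
with no canonical value; the fitted slope (and at large counts, the test
itself) depends on it.

**Known limitation — curvature.** The reduced model assumes log-linear
counts across the window. Real BP histograms are approximately
normal-shaped, i.e. log-quadratic; with enough readings the 2-df LRT will
reject on curvature alone, and even β₂ acquires bias when the window sits
on a steep flank (as for dBP@90 when the population mode is ~70 mm Hg).
Segmentation p-values at very large n should therefore be read together
with the step coefficient and the fitted-curve export, and a narrower
window reduces (but does not remove) the effect. The null calibration
results below hold when the smooth model is true; they are statements
about the test, not about model adequacy on any particular dataset.

## Synthetic observer-behaviour generator

Per visit: true (sBP, dBP) from a bivariate normal (defaults 115/12,
70/9 mm Hg, correlation 0.6 — plausible for a young, largely pregnant
population; arbitrary defaults, fully configurable), readings = true +
N(0, σ_w²) rounded to integers (σ_w = 4 mm Hg default). Each displayed
reading then passes, in this fixed order:

1. **device artifact**: if the visit's latent true dBP lies in [55, 75],
   with probability `pi62` the displayed dBP becomes exactly 62;
2. **digit heaping**: with probability `theta0` transcribe the nearest
   multiple of 10 (ties up); otherwise with probability `theta5` the
   nearest value *ending in 5* (so heap-to-5 never produces a terminal 0
   and the closed-form oracle below stays exact);
3. **threshold displacement** (sBP only): a value in [T, T+w_b] moves,
   with probability `phi_avoid`, to a uniform level in [T−w_b, T−1]; a
   value in [T−w_b, T−1] moves to exactly T with probability
   `psi_prefer` (w_b = 4 default).

The triplicate rule is then applied through the same pipeline. Two
reproducibility properties are load-bearing for the tests: each visit
draws from its own `SeedSequence(seed, spawn_key=(i,))` substream, so
extending a cohort never changes earlier visits; and each reading consumes
a fixed block of draws whether or not a mechanism fires, so toggling one
mechanism never perturbs the realisation of the others (enabling systolic
displacement leaves every diastolic value identical — exactly zero
cross-talk at the data level).

Closed-form expected terminal proportions (the parameter-recovery oracle),
with b₀, b₅ the pre-heaping digit probabilities (0.10 up to a
discretised-normal correction that is ≪ 1e-10 at these SDs):

    prop0 = θ0 + (1−θ0)(1−θ5)·b0   (+ displacement corrections for sBP)
    prop5 = (1−θ0)·[θ5 + (1−θ5)·b5]

For dBP the artifact first moves mass q = pi62·P(true dBP ∈ [55,75]) onto
digit 2, shrinking b₀ and b₅ by (1−q). For sBP the displacement terms
subtract `phi_avoid` × the post-heaping mass at level T and add
`psi_prefer` × the post-heaping mass of [T−w_b, T−1]; these corrections
assume w_b ≤ 4 (no heap target inside the band below T).

What the generator does **not** model: gestational-age or visit-order BP
trends, white-coat effects, observer-specific heaping intensity, device
calibration drift, and any correlation between behaviours and BP level
(displacement aside). Passing tests therefore demonstrate that the
detectors recover *these* mechanisms at realistic magnitudes — not that
real cohorts contain no other artifacts.

## Validation gates and degenerate inputs

Physiological plausibility gates (40–300 / 20–200 mm Hg, dBP < sBP) are a
package choice, configurable. Empty strata, zero denominators, k₂ = 0
ratios and unbounded CI limits propagate as explicit undefined values
(NaN in memory, null in JSON) rather than exceptions or silent infinities,
so a report is always produced. The audit report round-trips losslessly
through JSON; a JSON-Schema document describing it ships with the package.

## Problem sizes used in the shipped checks

The test suite validates the Fisher implementation exhaustively against
integer-arithmetic enumeration on all 2×2 tables with total ≤ 60
(~635,000 tables), the Koopman bounds on 100 random tables against grid
inversion to 1e-6, test calibration on 2000 null strata / 2000 null
histograms / 2000 CI replicates, and parameter recovery on cohorts of
1500–5000 visits; the acceptance script simulates one 5000-visit cohort.
These sizes give Monte-Carlo error comfortably inside the stated
tolerances while keeping a full run to a few minutes.
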