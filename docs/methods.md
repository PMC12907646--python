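# Methods

## Generative model

Each simulated subject is a quadruple `(md0, r, σ, p)` drawn once and held
fixed: baseline mean deviation `md0 ~ Normal(−4, 2)` dB (mostly early-stage
glaucoma), progression rate `r` from an Azzalini skew-normal with location
−0.05 dB/yr, scale 0.8 dB/yr and shape −2 (a long tail of fast
progressors; median −0.57 dB/yr), intrinsic test-retest variability
`σ = exp(Normal(0.5, 0.4))` dB (strictly positive, median e^0.5 ≈ 1.65),
and intrinsic reliability `p = 0.5 + 0.49·Beta(9, 1.5)` (biased towards
reliable subjects, long left tail; median ≈ 0.93). "Low/high" of the
reliability distribution are implemented as a linear rescaling of a
standard beta onto [0.5, 0.99]; the lognormal parameters are those of the
underlying normal on the log scale. Both readings are confirmed by the
resulting medians (0.93 and 1.65).

The four parameters are sampled mutually independently. This is a
deliberate simplification: in real patients worse MD is associated with
higher variability, and a consequence of independence is that critical
times to variability estimation carry **no** information about `md0` or
`σ` (see "Scale invariance" below).

The skew-normal sampler uses the delta representation
`X = ξ + ω(δ|Z₀| + √(1−δ²)Z₁)`, `δ = α/√(1+α²)`; it is validated in the
test suite against `scipy.stats.skewnorm` quantiles and a
numeric-integration mean oracle.

## Test series

The core dataset simulates 4 MD results per visit on the finest grid — 81
visits at 0, 0.25, …, 20 years (long-term plan) or 28 visits at days
0, …, 27 (short-term plan). Every result is
`md0 + r·t_years + Normal(0, σ²)`; on the daily grid the slope contributes
`r·(day/365)`, so the *analysis* choice of skipping progression
normalization, not the generator, embodies the "no progression over days"
assumption. Each result is independently kept with probability `p`
(reliability is per test, not per visit); discarded results are generated
and masked, which has no distributional consequence. No learning, aging or
floor effects are modelled, and within-visit repeats share the same noise
SD as between-visit tests.

The 12 testing conditions (tests per visit k ∈ {1,2,3,4} × review-interval
multiplier m ∈ {1,2,4}) are derived strictly by subsetting the core arrays
(visits 0, m, 2m, … and the first k test columns), so sparser conditions
are exact subsets of denser ones under the same seed.

Randomness: population sampling and each schedule family's noise and
reliability draws use separate child streams of a single master
`SeedSequence`, giving byte-identical outputs for a fixed seed. Draws are
made in fixed array order rather than per-subject substreams; permutation
consistency needs no per-subject streams because conditions are subsets,
never re-simulations.

## Per-visit estimates

At visit v the clinically observable estimates are cumulative over
everything administered so far:

* reliability `p̂_v` = kept tests / administered tests (discarded tests
  count in the denominator); defined from the first visit;
* variability `σ̂_v` = sample SD (n−1 denominator) of all kept values up to
  v. Long-term plan: an OLS slope `r̂_v` is first fitted to all kept
  (t, md) points up to v and **all** of those points are re-adjusted as
  `md − r̂_v·t` before the SD is taken; `σ̂_v` is undefined until ≥ 2 kept
  values exist on ≥ 2 distinct visit times. Short-term plan: raw values,
  undefined until 2 kept values exist.

The re-adjust-all reading (rather than freezing each visit's adjustment at
its contemporaneous slope estimate) follows from estimating variability
"with the best available data at each visit"; the frozen alternative was
evaluated and changes cohort medians by at most one visit while degrading
the ground-truth-criterion behaviour, and is not used.

## Stopping rules

Both rules scan estimates in visit order, skipping visits whose estimate is
undefined (including visits where every test was discarded) without
resetting the count:

* consecutive criterion (TcV, TcR): first triplet of consecutive defined
  estimates with `max − min ≤ τ·mean(triplet)`; the third visit's time is
  the critical time. τ defaults to 0.05 (0.10 is the documented
  alternative). A zero-spread triplet (including all-zero) qualifies. The
  range-to-mean denominator is a design choice; it is validated by the
  grid-floor medians it reproduces (e.g. TcR at the third visit for
  single-test schedules).
* ground-truth criterion (TgV, TgR): first triplet of consecutive defined
  estimates each with `|e − truth| ≤ τ·truth`. Undefined for non-positive
  truth (only reachable with degenerate overrides).

Censoring: a subject whose rule never fires within the horizon carries NaN;
censored subjects are excluded from medians/IQRs and counted in the
denominators of cumulative detection curves. Critical times live on the
visit grid (multiples of 0.25 yr, or integer days) without interpolation.
Qualification is monotone in τ, so widening the tolerance never delays a
critical time (property-tested).

Wherever TcV (TcR) is detected, the estimate at that visit and its
difference from `σ` (`p`) are recorded; the pairing filter for
difference-from-truth analyses (both consecutive and ground-truth times
detected) is applied downstream in the analysis layer.

The production scan is fully vectorised across subjects (cumulative sums
for the running OLS/SD; a stable compaction of eligible visits for the
window scan). A per-subject reference implementation and a naive O(n²)
re-scan oracle are kept alongside and verified equivalent on random gapped
series and random cohorts.

## Analysis layer

Medians/quartiles use linear interpolation between order statistics (the
grid quantization makes the rule nearly irrelevant). Group comparisons use
the Kruskal–Wallis rank test; difference-from-truth distributions get a
one-sample t-test against zero (degenerate all-equal inputs yield NaN
statistics). Predictor regressions are univariable OLS fits of critical
time on each of `md0`, `r`, `σ`, `p` over detected subjects pooled across
the 12 conditions of a schedule family — simple regressions so that
per-predictor R² values are summable; zero-variance predictors are flagged
with NaN rows.

## Scale invariance of variability critical times

Under this generative model every term of the detrended (or raw) estimate
series scales linearly in σ: the noise is `σ·z`, the slope error is
proportional to σ, hence `σ̂_v = σ·f(z)` with `f` independent of σ. Both
stopping rules compare ratios, so TcV and TgV are distributed independently
of σ (and of `md0`, which drops out of the SD entirely). Regressions of
TcV on σ therefore estimate a true coefficient of zero; any measured sign
is sampling noise. Reliability does retain a real (weak) effect on TcV
through data loss, and a strong negative effect on TcR/TgR: highly reliable
subjects hit flat `p̂` triplets at the grid floor.

## Detection-probability framework

Single-test detection of a fixed difference `d` at noise σ is modelled as
`Φ(d/σ)` (one-sided detection of a positive shift; the signal-to-noise
ratio is `d/σ`). Multi-test detection assumes independent tests:
`1 − (1 − Φ(d/σ))^n`. Limits: σ→0 gives certainty, σ→∞ gives the 0.5
guessing floor. The default grid uses d = 0.8 dB over
σ ∈ {0.5, 1, 1.5, 2, 2.5} and n = 1..4.

## Problem sizes and defaults

The study conditions are n = 100 000 subjects, τ = 0.05, all 12 conditions
per family; the cohort-scale test suite runs the full size (about a minute
for both families on one core; ~0.6 GB peak). `RunConfig` defaults mirror
these conditions. The README example uses n = 2000 purely for illustration;
all cohort medians quoted at full size are computed by the test suite, not
stored.

## Known limitations

* Reliability and variability are deliberately decoupled, and parameters
  are mutually independent; associations observed in clinical data (worse
  MD ↔ higher variability, variable ↔ unreliable) are out of scope, so
  predictor regressions on simulated data mostly establish null effects.
* The simulation operates on the MD summary index only — no pointwise
  24-2/10-2 grids, thresholding algorithms, or catch-trial mechanics.
* Detected-only medians under heavy censoring (short horizons, sparse
  review) are not monotone in testing intensity: detecting *more* subjects
  can raise the median. Cumulative detection curves are the robust
  comparison there.
* The multi-test detection column assumes independence between same-visit
  tests; correlated within-visit noise would lower the ≥1-of-n
  probabilities.
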