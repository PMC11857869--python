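# Methods

## Problem setting

A published KM figure carries more information than the hazard ratio
printed beside it: the curve itself, the numbers-at-risk row, and often a
total event count. `km2ipd` turns these into a patient-level dataset whose
product-limit estimate reproduces the published curve, so that any
standard time-to-event analysis — and in particular an RMST-based
non-inferiority test — can be run as if the IPD had been shared. All
times are months; survival is a probability.

## Curve sanitization

Digitizer output is noisy: clicks may be unsorted, duplicated, slightly
above 1 or below 0, and locally increasing. Ingestion sorts by time,
clamps to [0, 1] and collapses duplicate times to the minimum survival
(the bottom of a re-clicked vertical drop). `sanitize_monotone` then
replaces the survival sequence by its least-squares non-increasing
approximation (pool-adjacent-violators, via isotonic regression with a
decreasing constraint). PAVA is the L2-optimal monotone fit, is the
identity on monotone input, and therefore idempotent. Percent vs
probability scale is an explicit caller choice (`survival_scale`); no
auto-detection is attempted because 0–1 vs 0–100 cannot be disambiguated
reliably near small survival values.

## Reconstruction algorithm

Inputs: a sanitized curve (clicks (t_k, S_k)), a risk table (times t_i,
counts n_i, with t_0 = 0 and n_0 the arm size), and optionally the total
event count D.

Per interval [t_i, t_{i+1}), with running at-risk count n and
reconstructed survival S at the last allocated event:

1. For a candidate censoring count c, place censorings at the interval
   positions (j − 0.5)/c, j = 1..c — the uniform-censoring assumption with
   midpoint spacing, which avoids collisions with boundary clicks.
2. Walk clicks and censorings in time order (events before censorings at
   tied times, matching the KM risk-set convention). At click k allocate
   d_k = round(n (1 − S_k / S)) events, clamped to [0, n]; update
   S ← S (1 − d_k/n), n ← n − d_k. Because the inversion always targets
   the *reconstructed* S, rounding residue at one click automatically
   carries to the next — over a vertical drop digitized as several clicks
   the allocation behaves like a largest-remainder apportionment, with no
   systematic undercount.
3. The implied at-risk count at t_{i+1} is compared with the published
   n_{i+1}; c is adjusted by monotone integer bisection over
   [0, n at interval start]. Ties in mismatch break toward fewer
   censorings. If no c matches exactly, the best match is kept and the
   report's `converged` flag is cleared.

After the last risk boundary no published count constrains censoring, so
no interior censorings are placed; events are allocated from the remaining
drops and every patient still at risk is censored at the last click time
(administrative censoring — the minimal assumption). If D is supplied, the
final interval is rebalanced: missing events are taken from the
end-censored patients (at the last click time), surplus events are
converted back to censorings starting from the latest allocations. With
only n_0 available (no interior boundaries) the censoring-matching loop is
skipped entirely.

The procedure is fully deterministic — no random numbers — so secondary
analyses are exactly reproducible. Output size is always n_0;
events + censorings conserve the arm size by construction.

Fidelity is scored against the input clicks: `max_abs_dev` and `rmse` of
|S_k − Ŝ(t_k)| with Ŝ the right-continuous KM step function of the
reconstructed data. When clicks are exact KM step values and censoring is
purely administrative at boundaries, reconstruction is exact up to the
integer-rounding bound 1/(2 n_0); in the test battery (exponential event
hazards 0.002–0.02/month, exponential dropout, 6-month risk rows) the
observed max deviation is a few 10⁻³, an order of magnitude inside the
0.02 working tolerance.

## Estimators

* **KM**: Ŝ(t) = Π_{t_j ≤ t} (1 − d_j/n_j); Greenwood variance
  Ŝ(t)² Σ d_j/(n_j(n_j − d_j)), with the j-th term set to 0 when
  n_j = d_j. Censorings tied with events leave the risk set after the
  events.
* **Median**: smallest event time with Ŝ ≤ 0.5 ("not reached" is a value,
  encoded NaN). Its CI comes from complementary-log-log confidence bands —
  bounded in [0, 1] and the default in the mainstream survival software
  lineage: the bound is the first time the corresponding band crosses 0.5.
* **Log-rank**: standard two-sample hypergeometric form, delegated to
  lifelines; checked in the tests against a from-first-principles oracle.
* **Cox**: treatment factor only (non-reference arms as indicators),
  fitted by lifelines' Newton–Raphson with the Efron tie correction —
  reconstructed IPD is tie-heavy by construction, and Efron is the less
  biased choice. Wald (β̂ᵀ V̂⁻¹ β̂) and likelihood-ratio statistics are
  reported on (arms − 1) df. Pairwise HRs between non-reference arms come
  from one fitted model, exp(β̂_a − β̂_b), so the printed HRs are exactly
  transitive. An optional trial-stratified fit is exposed; the default is
  the unstratified pooled fit.
* **RMST**: area under the KM step function on [0, τ]; variance
  Σ_{t_j ≤ τ} (area from t_j to τ)² d_j/(n_j(n_j − d_j)). τ beyond the
  observed follow-up raises rather than extrapolates.
* CI quantiles use exact normal quantiles (1.959964, 1.644854), rounding
  only at presentation.

## Non-inferiority layer

Loss = RMST_ref − RMST_test with SE = √(SE_ref² + SE_test²) (pooled arms
are independent). z = (Δ − loss)/SE; p_noninf is the upper normal tail
under the boundary null loss = Δ; the decision (90% CI upper bound < Δ)
coincides algebraically with z > 1.644854 and p < 0.05 one-sided — the
two-sided-90%-CI / one-sided-0.05 pairing conventional for
non-inferiority. The margin is always configuration (default 2 event-free
months at τ = 30); it encodes clinical judgment and is never inferred
from data. The p-value is clamped to the open unit interval at float
resolution so extreme z never reports exactly 0 or 1.

`convert_ci` assumes normality: SE = (upper − lower)/(2 z_from). Applied
to published rounded inputs this reproduces printed 90% bounds to the
third decimal (one bound in the motivating example lands one unit off in
the third decimal purely from input rounding).

## Pooling and heterogeneity

Pooling concatenates per-trial records under canonical treatment labels
(an explicit (trial, arm) → treatment map; unmapped pairs are errors, not
guesses), keeps trial_id on every record, and does no time rescaling —
follow-up is pooled on the raw month scale. `heterogeneity` reports the
treatment-factor LRT/Wald pair (df = arms − 1) and, separately, a
`trial_strata` mode comparing trial-stratified vs pooled partial
likelihoods (df = trials − 1, statistic clamped at 0). The stratified and
unstratified partial likelihoods are built on different risk sets, so this
second mode is a crude diagnostic, not a calibrated test; it is provided
because a between-study check is routinely wanted alongside the pooled
fit.

## Synthetic-data generator

Event times are (piecewise-)exponential; censoring is the minimum of an
exponential dropout time and an administrative cutoff. The default
scenario mirrors the motivating pooled comparison: arms of 1783, 1054 and
382 patients, 30-month horizon, common event hazard 0.00275/month and
dropout 0.01/month, chosen so roughly 7% of patients (≈221/3219) have an
event — the censoring-heavy regime the reconstruction assumptions target.
"Publishing" an arm samples its KM step function on a 3-month click grid
(plus every event step in fine mode, the default), optionally adds
Gaussian click jitter and re-sanitizes, and tabulates exact at-risk counts
every 6 months.

What the generator does *not* emulate: digitizer axis-calibration error
(only additive jitter), non-uniform within-interval censoring,
informative censoring, and delayed/crossing hazards unless configured
piecewise. Passing tests therefore demonstrate correctness of the
inversion and estimators under the method's own assumptions, not
robustness to arbitrary real-world digitization pathologies.

Problem sizes used by the shipped experiments were chosen to make
Monte-Carlo error small relative to the quantities checked while keeping
the whole suite fast on a laptop: 20 arms of 200–1000 patients for
fidelity, 200 replicates at 500/arm for HR/RMST recovery (log-HR MC SE
≈ 0.009), 1000 replicates at 300/arm for type-I calibration (binomial SE
≈ 0.007 at α = 0.05).

## Numerical and design choices

* Event allocation rounds half away from zero (floor(x + 0.5)); the
  self-correcting target makes the choice immaterial beyond one event.
* Censoring-count bisection assumes the implied boundary count is
  monotone non-increasing in c; in the rare non-monotone case the search
  still terminates and the best candidate is kept with `converged=False`.
* Risk-table boundaries beyond the last click are ignored (nothing
  constrains them); risk rows where nobody remains at risk are dropped at
  generation.
* Degenerate inputs: flat curves yield zero events; all-censored data
  give Ŝ ≡ 1 and RMST = τ with SE 0; a zero-width CI in `convert_ci`
  warns and returns a zero-width interval.
* Whether published total event counts were used alongside curves is
  often unknowable for a given paper; both modes are supported
  (`total_events=None` skips the final rebalance).

## Known limitations

* Reconstruction assumes the published curve is itself a KM estimate with
  non-informative censoring; it cannot repair mislabeled axes or
  truncated curves.
* The NI test is normal-theory on the RMST difference; very small arms or
  τ near the follow-up limit inflate the SE and the test loses power but
  keeps its level (verified by the calibration experiment).
* The trial-strata heterogeneity statistic is a diagnostic only (see
  above).
* Covariate-adjusted Cox models, parametric survival fits and competing
  risks are out of scope.
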