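# Methods

## Model structure and assumptions

The analysis is a deterministic cohort (Markov) simulation over three health
states — progression-free on first-line therapy (PFS), progressive disease
(PD, partially on second-line therapy), and death — with monthly cycles and
a 120-cycle (10-year) horizon, taken as lifetime for advanced HCC. The whole
cohort starts in PFS; death is absorbing; there is no PD→PFS transition, no
tunnel states, and no time-varying probabilities. Survivors at the horizon
contribute nothing beyond it (no terminal extrapolation).

Constant per-cycle transition probabilities are equivalent to exponential
sojourn times. Under that assumption a reported median time-to-event `m`
(months) converts to a per-cycle probability `p = 1 − 0.5^(cycle/m)`;
PFS→PD uses the PFS median, PFS→Death the OS median, and PD→Death the
post-progression median `m_OS − m_PFS`. Two caveats are inherent to this
inversion and documented rather than patched:

- A trial's PFS endpoint counts progression *or* death, so its median
  reflects the total PFS-exit hazard. Assigning it wholly to PFS→PD
  overstates progression slightly whenever pre-progression mortality is
  non-negligible; the split between the two exit causes is simply not
  identified from two medians. The synthetic round-trip tests therefore
  check recovery of the exit probability, not of the split.
- Published probability tables may carry rounded intermediates; where a
  published entry disagrees with the formula in the 4th decimal the package
  reports the formula value (and the test suite pins the discrepancy).

Strategies whose probabilities cannot be derived (median OS not reached, or
values published only as calibrated constants) carry directly specified
probabilities in the configuration, which always override derivation.

## Key parameters

| parameter | default | units | note |
|---|---|---|---|
| cycle length | 1 | month | trial assessment granularity |
| horizon | 120 | cycles | 10 years, lifetime for this population |
| annual discount rate | 0.03 | /year | applied to costs and QALYs |
| utilities (PFS, PD, death) | 0.76, 0.68, 0 | /year | literature EQ-5D values |
| WTP threshold | 35,526.90 | USD/QALY | 3× 2022 per-capita GDP, China |
| OWSA spread | ±20% | of base | published range convention |
| PSA iterations | 10,000 | draws | published count |
| PSA SD rule | 0.2·mean/1.96 | — | 95% interval spans the ±20% range |

Costs are per-cycle USD line items (two drugs, routine tests, adverse-event
management in PFS; averaged second-line therapy in PD), converted upstream
at a fixed ￥7.24/$ — the package carries no currency logic. The AE cost is
per-cycle by default (as cost tables label it) with a one-time-at-entry mode
as a flag. Utilities are annual weights; a cycle contributes
`u · cycle/12` QALYs per person-cycle.

## Accrual and discounting conventions

Published cohort analyses rarely state when within a cycle membership is
counted or how an annual rate maps to monthly factors, yet these choices
move 10-year totals by tens of percent. Both are therefore first-class
configuration, with a `convention_sweep` report over all nine combinations:

- accrual: end-of-cycle, start-of-cycle, half-cycle (trapezoid);
- discounting: continuous-monthly `(1+r)^(−t/12)`, annual-step
  `(1+r)^(−⌊t/12⌋)`, per-cycle `(1−r)^t`.

Library defaults are the methodologically standard end-of-cycle +
continuous-monthly. The packaged HCC configuration instead sets half-cycle +
per-cycle, because that combination is the evident convention of the
original analysis: the discounted person-cycles implied by the published
per-state cost and QALY breakdown (20 values) match it to within ~2% per
state, several times closer than any alternative, and the per-cycle discount
pattern is a well-known artefact of decision-tree software configured with
monthly stages. Even so, totals are not bit-reproducible — published
rounding and residual convention detail leave a few-percent gap, which the
tests treat as a bracketing (within 15%) rather than an equality check. One
knock-on effect: the model's own S+B-vs-C+R ICER is $63,829, below the
$70,725 obtainable from the published (unrounded-internal) totals, because
the incremental QALY denominator is small (≈0.24 vs ≈0.21) and absorbs all
the per-state mismatch; the CEAC crossover tracks the same value.

## Calibration

When medians are unavailable, the three probabilities are fitted by
least squares to digitized Kaplan–Meier points: the objective is the
equally weighted SSE between model PFS/OS curves — interpolated linearly in
time between cycle knots — and the KM survival values at the KM point times.
Neither an objective nor an optimizer is prescribed by convention, so the
package uses a documented, deterministic choice: a 12-per-dimension
log-spaced coarse grid over (1e-5, 0.999)³ (skipping infeasible PFS rows)
followed by bounded L-BFGS-B refinement; the refined optimum is never worse
than the best grid point. Degenerate inputs (all-ones curves, a missing
endpoint, fewer than 3 points) are rejected as unidentifiable. A diagnostic
`model_median` reports the fitted model's implied medians (linear
interpolation between cycles; infinite if 0.5 is never crossed).

## Sensitivity analysis

OWSA reruns the full deterministic model at 0.8× and 1.2× of one parameter
(cost item, utility, or transition probability) and records the outcome —
the strategy's CER, or its raw incremental ratio versus a reference, which
is reported even when the comparison is dominance (negative ΔE gives a
negative ratio, as tornado plots conventionally show). Bars are ordered by
outcome range. Because each utility can be perturbed independently, the
utility-ordering constraint (u_PD ≤ u_PFS) binds configuration inputs only,
not perturbed or sampled values.

PSA draws costs from gamma and utilities from beta distributions, moment
matched to mean = base and SD = 0.2·mean/1.96 (a beta SD infeasible for its
mean is shrunk to feasibility with a warning). The two utilities and the
routine-test unit cost are single shared parameters — one draw applied to
every strategy per iteration — while drug, AE and second-line costs are
per-strategy. Transition probabilities are held at base by default (the
published distribution assignments cover costs and utilities);
`include_probs=True` adds beta-distributed probabilities. Draws come
parameter-major from one seeded numpy generator in a fixed order, so a fixed
seed reproduces results bit-identically regardless of iteration count
chunking. With probabilities fixed, totals are linear in the draws given the
precomputed occupancy trace, so the 10,000-iteration run is vectorized and
takes well under a second; equivalence with a strategy-by-strategy rebuild
is asserted in tests.

CEAC acceptability is the fraction of iterations in which a strategy has
the strictly highest NMB, ties split equally, on a WTP grid of 0–150,000 in
$500 steps (resolving both the threshold and the observed crossover).
`crossover_wtp` returns the first grid point where one curve overtakes
another and stays above to the end of the grid, warning on earlier
unsustained crossings.

## Synthetic data

`simulate_patients` generates continuous-time exponential event times at
rates `−ln(1−p)` (competing progression/death from PFS, then
post-progression death), with censoring from exponential dropout plus an
administrative cut-off under uniform accrual — which produces realistic
"median OS not reached" datasets on demand. KM estimation (curves and
medians) is delegated to lifelines. The generator emulates the statistical
structure the cohort model assumes — constant hazards, independent
censoring, a single arm with no covariates, no per-patient cost microdata —
so recovery tests demonstrate internal consistency of the pipeline, not
robustness to real-world features such as non-proportional hazards, cure
fractions or informative censoring.

## Numerical choices and edge cases

- Probability/rate conversions use `log1p`/`expm1`; round-trips are exact to
  machine precision; `p = 1` (infinite rate) and non-positive medians are
  domain errors; an infinite median maps to probability 0.
- Traces are validated to conserve mass within 1e-12 with monotone death
  occupancy; non-stochastic matrices are rejected.
- Frontier ties: cost ties sort by QALY descending then input order;
  extended dominance removes only strictly non-increasing incremental-ICER
  steps, so exactly collinear strategies are retained.
- Report rounding: money and QALYs to 2 dp, probabilities to 4 dp; CSV/JSON
  outputs keep full precision.

## Known limitations

- Cross-trial comparison inherits the source trials' population differences;
  nothing adjusts for them.
- The exponential/constant-hazard assumption ignores the shape of real
  survival curves beyond their medians.
- The 10-year horizon truncation slightly penalizes strategies whose
  benefit accrues late.
- Published totals are reproduced approximately (see the convention
  discussion above), and quantities with small incremental denominators
  (ICERs, crossover WTPs) amplify that residual into ~10% differences.
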