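# markovcea

Markov cohort cost-effectiveness analysis for three-state oncology treatment
models, built around a worked comparison of five first-line immuno-combination
therapies for unresectable hepatocellular carcinoma (HCC): camrelizumab +
rivoceranib (C+R), sintilimab + bevacizumab biosimilar (S+B), pembrolizumab +
lenvatinib (P+L), atezolizumab + bevacizumab (A+B) and tremelimumab +
durvalumab (STRIDE).

It is written for health-economics analysts and methods researchers who want
a published-style cohort analysis as inspectable, testable code: every
modelling convention that decision-tree software usually hides (accrual
timing, discount compounding, adverse-event cost handling) is an explicit,
swappable setting.

## The model

A cohort starts progression-free (PFS) and moves each monthly cycle among
the states {PFS, PD, Death} by a row-stochastic matrix; death is absorbing
and there is no PD→PFS recovery. When a trial reports median PFS and OS,
monthly transition probabilities follow from the exponential assumption

    p = 1 − 0.5^(cycle_length / median),    r = −ln(1−p) / cycle_length,

with PFS→PD from the PFS median, PFS→Death from the OS median, and PD→Death
from the post-progression median (OS − PFS). When the OS median is not
reached (as for S+B), probabilities are instead calibrated by least squares
to Kaplan–Meier curves. Discounted totals accrue as

    Cost  = Σ_t occupancy(t) · c_state · d(t)
    QALYs = Σ_t occupancy(t) · u_state · (cycle/12) · d(t)

over a 120-cycle (10-year) horizon with a 3%/year discount. Strategies are
compared by CER (C/E), ICER (ΔC/ΔE), net monetary benefit
(NMB = WTP·E − C at WTP $35,526.90/QALY), and a dominance/extended-dominance
frontier; uncertainty by ±20% one-way (tornado) analysis and a 10,000-draw
probabilistic sensitivity analysis (gamma costs, beta utilities) summarized
as cost-effectiveness acceptability curves (CEAC).

A synthetic-trial module simulates patient-level exponential event times with
censoring from known probabilities, so median round-trips and KM calibration
are testable end to end with known ground truth.

## Worked example

The packaged configuration carries the five published strategies (monthly
transition probabilities, per-cycle USD costs, utilities 0.76/0.68) under the
reconstruction conventions (half-cycle accrual, per-cycle discounting — see
`docs/methods.md`):

```bash
$ markovcea run --no-psa
                 C+R       S+B       P+L       A+B     STRIDE
cost_total  11635.56  27098.86  55799.98  71485.87   85378.76
qaly_total      0.88      1.12      0.83      0.90       0.74
cer         13265.82  24209.04  67249.30  79339.17  116145.14

Frontier: C+R -> S+B
ICER S+B vs C+R: 63,829.05 $/QALY
P+L: dominated (by C+R)
A+B: dominated (by S+B)
STRIDE: dominated (by C+R)
```

C+R is the cheapest and anchors the frontier (~$13.3k per QALY); only S+B
adds QALYs at any price, at ~$64k per additional QALY — above the $35,526.90
willingness-to-pay threshold, so C+R is the cost-effective choice. P+L, A+B
and STRIDE cost more and deliver no more health than a frontier strategy.

```bash
$ markovcea psa --iterations 10000
iterations: 10000, seed: 20240816
acceptability[C+R] at WTP 35,526.90: 0.999
acceptability[S+B] at WTP 35,526.90: 0.001
...
```

At the threshold, C+R is optimal in >99% of Monte Carlo draws. The same
analyses are available as a library:

```python
import markovcea as m

cfg = m.load_config(m.example_config_path())
results = m.evaluate_all(cfg.model)          # {"C+R": CEResult, ...}
report = m.frontier(results)                 # dominance + frontier ICERs
psa = m.run_psa(cfg.model, 10_000, seed=1)
curve = m.ceac(psa)
m.crossover_wtp(curve, "C+R", "S+B")         # WTP where S+B takes over
```

Other subcommands: `markovcea owsa` (tornado), `markovcea calibrate`
(KM fitting), `markovcea simulate` (synthetic cohorts).

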