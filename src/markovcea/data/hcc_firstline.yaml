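# Five first-line immuno-combination strategies for unresectable HCC,
# as published: trial medians (months), monthly transition probabilities,
# per-cycle costs (USD) and state utilities.
#
# The accrual/discounting conventions reconstruct the original analysis:
# half-cycle-corrected membership with the 3% discount applied per monthly
# cycle reproduces the published per-state cost and QALY breakdown far more
# closely than any other convention combination (see docs/methods.md).
#
# A+B and S+B probabilities were calibrated to KM curves by the original
# analysts and are given directly; the remaining strategies carry both their
# medians and the published probabilities (which the median-to-probability
# formula reproduces; the derivation is cross-checked in the test suite).

model:
  cycle_length_months: 1
  horizon_cycles: 120
  annual_discount_rate: 0.03
  accrual: half-cycle
  discounting: per-cycle-rate
  ae_cost_mode: per-cycle

wtp: 35526.90

reference_strategy: "C+R"

psa:
  n_iterations: 10000
  seed: 20240816
  spread: 0.2

strategies:
  - name: "C+R"            # camrelizumab + rivoceranib
    median_pfs: 5.6
    median_os: 22.1
    subsequent_treatment_fraction: 0.331
    grade34_ae_rate: 0.81
    probs: {pfs_to_pd: 0.1164, pfs_to_death: 0.0309, pd_to_death: 0.0411}
    costs: {drug_a: 433.9607, drug_b: 474.7423, test: 175.4512, ae: 42.0894, pd: 590.1987}
    utilities: {pfs: 0.76, pd: 0.68}

  - name: "S+B"            # sintilimab + bevacizumab biosimilar (median OS not reached)
    median_pfs: 4.6
    subsequent_treatment_fraction: 0.29
    grade34_ae_rate: 0.53
    probs: {pfs_to_pd: 0.0643, pfs_to_death: 0.0048, pd_to_death: 0.0470}
    costs: {drug_a: 397.9770, drug_b: 1850.5928, test: 175.4512, ae: 20.9631, pd: 320.9421}
    utilities: {pfs: 0.76, pd: 0.68}

  - name: "P+L"            # pembrolizumab + lenvatinib
    median_pfs: 8.2
    median_os: 21.2
    subsequent_treatment_fraction: 0.441
    grade34_ae_rate: 0.615
    probs: {pfs_to_pd: 0.0811, pfs_to_death: 0.0322, pd_to_death: 0.0519}
    costs: {drug_a: 6602.7324, drug_b: 1343.1722, test: 175.4512, ae: 21.3019, pd: 125.829}
    utilities: {pfs: 0.76, pd: 0.68}

  - name: "A+B"            # atezolizumab + bevacizumab (probabilities as published)
    median_pfs: 6.9
    median_os: 19.2
    subsequent_treatment_fraction: 0.185
    grade34_ae_rate: 0.568
    probs: {pfs_to_pd: 0.0656, pfs_to_death: 0.0263, pd_to_death: 0.0495}
    costs: {drug_a: 6043.3532, drug_b: 2487.3559, test: 175.4512, ae: 6.7592, pd: 246.9244}
    utilities: {pfs: 0.76, pd: 0.68}

  - name: "STRIDE"         # tremelimumab + durvalumab
    median_pfs: 3.78
    median_os: 16.43
    subsequent_treatment_fraction: 0.407
    grade34_ae_rate: 0.505
    probs: {pfs_to_pd: 0.1675, pfs_to_death: 0.0414, pd_to_death: 0.0534}
    costs: {drug_a: 12380.9524, drug_b: 7498.5490, test: 175.4512, ae: 12.4781, pd: 937.3418}
    utilities: {pfs: 0.76, pd: 0.68}
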