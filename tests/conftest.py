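"""Shared fixtures: the packaged five-strategy model and published reference values."""

from __future__ import annotations

import math

import pytest

import markovcea as m

# Published base-case results used as reference values across the suite:
# per-state discounted costs (USD), QALYs, and the cost-effectiveness ratio.
PUBLISHED_BASE_CASE = {
    "A+B": dict(cost_pfs=69_263.76, cost_pd=1_721.30, cost_total=70_985.06,
                qaly_pfs=0.50, qaly_pd=0.40, qaly_total=0.90, cer=78_872.289),
    "STRIDE": dict(cost_pfs=76_476.08, cost_pd=8_112.92, cost_total=84_589.01,
                   qaly_pfs=0.24, qaly_pd=0.49, qaly_total=0.73, cer=115_887.68),
    "S+B": dict(cost_pfs=24_178.44, cost_pd=2_783.16, cost_total=26_961.60,
                qaly_pfs=0.63, qaly_pd=0.49, qaly_total=1.12, cer=24_072.86),
    "C+R": dict(cost_pfs=6_259.67, cost_pd=5_849.59, cost_total=12_109.27,
                qaly_pfs=0.35, qaly_pd=0.56, qaly_total=0.91, cer=13_306.89),
    "P+L": dict(cost_pfs=54_487.29, cost_pd=895.24, cost_total=55_382.53,
                qaly_pfs=0.42, qaly_pd=0.40, qaly_total=0.83, cer=66_725.94),
}

#: ICER of S+B versus C+R computed by the original analysts from unrounded totals.
PUBLISHED_ICER_SB_CR = 70_725.38


@pytest.fixture(scope="session")
def analysis_config() -> m.AnalysisConfig:
    return m.load_config(m.example_config_path())


@pytest.fixture(scope="session")
def model(analysis_config) -> m.DecisionModel:
    return analysis_config.model


@pytest.fixture(scope="session")
def base_results(model):
    return m.evaluate_all(model)


@pytest.fixture()
def published_results():
    """Published totals wrapped as results (ratio arithmetic inputs)."""
    return {
        name: m.CEResult.from_totals(v["cost_total"], v["qaly_total"])
        for name, v in PUBLISHED_BASE_CASE.items()
    }


def hand_ledger(matrix, state_costs, utilities, config):
    """Brute-force per-cycle ledger, independent of the engine internals.

    Pure-python explicit enumeration: propagates the occupancy row by row,
    then sums cost and QALY contributions cycle by cycle under the configured
    accrual and discounting conventions.  Only meant for tiny horizons.
    """
    occ = [(1.0, 0.0, 0.0)]
    for _ in range(config.horizon):
        p, d, x = occ[-1]
        occ.append(
            (
                p * matrix[0][0],
                p * matrix[0][1] + d * matrix[1][1],
                p * matrix[0][2] + d * matrix[1][2] + x,
            )
        )

    def disc(t: int) -> float:
        r = config.annual_discount_rate
        months = t * config.cycle_length
        name = config.discount_compounding.value
        if name == "continuous-monthly":
            return (1 + r) ** (-months / 12)
        if name == "annual-step":
            return (1 + r) ** (-math.floor(months / 12))
        return (1 - r) ** t

    conv = config.accrual_convention.value
    cost_pfs = cost_pd = q_pfs = q_pd = 0.0
    for t in range(1, config.horizon + 1):
        if conv == "end-of-cycle":
            w, f = occ[t], disc(t)
        elif conv == "start-of-cycle":
            w, f = occ[t - 1], disc(t - 1)
        else:  # half-cycle
            w = tuple(0.5 * (a + b) for a, b in zip(occ[t - 1], occ[t]))
            f = disc(t - 1)
        cost_pfs += w[0] * state_costs.pfs_total * f
        cost_pd += w[1] * state_costs.pd_cost * f
        q_pfs += w[0] * utilities.u_pfs * config.cycle_length / 12 * f
        q_pd += w[1] * utilities.u_pd * config.cycle_length / 12 * f
    if config.ae_cost_mode.value == "one-time":
        cost_pfs += state_costs.ae_one_time
    return cost_pfs, cost_pd, q_pfs, q_pd
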