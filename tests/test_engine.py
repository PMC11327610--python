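"""Cohort trace propagation, discounting and cost/QALY accrual."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import markovcea as m
from conftest import hand_ledger

CR = m.TransitionProbs(0.1164, 0.0309, 0.0411)


def cfg(**kw) -> m.ModelConfig:
    return m.ModelConfig(**kw)


# -- discounting --------------------------------------------------------------


def test_discount_factor_examples():
    cont = cfg(discount_compounding="continuous-monthly")
    assert m.discount_factor(0, cont) == 1.0
    assert m.discount_factor(12, cont) == pytest.approx(1 / 1.03)
    step = cfg(discount_compounding="annual-step")
    assert m.discount_factor(0, step) == 1.0
    assert m.discount_factor(24, step) == pytest.approx(1.03**-2)
    assert m.discount_factor(11, step) == 1.0  # still within the first year
    percyc = cfg(discount_compounding="per-cycle-rate")
    assert m.discount_factor(10, percyc) == pytest.approx(0.97**10)


# -- trace --------------------------------------------------------------------


def test_trace_identity_matrix_is_constant():
    tr = m.run_trace(np.eye(3), cfg(horizon=10))
    assert np.allclose(tr.occupancy, [1.0, 0.0, 0.0])


def test_trace_immediate_absorption():
    M = m.build_transition_matrix(m.TransitionProbs(0.0, 1.0, 0.0))
    tr = m.run_trace(M, cfg(horizon=3))
    assert tuple(tr.occupancy[1]) == (0.0, 0.0, 1.0)


def test_trace_hand_values_first_cycles():
    tr = m.run_trace(m.build_transition_matrix(CR), cfg(horizon=5))
    assert np.allclose(tr.occupancy[1], [0.8527, 0.1164, 0.0309])
    # cycle-2 PD share: survivors progressing plus PD patients surviving
    expected_pd2 = 0.8527 * 0.1164 + 0.1164 * (1 - 0.0411)
    assert tr.occupancy[2, 1] == pytest.approx(expected_pd2)


def test_trace_rejects_bad_matrix():
    with pytest.raises(ValueError):
        m.run_trace(np.full((3, 3), 0.5), cfg())
    with pytest.raises(ValueError):
        m.run_trace(np.eye(2), cfg())


@given(
    p12=st.floats(0.0, 0.5),
    p13=st.floats(0.0, 0.5),
    p23=st.floats(0.0, 1.0),
    horizon=st.integers(1, 60),
)
@settings(derandomize=True, max_examples=100)
def test_trace_mass_conserved_and_death_monotone(p12, p13, p23, horizon):
    tr = m.run_trace(
        m.build_transition_matrix(m.TransitionProbs(p12, p13, p23)),
        cfg(horizon=horizon),
    )
    assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diff(tr.occupancy[:, 2]) >= -1e-15)
    assert np.all(tr.occupancy >= -1e-15)
    assert tuple(tr.occupancy[0]) == (1.0, 0.0, 0.0)


# -- accrual ------------------------------------------------------------------

ALL_CONVENTIONS = [
    (acc, disc)
    for acc in ("end-of-cycle", "start-of-cycle", "half-cycle")
    for disc in ("continuous-monthly", "annual-step", "per-cycle-rate")
]


@pytest.mark.parametrize(("accrual", "discounting"), ALL_CONVENTIONS)
def test_accumulate_matches_hand_ledger(accrual, discounting):
    """Engine totals equal an explicitly enumerated per-cycle ledger."""
    config = cfg(horizon=5, accrual_convention=accrual,
                 discount_compounding=discounting)
    costs = m.StateCosts(pfs_drug_cost=900.0, pfs_test_cost=170.0,
                         pfs_ae_cost=40.0, pd_cost=590.0)
    utils = m.UtilitySet(0.76, 0.68)
    M = m.build_transition_matrix(CR)
    res = m.accumulate(m.run_trace(M, config), costs, utils, config)
    exp_cpfs, exp_cpd, exp_qpfs, exp_qpd = hand_ledger(M, costs, utils, config)
    assert res.cost_pfs == pytest.approx(exp_cpfs, rel=1e-12)
    assert res.cost_pd == pytest.approx(exp_cpd, rel=1e-12)
    assert res.qaly_pfs == pytest.approx(exp_qpfs, rel=1e-12)
    assert res.qaly_pd == pytest.approx(exp_qpd, rel=1e-12)


def test_full_year_in_pfs_yields_utility_in_qalys():
    """12 undiscounted cycles fully progression-free accrue u_pfs QALYs."""
    config = cfg(horizon=12, annual_discount_rate=0.0,
                 accrual_convention="end-of-cycle")
    res = m.accumulate(
        m.run_trace(np.eye(3), config),
        m.StateCosts(0.0, 0.0, 0.0, 0.0),
        m.UtilitySet(0.76, 0.68),
        config,
    )
    assert res.qaly_total == pytest.approx(0.76)
    assert res.cost_total == 0.0


def test_zero_discount_equates_discounted_and_undiscounted():
    config = cfg(horizon=40, annual_discount_rate=0.0)
    res = m.accumulate(
        m.run_trace(m.build_transition_matrix(CR), config),
        m.StateCosts(1000.0, 100.0, 10.0, 500.0),
        m.UtilitySet(),
        config,
    )
    assert res.cost_total == pytest.approx(res.cost_total_undiscounted)
    assert res.qaly_total == pytest.approx(res.qaly_total_undiscounted)


def test_cost_linearity_and_qaly_invariance():
    config = cfg(horizon=60)
    trace = m.run_trace(m.build_transition_matrix(CR), config)
    utils = m.UtilitySet()
    c1 = m.StateCosts(800.0, 170.0, 40.0, 590.0)
    c2 = m.StateCosts(1600.0, 340.0, 80.0, 1180.0)
    r1 = m.accumulate(trace, c1, utils, config)
    r2 = m.accumulate(trace, c2, utils, config)
    assert r2.cost_total == pytest.approx(2 * r1.cost_total, rel=1e-12)
    assert r2.qaly_total == r1.qaly_total


def test_unit_utilities_measure_life_years():
    """With utilities (1,1) and no discounting, QALYs = person-years alive."""
    config = cfg(horizon=120, annual_discount_rate=0.0,
                 accrual_convention="end-of-cycle")
    trace = m.run_trace(m.build_transition_matrix(CR), config)
    res = m.accumulate(
        trace, m.StateCosts(0, 0, 0, 0), m.UtilitySet(1.0, 1.0), config
    )
    alive_cycles = trace.occupancy[1:, :2].sum()
    assert res.qaly_total == pytest.approx(alive_cycles / 12)


def test_one_time_ae_cost_added_once_undiscounted():
    base = cfg(horizon=12)
    one = dataclasses.replace(base, ae_cost_mode=m.AECostMode.ONE_TIME)
    items = m.CostLineItems(drug_a=100.0, ae=50.0)
    trace = m.run_trace(m.build_transition_matrix(CR), base)
    r = m.accumulate(trace, m.aggregate_state_costs(items, one), m.UtilitySet(), one)
    r0 = m.accumulate(
        trace,
        m.StateCosts(pfs_drug_cost=100.0, pfs_test_cost=0, pfs_ae_cost=0, pd_cost=0),
        m.UtilitySet(),
        one,
    )
    assert r.cost_total == pytest.approx(r0.cost_total + 50.0)


# -- survival curves ----------------------------------------------------------


def test_model_survival_shapes_and_examples():
    config = cfg(horizon=10)
    pfs, osc = m.model_survival(m.run_trace(np.eye(3), config))
    assert np.all(pfs == 1.0) and np.all(osc == 1.0)

    M = m.build_transition_matrix(m.TransitionProbs(0.0, 1.0, 0.0))
    _, osc = m.model_survival(m.run_trace(M, config))
    assert osc[0] == 1.0 and np.all(osc[1:] == 0.0)

    pfs, osc = m.model_survival(m.run_trace(m.build_transition_matrix(CR), config))
    assert np.all(np.diff(pfs) <= 1e-15)
    assert np.all(np.diff(osc) <= 1e-15)


def test_model_median_os_regression():
    """Model-implied C+R median OS (regression value, months)."""
    assert m.model_median(CR, "OS") == pytest.approx(18.4654, abs=1e-3)
    assert 18.0 <= m.model_median(CR, "OS") <= 22.0
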