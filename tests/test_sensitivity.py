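"""One-way (tornado) and probabilistic sensitivity analysis."""

import numpy as np
import pytest

import markovcea as m
from markovcea.sensitivity import ParameterRef, owsa_frame

# -- OWSA ---------------------------------------------------------------------


def test_owsa_inputs_are_plus_minus_20_percent(model):
    ref = ParameterRef("cost", "drug_a", "A+B")  # atezolizumab
    (row,) = m.owsa(model, strategy="A+B", parameters=[ref])
    assert row.base_input == pytest.approx(6043.3532)
    assert row.low_input == pytest.approx(4834.68, abs=0.005)
    assert row.high_input == pytest.approx(7252.02, abs=0.005)


def test_owsa_linear_parameter_symmetric_about_base(model):
    """A strategy's CER is affine in its own drug cost, so the ±20% outcomes
    sit symmetrically around the base-case CER."""
    ref = ParameterRef("cost", "drug_a", "A+B")
    (row,) = m.owsa(model, strategy="A+B", parameters=[ref])
    assert row.outcome_high - row.outcome_base == pytest.approx(
        row.outcome_base - row.outcome_low, rel=1e-6
    )
    assert row.outcome_low < row.outcome_base < row.outcome_high


def test_owsa_unrelated_parameter_has_zero_width(model):
    """Perturbing another strategy's cost cannot move this strategy's CER."""
    ref = ParameterRef("cost", "drug_a", "C+R")
    (row,) = m.owsa(model, strategy="A+B", parameters=[ref])
    assert row.range_width == 0.0


def test_owsa_orders_by_range_and_exports(model):
    rows = m.owsa(model, strategy="A+B", reference="C+R")
    widths = [r.range_width for r in rows]
    assert widths == sorted(widths, reverse=True)
    df = owsa_frame(rows)
    assert {"parameter", "low_input", "high_input", "range_width"} <= set(df.columns)
    # on the strategy's own CER the widest bar is the expensive drug's cost
    cer_rows = m.owsa(model, strategy="A+B")
    assert cer_rows[0].parameter.label == "drug_a[A+B]"


def test_owsa_unknown_parameter_rejected(model):
    with pytest.raises(KeyError):
        m.owsa(model, strategy="A+B",
               parameters=[ParameterRef("cost", "drug_a", "nope")])
    with pytest.raises(ValueError):
        ParameterRef("cost", "not_an_item", "A+B")


# -- PSA sampling -------------------------------------------------------------


def test_psa_sampling_moments_and_determinism(model):
    n = 10_000
    d1 = m.sample_psa_params(model, n, seed=7)
    d2 = m.sample_psa_params(model, n, seed=7)
    for k in d1:
        assert np.array_equal(d1[k], d2[k])
    # gamma cost draws: mean within 3 standard errors of base
    base = model.strategy("A+B").costs.drug_a
    sd = 0.2 * base / 1.96
    x = d1["drug_a[A+B]"]
    assert abs(x.mean() - base) < 3 * sd / np.sqrt(n)
    assert np.all(x >= 0)
    # beta utility draws: the SD rule gives sd ~ 0.0776 for mean 0.76
    u = d1["u_pfs"]
    assert abs(u.mean() - 0.76) < 3 * 0.0776 / np.sqrt(n)
    assert u.std() == pytest.approx(0.0776, rel=0.05)
    assert np.all((u >= 0) & (u <= 1))


def test_infeasible_beta_sd_is_shrunk_with_warning(model):
    strat = model.strategy("C+R")
    from dataclasses import replace

    tweaked = model.with_strategy(
        replace(strat, utilities=m.UtilitySet(u_pfs=0.995, u_pd=0.68))
    )
    with pytest.warns(UserWarning, match="shrunk"):
        d = m.sample_psa_params(tweaked, 1000, seed=1)
    assert np.all(d["u_pfs"] <= 1.0)


def test_run_psa_single_iteration_matches_rebuilt_model(model):
    """Oracle replay: totals of one PSA draw equal a model rebuilt by hand
    from that draw's sampled costs and utilities."""
    psa = m.run_psa(model, n_iterations=1, seed=123)
    draws = psa.draws
    for j, s in enumerate(model.strategies):
        sc = m.StateCosts(
            pfs_drug_cost=float(draws[f"drug_a[{s.name}]"][0] + draws[f"drug_b[{s.name}]"][0]),
            pfs_test_cost=float(draws["test"][0]),
            pfs_ae_cost=float(draws[f"ae[{s.name}]"][0]),
            pd_cost=float(draws[f"pd[{s.name}]"][0]),
        )
        uu = m.UtilitySet(float(draws["u_pfs"][0]), float(draws["u_pd"][0]))
        r = m.evaluate_strategy(s, model.config, state_costs=sc, utilities=uu)
        assert psa.costs[0, j] == pytest.approx(r.cost_total, rel=1e-12)
        assert psa.qalys[0, j] == pytest.approx(r.qaly_total, rel=1e-12)


def test_zero_variance_psa_reproduces_base_case(model, base_results):
    psa = m.run_psa(model, n_iterations=5, seed=9, spread=0.0)
    for j, name in enumerate(psa.names):
        assert np.allclose(psa.costs[:, j], base_results[name].cost_total)
        assert np.allclose(psa.qalys[:, j], base_results[name].qaly_total)


def test_psa_variance_to_zero_converges_to_base(model, base_results):
    psa = m.run_psa(model, n_iterations=50, seed=9, spread=1e-4)
    base_c = np.array([base_results[n].cost_total for n in psa.names])
    assert np.max(np.abs(psa.costs - base_c) / base_c) < 0.01


def test_psa_with_sampled_probabilities_matches_per_draw_rebuild(model):
    """The vectorized sampled-probability path equals strategy-by-strategy
    reruns with the drawn probabilities substituted."""
    psa = m.run_psa(model, n_iterations=3, seed=5, include_probs=True)
    d = psa.draws
    for i in range(3):
        for j, s in enumerate(model.strategies):
            from dataclasses import replace

            tp = m.TransitionProbs(
                float(min(d[f"p_pfs_pd[{s.name}]"][i],
                          0.999 - d[f"p_pfs_death[{s.name}]"][i])),
                float(d[f"p_pfs_death[{s.name}]"][i]),
                float(d[f"p_pd_death[{s.name}]"][i]),
            )
            sc = m.StateCosts(
                pfs_drug_cost=float(d[f"drug_a[{s.name}]"][i] + d[f"drug_b[{s.name}]"][i]),
                pfs_test_cost=float(d["test"][i]),
                pfs_ae_cost=float(d[f"ae[{s.name}]"][i]),
                pd_cost=float(d[f"pd[{s.name}]"][i]),
            )
            uu = m.UtilitySet(float(d["u_pfs"][i]), float(d["u_pd"][i]))
            r = m.evaluate_strategy(
                replace(s, probs=tp), model.config, state_costs=sc, utilities=uu
            )
            assert psa.costs[i, j] == pytest.approx(r.cost_total, rel=1e-9)
            assert psa.qalys[i, j] == pytest.approx(r.qaly_total, rel=1e-9)


def test_psa_scatter_shape(model):
    psa = m.run_psa(model, n_iterations=20, seed=3)
    df = psa.scatter("C+R")
    assert df.shape == (20, 8)  # (ΔC, ΔE) for 4 non-reference strategies
    assert "delta_cost[S+B]" in df.columns


# -- CEAC and crossover -------------------------------------------------------


def test_ceac_proportions_sum_to_one(model):
    psa = m.run_psa(model, n_iterations=500, seed=21)
    curve = m.ceac(psa, np.arange(0, 100_001, 5_000.0))
    assert np.allclose(curve.acceptability.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(curve.acceptability >= 0)


def test_degenerate_ceac_is_indicator_of_deterministic_winner(model, base_results):
    psa = m.run_psa(model, n_iterations=10, seed=2, spread=0.0)
    curve = m.ceac(psa, np.array([10_000.0, 35_526.9, 100_000.0]))
    for i, w in enumerate(curve.wtps):
        nmbs = {n: m.nmb(base_results[n], w) for n in curve.names}
        winner = max(nmbs, key=nmbs.get)
        assert curve.acceptability[i, curve.names.index(winner)] == 1.0


def test_ceac_ties_split_equally():
    psa = m.PSAResult(
        names=["a", "b"],
        costs=np.array([[10.0, 10.0]]),
        qalys=np.array([[1.0, 1.0]]),
    )
    curve = m.ceac(psa, np.array([0.0, 50.0]))
    assert np.allclose(curve.acceptability, 0.5)


def test_crossover_recovers_deterministic_indifference(published_results):
    """A zero-variance CEAC over the published totals crosses at their
    incremental cost-effectiveness ratio (to grid resolution)."""
    names = list(published_results)
    costs = np.array([[published_results[n].cost_total for n in names]])
    qalys = np.array([[published_results[n].qaly_total for n in names]])
    psa = m.PSAResult(names=names, costs=np.repeat(costs, 4, 0), qalys=np.repeat(qalys, 4, 0))
    curve = m.ceac(psa, m.default_wtp_grid())
    w = m.crossover_wtp(curve, "C+R", "S+B")
    assert w is not None
    assert abs(w - 70_725.38) <= 500.0  # one grid step


def test_crossover_none_when_never_overtaken():
    curve = m.CEACCurve(
        wtps=np.array([0.0, 1.0, 2.0]),
        names=["a", "b"],
        acceptability=np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]]),
    )
    assert m.crossover_wtp(curve, "a", "b") is None
    assert m.crossover_wtp(curve, "b", "a") == 0.0


def test_crossover_flags_unsustained_crossing():
    acc = np.array([[0.4, 0.6], [0.6, 0.4], [0.3, 0.7], [0.2, 0.8]])
    curve = m.CEACCurve(np.arange(4.0), ["a", "b"], acc)
    with pytest.warns(UserWarning, match="multiple times"):
        assert m.crossover_wtp(curve, "a", "b") == 2.0


def test_ceac_rejects_bad_grid(model):
    psa = m.run_psa(model, n_iterations=5, seed=1)
    with pytest.raises(ValueError):
        m.ceac(psa, np.array([]))
    with pytest.raises(ValueError):
        m.ceac(psa, np.array([1.0, 1.0]))
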