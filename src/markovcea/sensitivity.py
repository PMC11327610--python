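"""Deterministic and probabilistic sensitivity analysis.

One-way analysis (the tornado diagram) reruns the deterministic model with a
single parameter at ±20% of base; probabilistic analysis draws every cost
from a moment-matched gamma distribution and every utility from a
moment-matched beta distribution, reruns all strategies per draw, and
summarizes the result as an incremental scatter and cost-effectiveness
acceptability curves (CEAC).

The published ±20% ranges come without variances; the sampling rule here is
SD = spread·mean/1.96 (the 95% interval of an approximately normal
distribution spans the stated range), with ``spread`` configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .economics import WTPThreshold
from .engine import CEResult
from .model import DecisionModel, StrategyInputs, evaluate_all
from .parameters import (
    AECostMode,
    CostLineItems,
    TransitionProbs,
    UtilitySet,
    build_transition_matrix,
)
from .engine import discount_factors, run_trace
from . import economics

__all__ = [
    "ParameterRef",
    "OWSAResult",
    "PSAResult",
    "CEACCurve",
    "default_parameters",
    "apply_parameter",
    "owsa",
    "sample_psa_params",
    "run_psa",
    "ceac",
    "crossover_wtp",
    "default_wtp_grid",
]

_COST_ITEMS = ("drug_a", "drug_b", "test", "ae", "pd")
_PROB_ITEMS = ("p_pfs_pd", "p_pfs_death", "p_pd_death")


@dataclass(frozen=True)
class ParameterRef:
    """Address of one tunable model parameter.

    ``kind`` is ``"cost"`` (per-strategy cost line item), ``"utility"``
    (global, applied to every strategy) or ``"prob"`` (per-strategy
    transition probability).  ``item`` names the field; ``strategy`` is
    required except for utilities.
    """

    kind: str
    item: str
    strategy: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cost", "utility", "prob"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "cost" and self.item not in _COST_ITEMS:
            raise ValueError(f"unknown cost item {self.item!r}")
        if self.kind == "prob" and self.item not in _PROB_ITEMS:
            raise ValueError(f"unknown probability {self.item!r}")
        if self.kind == "utility" and self.item not in ("u_pfs", "u_pd"):
            raise ValueError(f"unknown utility {self.item!r}")
        if self.kind != "utility" and self.strategy is None:
            raise ValueError(f"{self.kind} parameter needs a strategy")

    @property
    def label(self) -> str:
        if self.kind == "utility":
            return self.item
        return f"{self.item}[{self.strategy}]"


def _base_value(model: DecisionModel, ref: ParameterRef) -> float:
    if ref.kind == "utility":
        return getattr(model.strategies[0].utilities, ref.item)
    strat = model.strategy(ref.strategy)
    if ref.kind == "cost":
        return getattr(strat.costs, ref.item)
    return getattr(strat.transition_probs(model.config.cycle_length), ref.item)


def apply_parameter(
    model: DecisionModel, ref: ParameterRef, value: float
) -> DecisionModel:
    """Copy of the model with one parameter set to ``value``.

    Utilities are global: the new value is written into every strategy.
    """
    if ref.kind == "utility":
        out = model
        for s in model.strategies:
            u = s.utilities
            kw = {"u_pfs": u.u_pfs, "u_pd": u.u_pd}
            kw[ref.item] = value
            out = out.with_strategy(replace(s, utilities=UtilitySet(**kw)))
        return out
    strat = model.strategy(ref.strategy)
    if ref.kind == "cost":
        return model.with_strategy(
            replace(strat, costs=replace(strat.costs, **{ref.item: value}))
        )
    tp = strat.transition_probs(model.config.cycle_length)
    kw = {k: getattr(tp, k) for k in _PROB_ITEMS}
    kw[ref.item] = value
    return model.with_strategy(replace(strat, probs=TransitionProbs(**kw)))


def default_parameters(
    model: DecisionModel, include_probs: bool = False
) -> list[ParameterRef]:
    """Every non-zero cost item per strategy, the two global utilities,
    and (optionally) every transition probability."""
    refs: list[ParameterRef] = [
        ParameterRef("utility", "u_pfs"),
        ParameterRef("utility", "u_pd"),
    ]
    for s in model.strategies:
        for item in _COST_ITEMS:
            if getattr(s.costs, item) > 0:
                refs.append(ParameterRef("cost", item, s.name))
        if include_probs:
            for item in _PROB_ITEMS:
                refs.append(ParameterRef("prob", item, s.name))
    return refs


@dataclass(frozen=True)
class OWSAResult:
    """One tornado bar: a parameter's ±spread inputs and outcome endpoints."""

    parameter: ParameterRef
    base_input: float
    low_input: float
    high_input: float
    outcome_base: float
    outcome_low: float
    outcome_high: float

    @property
    def range_width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def owsa(
    model: DecisionModel,
    strategy: str,
    reference: str | None = None,
    parameters: list[ParameterRef] | None = None,
    spread: float = 0.2,
) -> list[OWSAResult]:
    """One-way sensitivity analysis on the given strategy's outcome.

    The outcome is the strategy's CER, or its ICER versus ``reference`` when
    a reference strategy is named.  Each parameter is rerun at
    ``(1-spread)`` and ``(1+spread)`` times base with everything else fixed.
    Results are ordered by outcome range, widest first (tornado order).
    """
    if parameters is None:
        parameters = default_parameters(model)

    def outcome(m: DecisionModel) -> float:
        res = evaluate_all(m)
        if reference is None:
            return economics.cer(res[strategy])
        # tornado outcome: the raw incremental ratio, defined even when the
        # comparison is dominance (negative QALY difference gives a negative
        # ratio, which is how such bars are conventionally plotted)
        a, b = res[strategy], res[reference]
        de = a.qaly_total - b.qaly_total
        if de == 0.0:
            raise ValueError(
                f"ICER outcome undefined: {strategy} and {reference} have equal QALYs"
            )
        return (a.cost_total - b.cost_total) / de

    base_outcome = outcome(model)
    out = []
    for ref in parameters:
        base = _base_value(model, ref)
        if not base > 0:
            raise ValueError(f"parameter {ref.label} has non-positive base value")
        lo, hi = (1.0 - spread) * base, (1.0 + spread) * base
        out.append(
            OWSAResult(
                parameter=ref,
                base_input=base,
                low_input=lo,
                high_input=hi,
                outcome_base=base_outcome,
                outcome_low=outcome(apply_parameter(model, ref, lo)),
                outcome_high=outcome(apply_parameter(model, ref, hi)),
            )
        )
    out.sort(key=lambda r: -r.range_width)
    return out


def owsa_frame(results: list[OWSAResult]) -> pd.DataFrame:
    """Tornado table."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter.label for r in results],
            "low_input": [r.low_input for r in results],
            "high_input": [r.high_input for r in results],
            "outcome_low": [r.outcome_low for r in results],
            "outcome_high": [r.outcome_high for r in results],
            "outcome_base": [r.outcome_base for r in results],
            "range_width": [r.range_width for r in results],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _gamma_draws(rng: np.ndarray, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0 or mean == 0.0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, n)


def _beta_draws(rng, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    cap = np.sqrt(mean * (1.0 - mean))
    if sd >= cap:
        warnings.warn(
            f"beta SD {sd:.4f} infeasible for mean {mean}; shrunk to {0.99 * cap:.4f}"
        )
        sd = 0.99 * cap
    k = mean * (1.0 - mean) / sd**2 - 1.0
    return rng.beta(mean * k, (1.0 - mean) * k, n)


def sample_psa_params(
    model: DecisionModel,
    n: int,
    seed: int | np.random.Generator,
    spread: float = 0.2,
    include_probs: bool = False,
) -> dict[str, np.ndarray]:
    """Draw the PSA parameter matrix.

    Costs ~ gamma, utilities (and, optionally, transition probabilities)
    ~ beta, each moment-matched to mean = base and SD = spread·base/1.96.
    The utilities and the routine-test unit cost are single shared parameters
    (one draw per iteration applied to every strategy); drug, AE and
    second-line costs are drawn per strategy.  Draws are parameter-major from
    one seeded generator in a fixed order, so a fixed seed reproduces the
    stream exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = lambda m: spread * m / 1.96  # noqa: E731

    u0 = model.strategies[0].utilities
    draws: dict[str, np.ndarray] = {
        "u_pfs": _beta_draws(rng, u0.u_pfs, sd(u0.u_pfs), n),
        "u_pd": _beta_draws(rng, u0.u_pd, sd(u0.u_pd), n),
        "test": _gamma_draws(rng, model.strategies[0].costs.test, sd(model.strategies[0].costs.test), n),
    }
    for s in model.strategies:
        for item in ("drug_a", "drug_b", "ae", "pd"):
            m = getattr(s.costs, item)
            draws[f"{item}[{s.name}]"] = _gamma_draws(rng, m, sd(m), n)
        if include_probs:
            tp = s.transition_probs(model.config.cycle_length)
            for item in _PROB_ITEMS:
                m = getattr(tp, item)
                draws[f"{item}[{s.name}]"] = _beta_draws(rng, m, sd(m), n)
    return draws


def _person_cycles(model: DecisionModel, strat: StrategyInputs) -> tuple[float, float]:
    """Discounted PFS/PD person-cycles of one strategy under the base probs."""
    from .engine import _accrual_weights  # local: private but shared bookkeeping

    trace = run_trace(
        build_transition_matrix(strat.transition_probs(model.config.cycle_length)),
        model.config,
    )
    w, d = _accrual_weights(trace, model.config)
    return float(w[:, 0] @ d), float(w[:, 1] @ d)


def _person_cycles_batch(
    p: np.ndarray, model: DecisionModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized discounted person-cycles for a batch of probability triples."""
    cfg = model.config
    n = p.shape[0]
    occ = np.zeros((cfg.horizon + 1, n, 3))
    occ[0, :, 0] = 1.0
    stay_pfs = 1.0 - p[:, 0] - p[:, 1]
    stay_pd = 1.0 - p[:, 2]
    for t in range(cfg.horizon):
        occ[t + 1, :, 0] = occ[t, :, 0] * stay_pfs
        occ[t + 1, :, 1] = occ[t, :, 1] * stay_pd + occ[t, :, 0] * p[:, 0]
        occ[t + 1, :, 2] = 1.0 - occ[t + 1, :, 0] - occ[t + 1, :, 1]
    d = discount_factors(cfg)
    from .parameters import Accrual

    conv = cfg.accrual_convention
    if conv is Accrual.END:
        w, dd = occ[1:], d[1:]
    elif conv is Accrual.START:
        w, dd = occ[:-1], d[:-1]
    else:
        w, dd = 0.5 * (occ[:-1] + occ[1:]), d[:-1]
    pc = np.tensordot(dd, w, axes=(0, 0))  # (n, 3)
    return pc[:, 0], pc[:, 1]


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo totals: one row per iteration, one column per strategy."""

    names: list[str]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def scatter(self, reference: str) -> pd.DataFrame:
        """Incremental (ΔC, ΔE) of every strategy versus the reference."""
        j = self.names.index(reference)
        rows = {}
        for k, name in enumerate(self.names):
            if name == reference:
                continue
            rows[f"delta_cost[{name}]"] = self.costs[:, k] - self.costs[:, j]
            rows[f"delta_qaly[{name}]"] = self.qalys[:, k] - self.qalys[:, j]
        return pd.DataFrame(rows)


def run_psa(
    model: DecisionModel,
    n_iterations: int = 10_000,
    seed: int | None = None,
    spread: float = 0.2,
    include_probs: bool = False,
) -> PSAResult:
    """Second-order Monte Carlo: rerun all strategies per parameter draw.

    Transition probabilities are held at base by default (the published
    distribution assignments cover costs and utilities only);
    ``include_probs=True`` additionally samples them from beta
    distributions.  With probabilities fixed, each strategy's discounted
    person-cycles are computed once and the per-iteration totals follow
    exactly (costs and QALYs are linear in the sampled values given the
    occupancy trace).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    draws = sample_psa_params(model, n_iterations, seed, spread, include_probs)
    one_time_ae = model.config.ae_cost_mode is AECostMode.ONE_TIME

    k = len(model.strategies)
    costs = np.empty((n_iterations, k))
    qalys = np.empty((n_iterations, k))
    cyc_years = model.config.cycle_length / 12.0
    for j, s in enumerate(model.strategies):
        if include_probs:
            p = np.column_stack(
                [draws[f"{item}[{s.name}]"] for item in _PROB_ITEMS]
            )
            p[:, 0] = np.minimum(p[:, 0], 0.999 - p[:, 1])  # keep rows stochastic
            a, b = _person_cycles_batch(p, model)
        else:
            a, b = _person_cycles(model, s)
        ae = draws[f"ae[{s.name}]"]
        pfs_cost = draws[f"drug_a[{s.name}]"] + draws[f"drug_b[{s.name}]"] + draws["test"]
        if one_time_ae:
            costs[:, j] = a * pfs_cost + b * draws[f"pd[{s.name}]"] + ae
        else:
            costs[:, j] = a * (pfs_cost + ae) + b * draws[f"pd[{s.name}]"]
        qalys[:, j] = (a * draws["u_pfs"] + b * draws["u_pd"]) * cyc_years
    return PSAResult(
        names=model.strategy_names,
        costs=costs,
        qalys=qalys,
        draws=draws,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability (probability of being optimal) per strategy over WTP."""

    wtps: np.ndarray
    names: list[str]
    acceptability: np.ndarray  # (len(wtps), n_strategies)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.acceptability, columns=self.names)
        df.insert(0, "wtp", self.wtps)
        return df


def default_wtp_grid(stop: float = 150_000.0, step: float = 500.0) -> np.ndarray:
    """WTP grid 0..stop in steps of ``step`` USD/QALY."""
    return np.arange(0.0, stop + step / 2, step)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Fraction of iterations in which each strategy has the highest NMB.

    Exact NMB ties within an iteration are split equally among the tied
    strategies, so acceptability sums to 1 at every grid point.
    """
    wtps = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if wtps.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if np.any(np.diff(wtps) <= 0):
        raise ValueError("WTP grid must be strictly increasing")
    acc = np.empty((wtps.size, len(psa.names)))
    for i, w in enumerate(wtps):
        nmb = w * psa.qalys - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-6)
        acc[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(wtps=wtps, names=list(psa.names), acceptability=acc)


def crossover_wtp(curve: CEACCurve, a: str, b: str) -> float | None:
    """Smallest grid WTP at which ``b`` overtakes ``a`` for good.

    Returns the first WTP where ``b``'s acceptability strictly exceeds
    ``a``'s and never falls below it again on the grid; ``None`` if ``b``
    never overtakes.  Earlier unsustained crossings trigger an instability
    warning.
    """
    ja, jb = curve.names.index(a), curve.names.index(b)
    diff = curve.acceptability[:, jb] - curve.acceptability[:, ja]
    above = diff > 0
    sustained = above & (np.minimum.accumulate(diff[::-1])[::-1] >= 0)
    idx = np.nonzero(sustained)[0]
    if idx.size == 0:
        return None
    first = int(idx[0])
    if np.any(above[:first]):
        warnings.warn(
            f"CEAC of {b!r} crosses {a!r} multiple times; "
            "reporting the first sustained crossing"
        )
    return float(curve.wtps[first])
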