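"""Cohort simulation and discounted cost/QALY accrual.

The whole cohort starts progression-free and is pushed through the
row-stochastic monthly transition matrix for the model horizon.  Costs accrue
as (state occupancy) x (per-cycle state cost) x (discount factor); QALYs as
(state occupancy) x (annual utility x cycle_length/12) x (discount factor).
Where within the cycle occupancy is counted (start, end, or the half-cycle
average) and how the annual discount rate is mapped to monthly factors are
explicit conventions carried in :class:`~markovcea.parameters.ModelConfig`,
because published cohort models are rarely explicit about either and the
choice moves totals by several percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    Accrual,
    AECostMode,
    Discounting,
    ModelConfig,
    StateCosts,
    UtilitySet,
)

__all__ = [
    "MarkovTrace",
    "CEResult",
    "discount_factor",
    "discount_factors",
    "run_trace",
    "accumulate",
    "model_survival",
]

_MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort occupancy over cycles 0..horizon.

    ``occupancy`` has shape ``(horizon+1, 3)`` with columns (PFS, PD, Death);
    every row sums to 1 and the death column is non-decreasing.
    """

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 3 or occ.shape[0] < 2:
            raise ValueError("occupancy must have shape (horizon+1, 3)")
        if np.any(occ < -1e-12):
            raise ValueError("occupancy shares must be non-negative")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Cycle-indexed occupancy table."""
        return pd.DataFrame(
            self.occupancy,
            columns=["share_pfs", "share_pd", "share_death"],
            index=pd.RangeIndex(self.occupancy.shape[0], name="cycle"),
        )


@dataclass(frozen=True)
class CEResult:
    """Discounted (and undiscounted) cost and QALY totals with state breakdown."""

    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float
    cost_pfs_undiscounted: float = 0.0
    cost_pd_undiscounted: float = 0.0
    qaly_pfs_undiscounted: float = 0.0
    qaly_pd_undiscounted: float = 0.0

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd

    @property
    def cost_total_undiscounted(self) -> float:
        return self.cost_pfs_undiscounted + self.cost_pd_undiscounted

    @property
    def qaly_total_undiscounted(self) -> float:
        return self.qaly_pfs_undiscounted + self.qaly_pd_undiscounted

    @classmethod
    def from_totals(cls, cost_total: float, qaly_total: float) -> "CEResult":
        """Wrap bare (cost, QALY) totals, e.g. values quoted from a report.

        The per-state split is unknown, so everything is booked to the PFS
        component; totals and every downstream ratio are unaffected.
        """
        return cls(
            cost_pfs=cost_total,
            cost_pd=0.0,
            qaly_pfs=qaly_total,
            qaly_pd=0.0,
            cost_pfs_undiscounted=cost_total,
            cost_pd_undiscounted=0.0,
            qaly_pfs_undiscounted=qaly_total,
            qaly_pd_undiscounted=0.0,
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "cost_pfs": self.cost_pfs,
            "cost_pd": self.cost_pd,
            "cost_total": self.cost_total,
            "qaly_pfs": self.qaly_pfs,
            "qaly_pd": self.qaly_pd,
            "qaly_total": self.qaly_total,
            "cost_total_undiscounted": self.cost_total_undiscounted,
            "qaly_total_undiscounted": self.qaly_total_undiscounted,
        }


def discount_factor(cycle_index: int | np.ndarray, config: ModelConfig) -> float | np.ndarray:
    """Discount factor at the given cycle index under the configured mode."""
    t = np.asarray(cycle_index, dtype=float)
    if np.any(t < 0):
        raise ValueError("cycle_index must be >= 0")
    r = config.annual_discount_rate
    months = t * config.cycle_length
    mode = config.discount_compounding
    if mode is Discounting.CONTINUOUS_MONTHLY:
        out = (1.0 + r) ** (-months / _MONTHS_PER_YEAR)
    elif mode is Discounting.ANNUAL_STEP:
        out = (1.0 + r) ** (-np.floor(months / _MONTHS_PER_YEAR))
    elif mode is Discounting.PER_CYCLE:
        out = (1.0 - r) ** t
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown discounting mode {mode!r}")
    return out if out.ndim else float(out)


def discount_factors(config: ModelConfig) -> np.ndarray:
    """Vector of discount factors for cycles 0..horizon."""
    return np.asarray(discount_factor(np.arange(config.horizon + 1), config))


def run_trace(matrix: np.ndarray, config: ModelConfig) -> MarkovTrace:
    """Propagate the cohort: ``occupancy(t+1) = occupancy(t) @ matrix``.

    The cohort starts fully progression-free at cycle 0.
    """
    M = np.asarray(matrix, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3")
    if np.any(M < -1e-12) or not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    occ = np.empty((config.horizon + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for t in range(config.horizon):
        occ[t + 1] = occ[t] @ M
    return MarkovTrace(occ)


def _accrual_weights(trace: MarkovTrace, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle membership weights and matching discount factors.

    One weight row per model cycle 1..horizon.  END counts membership after
    each transition (discounted at the end index); START counts membership
    before it (discounted at the start index); HALF uses the trapezoid of the
    two (discounted at the start index, the usual half-cycle-corrected
    bookkeeping of decision-tree software).
    """
    occ = trace.occupancy
    d = discount_factors(config)
    conv = config.accrual_convention
    if conv is Accrual.END:
        return occ[1:], d[1:]
    if conv is Accrual.START:
        return occ[:-1], d[:-1]
    if conv is Accrual.HALF:
        return 0.5 * (occ[:-1] + occ[1:]), d[:-1]
    raise ValueError(f"accrual convention unset or unknown: {conv!r}")


def accumulate(
    trace: MarkovTrace,
    costs: StateCosts,
    utilities: UtilitySet,
    config: ModelConfig,
) -> CEResult:
    """Accrue discounted costs and QALYs over the trace.

    Utilities are annual weights, so each cycle contributes
    ``utility * cycle_length / 12`` QALYs per person-cycle.  A one-time AE
    cost (if configured) is charged undiscounted at model entry and booked to
    the PFS component.
    """
    w, d = _accrual_weights(trace, config)
    pc_pfs = float(w[:, 0] @ d)
    pc_pd = float(w[:, 1] @ d)
    pc_pfs_undisc = float(w[:, 0].sum())
    pc_pd_undisc = float(w[:, 1].sum())

    cycle_years = config.cycle_length / _MONTHS_PER_YEAR
    ae_once = costs.ae_one_time if config.ae_cost_mode is AECostMode.ONE_TIME else 0.0
    return CEResult(
        cost_pfs=pc_pfs * costs.pfs_total + ae_once,
        cost_pd=pc_pd * costs.pd_cost,
        qaly_pfs=pc_pfs * utilities.u_pfs * cycle_years,
        qaly_pd=pc_pd * utilities.u_pd * cycle_years,
        cost_pfs_undiscounted=pc_pfs_undisc * costs.pfs_total + ae_once,
        cost_pd_undiscounted=pc_pd_undisc * costs.pd_cost,
        qaly_pfs_undiscounted=pc_pfs_undisc * utilities.u_pfs * cycle_years,
        qaly_pd_undiscounted=pc_pd_undisc * utilities.u_pd * cycle_years,
    )


def model_survival(trace: MarkovTrace) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied PFS and OS curves, one value per cycle 0..horizon.

    ``pfs(t)`` is the PFS-state share; ``os(t) = 1 - death share``.  Both are
    non-increasing, which is what lets them be compared against trial
    Kaplan-Meier curves.
    """
    occ = trace.occupancy
    return occ[:, 0].copy(), 1.0 - occ[:, 2]
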