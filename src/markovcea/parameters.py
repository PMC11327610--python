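"""Transition probabilities, costs and utilities for the three-state cohort model.

Trial reports of first-line oncology regimens usually publish median
progression-free survival (PFS) and median overall survival (OS) rather than
per-cycle transition probabilities.  Under a constant-hazard (exponential)
assumption the two are interchangeable: a median time-to-event ``m`` implies a
per-cycle event probability ``p = 1 - 0.5**(cycle_length / m)``.  This module
performs that conversion, assembles the monthly transition matrix over the
states {PFS, PD, Death}, and aggregates per-cycle cost line items into
state-level costs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Accrual",
    "Discounting",
    "AECostMode",
    "TrialSummary",
    "TransitionProbs",
    "CostLineItems",
    "StateCosts",
    "UtilitySet",
    "ModelConfig",
    "CalibrationRequired",
    "prob_from_median",
    "prob_to_rate",
    "rate_to_prob",
    "derive_transition_probs",
    "build_transition_matrix",
    "aggregate_state_costs",
]

#: State ordering used throughout the package.
STATES = ("PFS", "PD", "Death")


class CalibrationRequired(ValueError):
    """Raised when a median needed for derivation is absent.

    The caller should fall back to Kaplan-Meier calibration
    (:mod:`markovcea.calibration`), as is necessary when a trial's median OS
    was not reached at data cut-off.
    """


class Accrual(str, enum.Enum):
    """When state membership is counted within each cycle."""

    END = "end-of-cycle"
    START = "start-of-cycle"
    HALF = "half-cycle"


class Discounting(str, enum.Enum):
    """How the annual discount rate is applied to monthly cycles.

    ``CONTINUOUS_MONTHLY``: factor ``(1+r)**(-t/12)`` at month ``t`` (the
    standard economics convention).  ``ANNUAL_STEP``: the factor changes once
    a year, ``(1+r)**(-floor(t/12))``.  ``PER_CYCLE``: the nominal rate is
    applied per cycle, ``(1-r)**t`` — not recommended for new analyses, but
    provided because decision-tree software is frequently (mis)configured this
    way and reproducing published models can require it.
    """

    CONTINUOUS_MONTHLY = "continuous-monthly"
    ANNUAL_STEP = "annual-step"
    PER_CYCLE = "per-cycle-rate"


class AECostMode(str, enum.Enum):
    """Adverse-event management cost: charged every PFS cycle or once."""

    PER_CYCLE = "per-cycle"
    ONE_TIME = "one-time"


@dataclass(frozen=True)
class TrialSummary:
    """Published summary statistics for one treatment strategy.

    Medians are in months; ``None`` marks a median that was not reached /
    not reported, which routes the strategy to KM calibration instead of the
    closed-form derivation.
    """

    strategy_name: str
    median_pfs: float | None = None
    median_os: float | None = None
    subsequent_treatment_fraction: float = 0.0
    grade34_ae_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("median_pfs", "median_os"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.median_pfs is not None and self.median_os is not None:
            if not self.median_os > self.median_pfs:
                raise ValueError(
                    "median_os must exceed median_pfs "
                    f"({self.median_os} <= {self.median_pfs})"
                )
        for name in ("subsequent_treatment_fraction", "grade34_ae_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class TransitionProbs:
    """Monthly transition probabilities between the three health states."""

    p_pfs_pd: float
    p_pfs_death: float
    p_pd_death: float

    def __post_init__(self) -> None:
        for name in ("p_pfs_pd", "p_pfs_death", "p_pd_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v!r}")
        if self.p_pfs_pd + self.p_pfs_death > 1.0 + 1e-12:
            raise ValueError(
                "p_pfs_pd + p_pfs_death exceeds 1 "
                f"({self.p_pfs_pd} + {self.p_pfs_death})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_pfs_pd, self.p_pfs_death, self.p_pd_death)


@dataclass(frozen=True)
class CostLineItems:
    """Per-cycle cost components (USD) for one strategy.

    ``drug_a``/``drug_b`` are the two agents of the combination, ``test`` the
    routine monitoring cost, ``ae`` the adverse-event management cost, and
    ``pd`` the progressive-disease (second-line) cost already averaged over
    second-line uptake.
    """

    drug_a: float = 0.0
    drug_b: float = 0.0
    test: float = 0.0
    ae: float = 0.0
    pd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("drug_a", "drug_b", "test", "ae", "pd"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost item {name} must be >= 0")


@dataclass(frozen=True)
class StateCosts:
    """Aggregated per-cycle state costs (USD/cycle).

    ``ae_one_time`` is non-zero only under :attr:`AECostMode.ONE_TIME`, in
    which case it is charged once at model start instead of entering the
    per-cycle PFS cost.
    """

    pfs_drug_cost: float
    pfs_test_cost: float
    pfs_ae_cost: float
    pd_cost: float
    ae_one_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pfs_drug_cost", "pfs_test_cost", "pfs_ae_cost", "pd_cost", "ae_one_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def pfs_total(self) -> float:
        """Total PFS-state cost per cycle."""
        return self.pfs_drug_cost + self.pfs_test_cost + self.pfs_ae_cost


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utility weights; death is anchored at zero.

    Base-case inputs should satisfy ``u_pd <= u_pfs`` (progression does not
    improve quality of life) and configuration loading enforces that; the
    dataclass itself only requires each weight to lie in [0, 1], because
    sensitivity analyses legitimately perturb one utility at a time across
    the other's value (a ±20% tornado bar on u_pfs does exactly this).
    """

    u_pfs: float = 0.76
    u_pd: float = 0.68
    u_death: float = 0.0

    def __post_init__(self) -> None:
        if self.u_death != 0.0:
            raise ValueError("u_death must be 0")
        for name in ("u_pfs", "u_pd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings of the cohort simulation.

    Defaults follow standard modelling practice (monthly cycles, 10-year
    horizon, 3%/year discount compounded continuously per month, end-of-cycle
    accrual).  Published models built in decision-tree software may require
    other conventions; all combinations are first-class.
    """

    cycle_length: float = 1.0  # months
    horizon: int = 120  # cycles
    annual_discount_rate: float = 0.03
    accrual_convention: Accrual = Accrual.END
    discount_compounding: Discounting = Discounting.CONTINUOUS_MONTHLY
    ae_cost_mode: AECostMode = AECostMode.PER_CYCLE

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValueError("annual_discount_rate must be in [0, 1)")
        # tolerate plain strings in configs
        object.__setattr__(self, "accrual_convention", Accrual(self.accrual_convention))
        object.__setattr__(
            self, "discount_compounding", Discounting(self.discount_compounding)
        )
        object.__setattr__(self, "ae_cost_mode", AECostMode(self.ae_cost_mode))


def prob_from_median(median: float, cycle_length: float = 1.0) -> float:
    """Per-cycle event probability implied by an exponential median.

    ``p = 1 - 0.5**(cycle_length/median)``, i.e. the event probability over
    one cycle when the time-to-event is exponential with median ``median``
    months.  ``median=inf`` maps to 0.

    Parameters
    ----------
    median : months, > 0
    cycle_length : months, > 0
    """
    if not median > 0:
        raise ValueError(f"median must be positive, got {median!r}")
    if not cycle_length > 0:
        raise ValueError(f"cycle_length must be positive, got {cycle_length!r}")
    if math.isinf(median):
        return 0.0
    return 1.0 - 0.5 ** (cycle_length / median)


def prob_to_rate(p: float, cycle_length: float = 1.0) -> float:
    """Instantaneous monthly rate equivalent to per-cycle probability ``p``.

    ``r = -ln(1-p)/cycle_length``; inverse of :func:`rate_to_prob`.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p!r}")
    if not cycle_length > 0:
        raise ValueError("cycle_length must be positive")
    return -math.log1p(-p) / cycle_length


def rate_to_prob(r: float, cycle_length: float = 1.0) -> float:
    """Per-cycle probability from a monthly rate: ``p = 1 - exp(-r*cycle)``."""
    if r < 0:
        raise ValueError(f"rate must be >= 0, got {r!r}")
    if not cycle_length > 0:
        raise ValueError("cycle_length must be positive")
    return -math.expm1(-r * cycle_length)


def derive_transition_probs(
    summary: TrialSummary, cycle_length: float = 1.0
) -> TransitionProbs:
    """Monthly transition probabilities from median PFS and OS.

    PFS→PD uses the PFS median, PFS→Death the OS median, and PD→Death the
    post-progression median ``median_os - median_pfs`` (the expected residual
    survival of progressing patients under the exponential assumption).

    Raises
    ------
    CalibrationRequired
        If either median is absent; such strategies must be calibrated to
        Kaplan-Meier curves instead.
    """
    if summary.median_pfs is None or summary.median_os is None:
        raise CalibrationRequired(
            f"strategy {summary.strategy_name!r}: median PFS/OS unavailable; "
            "calibrate transition probabilities to KM curves instead"
        )
    return TransitionProbs(
        p_pfs_pd=prob_from_median(summary.median_pfs, cycle_length),
        p_pfs_death=prob_from_median(summary.median_os, cycle_length),
        p_pd_death=prob_from_median(
            summary.median_os - summary.median_pfs, cycle_length
        ),
    )


def build_transition_matrix(tp: TransitionProbs) -> np.ndarray:
    """Row-stochastic 3x3 matrix over (PFS, PD, Death).

    Death is absorbing and there is no PD→PFS recovery.
    """
    p12, p13, p23 = tp.as_tuple()
    stay_pfs = 1.0 - p12 - p13
    if stay_pfs < -1e-12:
        raise ValueError("p_pfs_pd + p_pfs_death exceeds 1")
    return np.array(
        [
            [max(stay_pfs, 0.0), p12, p13],
            [0.0, 1.0 - p23, p23],
            [0.0, 0.0, 1.0],
        ]
    )


def aggregate_state_costs(
    line_items: CostLineItems, config: ModelConfig | None = None
) -> StateCosts:
    """Collapse cost line items into per-cycle state costs.

    Under the default per-cycle mode the AE cost is part of the recurring PFS
    cost (drug A + drug B + tests + AE); under one-time mode it is held aside
    and charged once at model entry.
    """
    config = config or ModelConfig()
    one_time = config.ae_cost_mode is AECostMode.ONE_TIME
    return StateCosts(
        pfs_drug_cost=line_items.drug_a + line_items.drug_b,
        pfs_test_cost=line_items.test,
        pfs_ae_cost=0.0 if one_time else line_items.ae,
        pd_cost=line_items.pd,
        ae_one_time=line_items.ae if one_time else 0.0,
    )
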