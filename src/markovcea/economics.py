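"""Cost-effectiveness ratios, dominance and the efficiency frontier.

Given each strategy's discounted cost and QALY totals this module computes
cost-effectiveness ratios (CER = cost/QALY), pairwise incremental ratios
(ICER = ΔC/ΔE), net monetary benefit (NMB = WTP·E − C), and classifies
strategies as on-frontier, dominated (another strategy costs no more and
yields at least as much health, one strictly), or extendedly dominated
(bypassed by a cheaper mixture of two frontier neighbours, detected as a
non-increasing incremental ICER sequence).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .engine import CEResult

__all__ = [
    "WTPThreshold",
    "Dominance",
    "IcerResult",
    "StrategyStatus",
    "FrontierReport",
    "cer",
    "icer",
    "nmb",
    "frontier",
]


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay per QALY (USD).

    The default is three times China's 2022 per-capita GDP, the WHO-style
    threshold used for the packaged analysis.
    """

    value: float = 35_526.90

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("WTP threshold must be >= 0")


class Dominance(str, enum.Enum):
    RATIO = "ratio"
    A_DOMINANT = "a dominant"
    A_DOMINATED = "a dominated"


@dataclass(frozen=True)
class IcerResult:
    """Outcome of an incremental comparison of strategy ``a`` against ``b``.

    ``ratio`` is the ICER in USD/QALY when the QALY difference is non-zero
    and neither strategy dominates; otherwise ``verdict`` carries the
    dominance classification and ``ratio`` is ``None``.
    """

    verdict: Dominance
    ratio: float | None = None

    def __float__(self) -> float:
        if self.ratio is None:
            raise ValueError(f"no ICER: {self.verdict.value}")
        return self.ratio


class StrategyStatus(str, enum.Enum):
    ON_FRONTIER = "on-frontier"
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly-dominated"


@dataclass(frozen=True)
class FrontierReport:
    """Dominance classification and frontier ICERs across strategies."""

    status: dict[str, StrategyStatus]
    dominated_by: dict[str, str | None]
    frontier: list[str]  # ordered by increasing cost
    frontier_icers: list[float]  # between consecutive frontier strategies
    results: dict[str, CEResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, st in self.status.items():
            r = self.results.get(name)
            rows.append(
                {
                    "strategy": name,
                    "cost_total": r.cost_total if r else float("nan"),
                    "qaly_total": r.qaly_total if r else float("nan"),
                    "cer": cer(r) if r and r.qaly_total > 0 else float("nan"),
                    "status": st.value,
                    "dominated_by": self.dominated_by.get(name) or "",
                }
            )
        return pd.DataFrame(rows)


def cer(r: CEResult) -> float:
    """Cost-effectiveness ratio, USD per QALY."""
    if not r.qaly_total > 0:
        raise ValueError("CER undefined: qaly_total must be > 0")
    return r.cost_total / r.qaly_total


def icer(a: CEResult, b: CEResult) -> IcerResult:
    """Incremental cost per QALY gained of ``a`` versus ``b``.

    Returns a dominance verdict instead of a ratio when one strategy is at
    least as cheap and at least as effective as the other (one strictly),
    including the equal-QALY, unequal-cost edge case.
    """
    dc = a.cost_total - b.cost_total
    de = a.qaly_total - b.qaly_total
    if dc == 0.0 and de == 0.0:
        raise ValueError("ICER undefined for identical results")
    if dc >= 0 and de <= 0:
        return IcerResult(Dominance.A_DOMINATED)
    if dc <= 0 and de >= 0:
        return IcerResult(Dominance.A_DOMINANT)
    return IcerResult(Dominance.RATIO, ratio=dc / de)


def nmb(r: CEResult, wtp: WTPThreshold | float) -> float:
    """Net monetary benefit at the given willingness-to-pay."""
    w = wtp.value if isinstance(wtp, WTPThreshold) else float(wtp)
    if w < 0:
        raise ValueError("WTP must be >= 0")
    return w * r.qaly_total - r.cost_total


def _strictly_dominated(
    name: str, results: dict[str, CEResult]
) -> str | None:
    """Return a strategy that dominates ``name``, if any."""
    r = results[name]
    for other, o in results.items():
        if other == name:
            continue
        if o.cost_total <= r.cost_total and o.qaly_total >= r.qaly_total:
            if o.cost_total < r.cost_total or o.qaly_total > r.qaly_total:
                return other
    return None


def frontier(results: dict[str, CEResult]) -> FrontierReport:
    """Build the cost-effectiveness frontier.

    Strategies are sorted by cost (ties: QALY descending, then input order);
    strictly dominated ones are removed first, then extendedly dominated ones
    (a strategy whose incremental ICER from its cheaper neighbour exceeds the
    ICER to its more expensive neighbour — strictly, so exact ties are
    retained).  Frontier ICERs are reported between consecutive survivors.
    """
    if not results:
        raise ValueError("at least one strategy is required")
    status: dict[str, StrategyStatus] = {}
    dominated_by: dict[str, str | None] = {n: None for n in results}

    for name in results:
        dom = _strictly_dominated(name, results)
        if dom is not None:
            status[name] = StrategyStatus.DOMINATED
            dominated_by[name] = dom

    order = {n: i for i, n in enumerate(results)}
    cand = [n for n in results if n not in status]
    cand.sort(key=lambda n: (results[n].cost_total, -results[n].qaly_total, order[n]))

    # iterative extended-dominance pruning
    while True:
        if len(cand) < 3:
            break
        icers = [
            (results[cand[i + 1]].cost_total - results[cand[i]].cost_total)
            / (results[cand[i + 1]].qaly_total - results[cand[i]].qaly_total)
            for i in range(len(cand) - 1)
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:  # strictly non-increasing step
                mid = cand[i + 1]
                status[mid] = StrategyStatus.EXTENDEDLY_DOMINATED
                dominated_by[mid] = None
                cand.pop(i + 1)
                removed = True
                break
        if not removed:
            break

    for n in cand:
        status[n] = StrategyStatus.ON_FRONTIER
    frontier_icers = [
        (results[cand[i + 1]].cost_total - results[cand[i]].cost_total)
        / (results[cand[i + 1]].qaly_total - results[cand[i]].qaly_total)
        for i in range(len(cand) - 1)
    ]
    # keep reporting order = input order
    status = {n: status[n] for n in results}
    return FrontierReport(
        status=status,
        dominated_by=dominated_by,
        frontier=cand,
        frontier_icers=frontier_icers,
        results=dict(results),
    )
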