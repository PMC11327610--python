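"""Strategy definitions and whole-model evaluation.

A :class:`DecisionModel` bundles the treatment strategies (each with its
trial summary or directly specified transition probabilities, cost line
items and utilities) with the structural :class:`ModelConfig` and the WTP
threshold.  Evaluating the model runs every strategy through the cohort
engine and returns per-strategy :class:`CEResult` objects — the single entry
point that the base case, the one-way sensitivity analysis and the
probabilistic sensitivity analysis all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .economics import WTPThreshold
from .engine import CEResult, accumulate, run_trace
from .parameters import (
    CostLineItems,
    ModelConfig,
    StateCosts,
    TransitionProbs,
    TrialSummary,
    UtilitySet,
    aggregate_state_costs,
    build_transition_matrix,
    derive_transition_probs,
)

__all__ = ["StrategyInputs", "DecisionModel", "evaluate_strategy", "evaluate_all"]


@dataclass(frozen=True)
class StrategyInputs:
    """One strategy's inputs: trial summaries, costs and utilities.

    ``probs`` directly specifies the monthly transition probabilities and
    takes precedence over derivation from the medians in ``summary`` — needed
    both for KM-calibrated strategies and for reproducing published
    probability tables verbatim.
    """

    name: str
    costs: CostLineItems
    utilities: UtilitySet = field(default_factory=UtilitySet)
    summary: TrialSummary | None = None
    probs: TransitionProbs | None = None

    def transition_probs(self, cycle_length: float = 1.0) -> TransitionProbs:
        """Resolved probabilities: the override if given, else derived."""
        if self.probs is not None:
            return self.probs
        if self.summary is None:
            raise ValueError(
                f"strategy {self.name!r}: neither probs nor trial summary given"
            )
        return derive_transition_probs(self.summary, cycle_length)


@dataclass(frozen=True)
class DecisionModel:
    """The full comparative analysis: strategies + structural settings."""

    strategies: tuple[StrategyInputs, ...]
    config: ModelConfig = field(default_factory=ModelConfig)
    wtp: WTPThreshold = field(default_factory=WTPThreshold)

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"strategy names must be unique, got {names}")
        object.__setattr__(self, "strategies", tuple(self.strategies))

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def strategy(self, name: str) -> StrategyInputs:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_strategy(self, strat: StrategyInputs) -> "DecisionModel":
        """Copy of the model with one strategy replaced (by name)."""
        return replace(
            self,
            strategies=tuple(
                strat if s.name == strat.name else s for s in self.strategies
            ),
        )


def evaluate_strategy(
    strat: StrategyInputs,
    config: ModelConfig,
    state_costs: StateCosts | None = None,
    utilities: UtilitySet | None = None,
) -> CEResult:
    """Run one strategy through the cohort engine.

    ``state_costs``/``utilities`` overrides support probabilistic reruns in
    which sampled values replace the base inputs.
    """
    tp = strat.transition_probs(config.cycle_length)
    trace = run_trace(build_transition_matrix(tp), config)
    return accumulate(
        trace,
        state_costs if state_costs is not None else aggregate_state_costs(strat.costs, config),
        utilities if utilities is not None else strat.utilities,
        config,
    )


def evaluate_all(model: DecisionModel) -> dict[str, CEResult]:
    """Deterministic base-case evaluation of every strategy."""
    return {
        s.name: evaluate_strategy(s, model.config) for s in model.strategies
    }
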