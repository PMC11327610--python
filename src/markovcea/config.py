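"""Declarative analysis configuration (YAML) and its validation.

A config file lists, per strategy: the trial medians (months) and/or
directly specified monthly transition probabilities, the per-cycle cost
line items (USD), and the state utilities; plus the structural model
settings, the WTP threshold, PSA settings and the OWSA parameter list.
A complete worked configuration for the five first-line HCC
immuno-combinations ships with the package (``hcc_firstline.yaml``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .economics import WTPThreshold
from .model import DecisionModel, StrategyInputs
from .parameters import (
    CostLineItems,
    ModelConfig,
    TransitionProbs,
    TrialSummary,
    UtilitySet,
)
from .sensitivity import ParameterRef

__all__ = ["ConfigError", "PSASettings", "AnalysisConfig", "load_config", "example_config_path"]

_DEFAULT_UTILITIES = UtilitySet(u_pfs=0.76, u_pd=0.68)


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class PSASettings:
    n_iterations: int = 10_000
    seed: int = 20_240_816
    spread: float = 0.2
    include_probs: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("psa.n_iterations must be >= 1")
        if not 0.0 <= self.spread < 1.0:
            raise ConfigError("psa.spread must be in [0, 1)")


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated analysis specification: model + analysis settings."""

    model: DecisionModel
    psa: PSASettings = field(default_factory=PSASettings)
    owsa_parameters: list[ParameterRef] | None = None  # None = defaults
    reference_strategy: str | None = None
    output_dir: Path | None = None


def example_config_path() -> Path:
    """Path of the packaged five-strategy HCC base-case configuration."""
    return Path(resources.files("markovcea").joinpath("data/hcc_firstline.yaml"))


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {where}.{key}")
    return mapping[key]


def _strategy_from_dict(d: dict) -> StrategyInputs:
    name = _require(d, "name", "strategies[]")
    where = f"strategies[{name}]"
    known = {"name", "median_pfs", "median_os", "subsequent_treatment_fraction",
             "grade34_ae_rate", "probs", "costs", "utilities"}
    for key in d:
        if key not in known:
            raise ConfigError(f"unknown key {where}.{key}")

    summary = None
    if d.get("median_pfs") is not None or d.get("median_os") is not None:
        try:
            summary = TrialSummary(
                strategy_name=name,
                median_pfs=d.get("median_pfs"),
                median_os=d.get("median_os"),
                subsequent_treatment_fraction=d.get("subsequent_treatment_fraction", 0.0),
                grade34_ae_rate=d.get("grade34_ae_rate", 0.0),
            )
        except ValueError as e:
            raise ConfigError(f"{where}: {e}") from e

    probs = None
    if "probs" in d and d["probs"] is not None:
        p = d["probs"]
        try:
            probs = TransitionProbs(
                p_pfs_pd=_require(p, "pfs_to_pd", f"{where}.probs"),
                p_pfs_death=_require(p, "pfs_to_death", f"{where}.probs"),
                p_pd_death=_require(p, "pd_to_death", f"{where}.probs"),
            )
        except ValueError as e:
            raise ConfigError(f"{where}.probs: {e}") from e

    c = _require(d, "costs", where)
    try:
        costs = CostLineItems(
            drug_a=c.get("drug_a", 0.0),
            drug_b=c.get("drug_b", 0.0),
            test=c.get("test", 0.0),
            ae=c.get("ae", 0.0),
            pd=c.get("pd", 0.0),
        )
    except ValueError as e:
        raise ConfigError(f"{where}.costs: {e}") from e

    if "utilities" in d and d["utilities"] is not None:
        u = d["utilities"]
        try:
            utilities = UtilitySet(
                u_pfs=_require(u, "pfs", f"{where}.utilities"),
                u_pd=_require(u, "pd", f"{where}.utilities"),
            )
        except ValueError as e:
            raise ConfigError(f"{where}.utilities: {e}") from e
        if utilities.u_pd > utilities.u_pfs:
            raise ConfigError(
                f"{where}.utilities: pd utility ({utilities.u_pd}) exceeds "
                f"pfs utility ({utilities.u_pfs})"
            )
    else:
        warnings.warn(
            f"{where}: utilities not given; applying defaults "
            f"(PFS {_DEFAULT_UTILITIES.u_pfs}, PD {_DEFAULT_UTILITIES.u_pd})"
        )
        utilities = _DEFAULT_UTILITIES

    return StrategyInputs(
        name=name, costs=costs, utilities=utilities, summary=summary, probs=probs
    )


def _parameter_from_dict(d: dict | str) -> ParameterRef:
    if isinstance(d, str):  # e.g. "u_pfs"
        return ParameterRef("utility", d)
    try:
        return ParameterRef(
            kind=_require(d, "kind", "owsa.parameters[]"),
            item=_require(d, "item", "owsa.parameters[]"),
            strategy=d.get("strategy"),
        )
    except ValueError as e:
        raise ConfigError(f"owsa.parameters[]: {e}") from e


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a YAML analysis configuration.

    Defaults applied when absent: 1-month cycles, 120-cycle horizon, 3%
    annual discount, WTP $35,526.90/QALY, PSA with 10,000 iterations, and
    utilities 0.76 (PFS) / 0.68 (PD).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    mc = raw.get("model", {}) or {}
    try:
        config = ModelConfig(
            cycle_length=mc.get("cycle_length_months", 1.0),
            horizon=mc.get("horizon_cycles", 120),
            annual_discount_rate=mc.get("annual_discount_rate", 0.03),
            accrual_convention=mc.get("accrual", "end-of-cycle"),
            discount_compounding=mc.get("discounting", "continuous-monthly"),
            ae_cost_mode=mc.get("ae_cost_mode", "per-cycle"),
        )
    except ValueError as e:
        raise ConfigError(f"model: {e}") from e

    strategies_raw = _require(raw, "strategies", "<top>")
    if not isinstance(strategies_raw, list) or not strategies_raw:
        raise ConfigError("strategies must be a non-empty list")
    strategies = [_strategy_from_dict(d) for d in strategies_raw]
    names = [s.name for s in strategies]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigError(f"duplicate strategy names: {sorted(dupes)}")

    try:
        wtp = WTPThreshold(raw.get("wtp", 35_526.90))
    except ValueError as e:
        raise ConfigError(f"wtp: {e}") from e

    try:
        model = DecisionModel(strategies=tuple(strategies), config=config, wtp=wtp)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    p = raw.get("psa", {}) or {}
    psa = PSASettings(
        n_iterations=p.get("n_iterations", 10_000),
        seed=p.get("seed", 20_240_816),
        spread=p.get("spread", 0.2),
        include_probs=p.get("include_probs", False),
    )

    owsa_raw = (raw.get("owsa", {}) or {}).get("parameters")
    owsa_params = [_parameter_from_dict(d) for d in owsa_raw] if owsa_raw else None

    reference = raw.get("reference_strategy")
    if reference is not None and reference not in names:
        raise ConfigError(f"reference_strategy {reference!r} is not a strategy name")

    out = raw.get("output_dir")
    return AnalysisConfig(
        model=model,
        psa=psa,
        owsa_parameters=owsa_params,
        reference_strategy=reference,
        output_dir=Path(out) if out else None,
    )
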