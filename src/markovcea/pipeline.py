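"""End-to-end analysis pipeline and report writing.

``run_pipeline`` executes base case → frontier → OWSA → PSA/CEAC and writes
machine-readable CSV/JSON reports plus a provenance log (config hash, seed,
conventions, package version) sufficient to reproduce every output
byte-identically.  ``convention_sweep`` reruns the deterministic base case
under all nine accrual × discounting combinations — the tool for judging how
sensitive totals are to unstated bookkeeping conventions when reproducing a
published model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, economics, sensitivity
from .config import AnalysisConfig
from .engine import CEResult
from .model import DecisionModel, evaluate_all
from .parameters import Accrual, Discounting

__all__ = ["PipelineResult", "run_pipeline", "convention_sweep", "results_table"]

_ROUND = {"cost": 2, "qaly": 2, "prob": 4}


@dataclass(frozen=True)
class PipelineResult:
    results: dict[str, CEResult]
    frontier: economics.FrontierReport
    owsa: list[sensitivity.OWSAResult] | None
    psa: sensitivity.PSAResult | None
    ceac: sensitivity.CEACCurve | None
    provenance: dict


def results_table(results: dict[str, CEResult], round_money: bool = True) -> pd.DataFrame:
    """Base-case results, one strategy per column (published-table layout)."""
    rows = {
        "cost_pfs": {n: r.cost_pfs for n, r in results.items()},
        "cost_pd": {n: r.cost_pd for n, r in results.items()},
        "cost_total": {n: r.cost_total for n, r in results.items()},
        "qaly_pfs": {n: r.qaly_pfs for n, r in results.items()},
        "qaly_pd": {n: r.qaly_pd for n, r in results.items()},
        "qaly_total": {n: r.qaly_total for n, r in results.items()},
        "cer": {n: economics.cer(r) for n, r in results.items()},
    }
    df = pd.DataFrame(rows).T
    return df.round(2) if round_money else df


def convention_sweep(model: DecisionModel) -> pd.DataFrame:
    """Deterministic totals under all 9 accrual × discounting combinations."""
    rows = []
    for acc in Accrual:
        for disc in Discounting:
            cfg = replace(
                model.config, accrual_convention=acc, discount_compounding=disc
            )
            res = evaluate_all(replace(model, config=cfg))
            for name, r in res.items():
                rows.append(
                    {
                        "accrual": acc.value,
                        "discounting": disc.value,
                        "strategy": name,
                        "cost_total": r.cost_total,
                        "qaly_total": r.qaly_total,
                    }
                )
    return pd.DataFrame(rows)


def _config_hash(cfg: AnalysisConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(x) for x in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    payload = json.dumps(encode(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    cfg: AnalysisConfig,
    output_dir: str | Path | None = None,
    seed: int | None = None,
    run_psa: bool = True,
    run_owsa: bool = True,
) -> PipelineResult:
    """Run the full analysis and (optionally) write the report bundle.

    ``seed`` overrides the config's PSA seed.  Output files (written when a
    directory is given): ``results.csv``, ``frontier.csv``, ``tornado.csv``,
    ``ceac.csv``, ``psa_scatter.csv``, ``trace_<strategy>.csv``,
    ``convention_sweep.csv`` and ``run_log.json``.
    """
    model = cfg.model
    results = evaluate_all(model)
    front = economics.frontier(results)

    reference = cfg.reference_strategy or min(
        results, key=lambda n: results[n].cost_total
    )

    owsa_res = None
    if run_owsa:
        owsa_res = {}
        for name in model.strategy_names:
            if name == reference:
                continue
            owsa_res[name] = sensitivity.owsa(
                model,
                strategy=name,
                reference=None,  # strategy CER outcome; ICER vs reference is affine in it
                parameters=cfg.owsa_parameters,
            )

    psa_res = ceac_res = None
    psa_seed = seed if seed is not None else cfg.psa.seed
    if run_psa:
        psa_res = sensitivity.run_psa(
            model,
            n_iterations=cfg.psa.n_iterations,
            seed=psa_seed,
            spread=cfg.psa.spread,
            include_probs=cfg.psa.include_probs,
        )
        ceac_res = sensitivity.ceac(psa_res)

    provenance = {
        "package": "markovcea",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "psa_seed": psa_seed if run_psa else None,
        "accrual": model.config.accrual_convention.value,
        "discounting": model.config.discount_compounding.value,
        "ae_cost_mode": model.config.ae_cost_mode.value,
        "horizon_cycles": model.config.horizon,
        "annual_discount_rate": model.config.annual_discount_rate,
        "wtp": model.wtp.value,
        "reference_strategy": reference,
    }

    out = PipelineResult(
        results=results,
        frontier=front,
        owsa=owsa_res,
        psa=psa_res,
        ceac=ceac_res,
        provenance=provenance,
    )

    outdir = Path(output_dir) if output_dir else cfg.output_dir
    if outdir is not None:
        _write_reports(out, cfg, Path(outdir))
    return out


def _write_reports(res: PipelineResult, cfg: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results_table(res.results, round_money=False).to_csv(outdir / "results.csv")
    res.frontier.to_frame().to_csv(outdir / "frontier.csv", index=False)
    convention_sweep(cfg.model).to_csv(outdir / "convention_sweep.csv", index=False)
    if res.owsa is not None:
        frames = []
        for strat, rows in res.owsa.items():
            df = sensitivity.owsa_frame(rows)
            df.insert(0, "strategy", strat)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(outdir / "tornado.csv", index=False)
    if res.psa is not None:
        res.ceac.to_frame().to_csv(outdir / "ceac.csv", index=False)
        ref = res.provenance["reference_strategy"]
        res.psa.scatter(ref).to_csv(outdir / "psa_scatter.csv", index=False)
    (outdir / "run_log.json").write_text(json.dumps(res.provenance, indent=2) + "\n")
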