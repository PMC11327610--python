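"""Synthetic trial cohorts with known ground-truth transition probabilities.

The cohort model assumes constant monthly hazards per state, i.e.
exponential sojourn times.  This module simulates exactly that process in
continuous time — competing exponential risks of progression and death while
progression-free, then an exponential post-progression survival — plus a
censoring mechanism (uniform accrual with an administrative cut-off, and
independent exponential dropout).  Because the ground truth is known, the
whole pipeline is testable end to end: Kaplan-Meier curves estimated from a
simulated cohort should calibrate back to the generating probabilities, and
KM medians should round-trip through the median-to-probability conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .calibration import KMCurve
from .parameters import TransitionProbs, TrialSummary, prob_to_rate

__all__ = ["SyntheticTrial", "simulate_patients", "km_from_patients", "make_summary"]


@dataclass(frozen=True)
class SyntheticTrial:
    """Per-patient event times (months) with their generating truth."""

    true_probs: TransitionProbs
    n_patients: int
    censoring_rate: float
    seed: int | None
    data: pd.DataFrame  # columns: id, pfs_time, pfs_event, os_time, os_event

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def simulate_patients(
    true_probs: TransitionProbs,
    n: int,
    censoring_rate: float = 0.0,
    seed: int | None = None,
    accrual_months: float = 0.0,
    max_followup: float | None = None,
) -> SyntheticTrial:
    """Simulate a single-arm cohort under the model's exponential assumptions.

    Progression and pre-progression death compete as independent
    exponentials with rates ``-ln(1-p)`` per month; post-progression
    survival is exponential with the PD→death rate.  Censoring combines
    exponential dropout at ``censoring_rate``/month with an administrative
    cut-off ``max_followup`` months after study start, under uniform accrual
    over ``accrual_months`` (so late enrollees have shorter follow-up, which
    is how real trials produce "median not reached").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censoring_rate < 0:
        raise ValueError("censoring_rate must be >= 0")
    r_pd = prob_to_rate(true_probs.p_pfs_pd)
    r_d1 = prob_to_rate(true_probs.p_pfs_death)
    r_d2 = prob_to_rate(true_probs.p_pd_death)
    if r_pd + r_d1 == 0 and censoring_rate == 0 and max_followup is None:
        raise ValueError(
            "all-zero probabilities with no censoring give non-terminating follow-up"
        )
    rng = np.random.default_rng(seed)

    t_prog = _exp_draw(rng, r_pd, n)
    t_death_pfs = _exp_draw(rng, r_d1, n)
    t_post = _exp_draw(rng, r_d2, n)

    pfs_exit = np.minimum(t_prog, t_death_pfs)
    progressed = t_prog < t_death_pfs
    os_true = np.where(progressed, pfs_exit + t_post, pfs_exit)

    # one censoring time per patient: dropout vs administrative cut-off
    drop = _exp_draw(rng, censoring_rate, n)
    if max_followup is not None:
        entry = rng.uniform(0.0, accrual_months, n) if accrual_months > 0 else np.zeros(n)
        admin = np.maximum(max_followup - entry, 0.0)
        cens = np.minimum(drop, admin)
    else:
        cens = drop

    pfs_time = np.minimum(pfs_exit, cens)
    pfs_event = pfs_exit <= cens
    os_time = np.minimum(os_true, cens)
    os_event = os_true <= cens

    data = pd.DataFrame(
        {
            "id": np.arange(n),
            "pfs_time": pfs_time,
            "pfs_event": pfs_event.astype(int),
            "os_time": os_time,
            "os_event": os_event.astype(int),
        }
    )
    return SyntheticTrial(
        true_probs=true_probs,
        n_patients=n,
        censoring_rate=censoring_rate,
        seed=seed,
        data=data,
    )


def _exp_draw(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    return rng.exponential(1.0 / rate, n) if rate > 0 else np.full(n, np.inf)


def km_from_patients(trial: SyntheticTrial, endpoint: str) -> KMCurve:
    """Product-limit survival curve for one endpoint of a simulated cohort.

    Estimation is delegated to lifelines; the fitted step function is
    returned as points at t=0 and each distinct event time.
    """
    if endpoint not in ("PFS", "OS"):
        raise ValueError("endpoint must be 'PFS' or 'OS'")
    col = endpoint.lower()
    times = trial.data[f"{col}_time"].to_numpy()
    events = trial.data[f"{col}_event"].to_numpy().astype(bool)
    if not events.any():
        raise ValueError(f"no observed {endpoint} events; curve unidentifiable")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    # keep t=0 and the event-time steps only
    event_times = np.unique(times[events])
    keep = np.isin(t, event_times) | (t == 0.0)
    return KMCurve(times=t[keep], survival=s[keep], endpoint=endpoint)


def make_summary(trial: SyntheticTrial, name: str = "synthetic") -> TrialSummary:
    """Package KM medians as a trial summary.

    A median that the KM curve never reaches (survival still above 0.5 at
    last follow-up) is left absent, which routes the strategy to KM
    calibration — the same situation as a trial whose median OS was not
    reached.
    """
    medians = {}
    for endpoint in ("PFS", "OS"):
        col = endpoint.lower()
        kmf = KaplanMeierFitter()
        kmf.fit(
            trial.data[f"{col}_time"].to_numpy(),
            trial.data[f"{col}_event"].to_numpy().astype(bool),
        )
        m = float(kmf.median_survival_time_)
        medians[endpoint] = None if not np.isfinite(m) else m
    if (
        medians["PFS"] is not None
        and medians["OS"] is not None
        and medians["OS"] <= medians["PFS"]
    ):
        # degenerate small-sample case: keep OS absent rather than invalid
        medians["OS"] = None
    return TrialSummary(
        strategy_name=name,
        median_pfs=medians["PFS"],
        median_os=medians["OS"],
    )
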