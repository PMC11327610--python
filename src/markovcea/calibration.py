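"""Estimate transition probabilities from Kaplan-Meier curves.

When a trial has not reached its median OS (as happens with effective
therapies and short follow-up), the closed-form median-to-probability
conversion is unavailable.  The fallback is calibration: choose the three
monthly transition probabilities whose model-implied PFS and OS curves best
fit digitized KM points, by least squares.  The objective surface is cheap,
three-dimensional and can be multimodal, so the optimizer is a coarse grid
search followed by bounded local refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .parameters import ModelConfig, TransitionProbs

__all__ = ["KMCurve", "CalibrationResult", "calibrate_to_km", "model_median"]

_BOUNDS = (1e-5, 0.999)


@dataclass(frozen=True)
class KMCurve:
    """Digitized Kaplan-Meier points for one endpoint.

    ``times`` (months) must be strictly increasing and ``survival``
    proportions non-increasing; if t=0 is present its survival must be 1.
    """

    times: np.ndarray
    survival: np.ndarray
    endpoint: str  # "PFS" or "OS"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError("endpoint must be 'PFS' or 'OS'")
        if t.ndim != 1 or t.shape != s.shape or t.size == 0:
            raise ValueError("times and survival must be equal-length 1-d arrays")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival must be proportions in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if t[0] == 0 and abs(s[0] - 1.0) > 1e-12:
            raise ValueError("survival at t=0 must be 1")

    @classmethod
    def from_csv(cls, path, endpoint: str) -> "KMCurve":
        """Read a 2-column (time_months, survival) CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected 2 columns (time_months, survival)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), endpoint)


@dataclass(frozen=True)
class CalibrationResult:
    """Best-fit probabilities with goodness-of-fit diagnostics."""

    probs: TransitionProbs
    sse: float
    residuals_pfs: np.ndarray
    residuals_os: np.ndarray
    grid_sse: float  # best objective value on the coarse grid (pre-refinement)


def _survival_batch(
    p: np.ndarray, horizon: int
) -> tuple[np.ndarray, np.ndarray]:
    """Model PFS and OS curves for a batch of probability triples.

    ``p`` has shape (n, 3); returns two (n, horizon+1) arrays.  Vectorized
    closed-form recursion (the PD occupancy recurrence), so grid search over
    thousands of candidates stays cheap.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    stay_pfs = 1.0 - p[:, 0] - p[:, 1]
    stay_pd = 1.0 - p[:, 2]
    n = p.shape[0]
    pfs = np.empty((n, horizon + 1))
    pd_share = np.empty((n, horizon + 1))
    pfs[:, 0] = 1.0
    pd_share[:, 0] = 0.0
    for t in range(horizon):
        pd_share[:, t + 1] = pd_share[:, t] * stay_pd + pfs[:, t] * p[:, 0]
        pfs[:, t + 1] = pfs[:, t] * stay_pfs
    return pfs, pfs + pd_share


def _interp_model(curve: np.ndarray, times: np.ndarray, cycle_length: float) -> np.ndarray:
    """Model curve linearly interpolated at KM point times (months)."""
    cycles = np.arange(curve.shape[-1]) * cycle_length
    return np.interp(times, cycles, curve)


def calibrate_to_km(
    pfs_km: KMCurve,
    os_km: KMCurve,
    config: ModelConfig | None = None,
    grid_points: int = 12,
) -> CalibrationResult:
    """Least-squares fit of the three transition probabilities to KM data.

    The objective is the equally weighted sum of squared differences between
    the model PFS/OS curves (interpolated linearly between cycles) and the KM
    survival values at the KM point times.  A ``grid_points``-per-dimension
    log-spaced grid over the probability bounds locates the basin; L-BFGS-B
    refines within it.

    Raises
    ------
    ValueError
        If either curve is missing, has fewer than 3 points, or is degenerate
        (no observed mortality/progression, which leaves the probabilities
        unidentifiable).
    """
    if pfs_km is None or os_km is None:
        raise ValueError("both PFS and OS curves are required for calibration")
    if pfs_km.endpoint != "PFS" or os_km.endpoint != "OS":
        raise ValueError("curves must be passed as (PFS, OS) in that order")
    for c in (pfs_km, os_km):
        if c.times.size < 3:
            raise ValueError(f"{c.endpoint} curve needs >= 3 points")
        if np.all(c.survival >= 1.0 - 1e-12):
            raise ValueError(
                f"{c.endpoint} curve shows no events; probabilities unidentifiable"
            )
    config = config or ModelConfig()
    horizon = max(
        config.horizon,
        int(np.ceil(max(pfs_km.times.max(), os_km.times.max()) / config.cycle_length)),
    )

    def objective_batch(p: np.ndarray) -> np.ndarray:
        pfs_curves, os_curves = _survival_batch(p, horizon)
        sse = np.empty(pfs_curves.shape[0])
        for i in range(pfs_curves.shape[0]):
            rp = _interp_model(pfs_curves[i], pfs_km.times, config.cycle_length) - pfs_km.survival
            ro = _interp_model(os_curves[i], os_km.times, config.cycle_length) - os_km.survival
            sse[i] = rp @ rp + ro @ ro
        return sse

    axis = np.geomspace(0.002, 0.6, grid_points)
    g1, g2, g3 = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([g1.ravel(), g2.ravel(), g3.ravel()])
    grid = grid[grid[:, 0] + grid[:, 1] <= 0.999]
    grid_sse = objective_batch(grid)
    best = grid[int(np.argmin(grid_sse))]
    best_grid_sse = float(grid_sse.min())

    def objective_one(x: np.ndarray) -> float:
        if x[0] + x[1] > 0.999:  # keep the PFS row stochastic
            return 1e6 + (x[0] + x[1])
        return float(objective_batch(x[None, :])[0])

    res = optimize.minimize(
        objective_one,
        best,
        method="L-BFGS-B",
        bounds=[_BOUNDS] * 3,
        options={"maxiter": 500},
    )
    x = res.x if res.fun <= best_grid_sse else best
    if res.fun > best_grid_sse:  # pragma: no cover - defensive
        warnings.warn("local refinement failed to improve on the grid optimum")
    probs = TransitionProbs(*np.clip(x, _BOUNDS[0], _BOUNDS[1]))

    pfs_curve, os_curve = _survival_batch(np.array([probs.as_tuple()]), horizon)
    rp = _interp_model(pfs_curve[0], pfs_km.times, config.cycle_length) - pfs_km.survival
    ro = _interp_model(os_curve[0], os_km.times, config.cycle_length) - os_km.survival
    return CalibrationResult(
        probs=probs,
        sse=float(rp @ rp + ro @ ro),
        residuals_pfs=rp,
        residuals_os=ro,
        grid_sse=best_grid_sse,
    )


def model_median(
    tp: TransitionProbs,
    endpoint: str,
    config: ModelConfig | None = None,
) -> float:
    """First time (months) the model survival curve crosses 0.5.

    Linearly interpolated between cycles; ``inf`` if the curve never reaches
    0.5 within the horizon.  A calibration diagnostic: compare against the
    trial's reported medians.
    """
    config = config or ModelConfig()
    pfs, osc = _survival_batch(np.array([tp.as_tuple()]), config.horizon)
    curve = {"PFS": pfs[0], "OS": osc[0]}[endpoint]
    below = np.nonzero(curve <= 0.5)[0]
    if below.size == 0:
        return float("inf")
    i = int(below[0])
    if i == 0:  # pragma: no cover - survival starts at 1
        return 0.0
    s0, s1 = curve[i - 1], curve[i]
    frac = (s0 - 0.5) / (s0 - s1)
    return (i - 1 + frac) * config.cycle_length
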