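"""Replication engine: generate -> fit -> test, many times.

Estimates statistical power, type-I error, sampling distributions of the
exposure hazard ratio, and survival-curve sampling variability. Each
replicate runs on an independent substream spawned from a master seed
(:class:`numpy.random.SeedSequence`), so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytic_oracle import true_survival
from .dgm import Scenario, generate_cohort
from .weibull_inference import (
    NoEventsError,
    fit_weibull_ph,
    predict_survival,
    wald_hr_test,
)

__all__ = [
    "ReplicationResult",
    "CalibrationResult",
    "CurveEnsemble",
    "run_replications",
    "summarize_sampling_distribution",
    "calibrate_sample_size",
    "survival_curve_ensemble",
]

_MODES = ("null", "alternative")
DEFAULT_POWER_REPS = 10_000
DEFAULT_CURVE_REPS = 900


@dataclass(frozen=True)
class ReplicationResult:
    """Per-replicate estimates and the aggregate rejection proportion.

    Arrays have length ``n_requested`` and are aligned by replicate;
    non-converged replicates hold NaN estimates and are excluded from the
    power denominator (``power = rejections among converged / n_converged``).
    """

    n_requested: int
    n_converged: int
    estimates: np.ndarray  # beta1_hat per replicate (NaN if not converged)
    ses: np.ndarray
    pvalues: np.ndarray
    rejections: np.ndarray  # boolean; False where not converged
    converged: np.ndarray  # boolean mask
    n_events: np.ndarray
    power: float
    mc_se: float
    mean_events: float
    seed: int
    mode: str
    alpha: float

    @property
    def n_excluded(self) -> int:
        return self.n_requested - self.n_converged

    def to_frame(self) -> pd.DataFrame:
        """One row per replicate (replication CSV)."""
        with np.errstate(invalid="ignore"):
            zs = self.estimates / self.ses
        return pd.DataFrame(
            {
                "rep": np.arange(1, self.n_requested + 1),
                "beta1_hat": self.estimates,
                "se": self.ses,
                "z": zs,
                "p": self.pvalues,
                "reject": self.rejections.astype(int),
                "converged": self.converged.astype(int),
                "n_events": self.n_events,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "alpha": self.alpha,
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "n_excluded": self.n_excluded,
            "power": self.power,
            "mc_se": self.mc_se,
            "mean_events": self.mean_events,
        }


def run_replications(
    scenario: Scenario,
    n_reps: int,
    mode: str = "alternative",
    master_seed: int = 0,
) -> ReplicationResult:
    """Replicate generate -> fit -> Wald test ``n_reps`` times.

    In ``null`` mode the exposure effect is forced to zero in the
    *generating* model only; the analysis model and test level are
    unchanged, so the rejection proportion estimates the type-I error.
    In ``alternative`` mode it estimates power at the scenario's effect.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    gen_scenario = scenario.with_null_exposure() if mode == "null" else scenario

    estimates = np.full(n_reps, np.nan)
    ses = np.full(n_reps, np.nan)
    pvalues = np.full(n_reps, np.nan)
    rejections = np.zeros(n_reps, dtype=bool)
    converged = np.zeros(n_reps, dtype=bool)
    n_events = np.zeros(n_reps, dtype=int)

    for i, child in enumerate(np.random.SeedSequence(master_seed).spawn(n_reps)):
        cohort = generate_cohort(gen_scenario, np.random.default_rng(child))
        n_events[i] = cohort.n_events
        try:
            fit = fit_weibull_ph(cohort)
        except NoEventsError:
            continue  # counted as excluded (non-converged)
        converged[i] = fit.converged
        if not fit.converged:
            continue
        w = wald_hr_test(fit, coefficient=1)
        estimates[i] = w.estimate
        ses[i] = w.se
        pvalues[i] = w.p_two_sided
        rejections[i] = w.p_two_sided < scenario.alpha

    n_conv = int(converged.sum())
    power = float(rejections[converged].sum() / n_conv) if n_conv else float("nan")
    mc_se = float(np.sqrt(power * (1.0 - power) / n_conv)) if n_conv else float("nan")
    return ReplicationResult(
        n_requested=n_reps,
        n_converged=n_conv,
        estimates=estimates,
        ses=ses,
        pvalues=pvalues,
        rejections=rejections,
        converged=converged,
        n_events=n_events,
        power=power,
        mc_se=mc_se,
        mean_events=float(n_events.mean()),
        seed=int(master_seed),
        mode=mode,
        alpha=scenario.alpha,
    )


def summarize_sampling_distribution(
    result: ReplicationResult,
    percentiles: Sequence[float] = (1, 2.5, 5, 25, 50, 75, 95, 97.5, 99),
    bins: int = 40,
) -> dict:
    """Summaries of the HR sampling distribution across replicates."""
    est = result.estimates[result.converged]
    if len(est) < 2:
        raise ValueError("need at least 2 converged replicates to summarize")
    hrs = np.exp(est)
    counts, edges = np.histogram(hrs, bins=bins)
    return {
        "n": int(len(est)),
        "geometric_mean_hr": float(np.exp(est.mean())),
        "sd_log_hr": float(est.std(ddof=1)),
        "percentiles_hr": {
            float(q): float(v) for q, v in zip(percentiles, np.percentile(hrs, percentiles))
        },
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }


@dataclass(frozen=True)
class CalibrationResult:
    """Power estimates on a grid of sample sizes."""

    table: pd.DataFrame  # columns: n, power, mc_se, n_converged
    target_power: float
    selected_n: Optional[int]  # smallest candidate meeting the target, or None

    @property
    def sufficient(self) -> bool:
        return self.selected_n is not None


def calibrate_sample_size(
    scenario: Scenario,
    target_power: float,
    candidate_ns: Sequence[int],
    n_reps: int = 1000,
    master_seed: int = 0,
) -> CalibrationResult:
    """Estimate power at each candidate n; select the smallest sufficient one."""
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must be in (0, 1), got {target_power}")
    candidate_ns = [int(n) for n in candidate_ns]
    if not candidate_ns:
        raise ValueError("candidate_ns must be nonempty")
    if any(b <= a for a, b in zip(candidate_ns, candidate_ns[1:])):
        raise ValueError("candidate_ns must be strictly increasing")

    seeds = np.random.SeedSequence(master_seed).generate_state(len(candidate_ns))
    rows = []
    selected = None
    for n, seed in zip(candidate_ns, seeds):
        res = run_replications(scenario.with_n(n), n_reps, "alternative", int(seed))
        rows.append(
            {"n": n, "power": res.power, "mc_se": res.mc_se, "n_converged": res.n_converged}
        )
        if selected is None and res.power >= target_power:
            selected = n
    return CalibrationResult(
        table=pd.DataFrame(rows), target_power=target_power, selected_n=selected
    )


@dataclass(frozen=True)
class CurveEnsemble:
    """Fitted survival curves across replicates plus the true curve."""

    time_grid: np.ndarray
    curves: np.ndarray  # (n_converged, len(time_grid))
    true_curve: np.ndarray
    envelope_low: np.ndarray  # pointwise min across replicates
    envelope_high: np.ndarray
    median_curve: np.ndarray
    pattern: Tuple[int, int]  # (x, z)
    n_requested: int
    n_converged: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time_grid,
                "true": self.true_curve,
                "median": self.median_curve,
                "low": self.envelope_low,
                "high": self.envelope_high,
            }
        )
        return df


def survival_curve_ensemble(
    scenario: Scenario,
    n_reps: int,
    pattern: Tuple[int, int],
    time_grid: Sequence[float],
    master_seed: int = 0,
) -> CurveEnsemble:
    """Sampling variability of the estimated survival curve at one pattern.

    Each replicate's curve comes from its own fitted model; the true curve
    is computed analytically from the generating model and does not depend
    on ``n_reps`` or the seed.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("time_grid must be nonempty")
    x, z = pattern

    curves = []
    for child in np.random.SeedSequence(master_seed).spawn(n_reps):
        cohort = generate_cohort(scenario, np.random.default_rng(child))
        try:
            fit = fit_weibull_ph(cohort)
        except NoEventsError:
            continue
        if fit.converged:
            curves.append(predict_survival(fit, time_grid, x=x, z=z))
    curves = np.asarray(curves)
    true_curve = np.asarray(
        [true_survival(scenario.outcome, t, x=x, z=z) for t in time_grid]
    )
    return CurveEnsemble(
        time_grid=time_grid,
        curves=curves,
        true_curve=true_curve,
        envelope_low=curves.min(axis=0),
        envelope_high=curves.max(axis=0),
        median_curve=np.median(curves, axis=0),
        pattern=(x, z),
        n_requested=n_reps,
        n_converged=len(curves),
    )
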