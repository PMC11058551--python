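"""Data-generating mechanism for a confounded time-to-event cohort.

The causal ordering is confounder -> exposure -> outcome:

* a binary confounder ``z`` (age group) drawn Bernoulli(prevalence);
* a binary exposure ``x`` (physical activity) drawn Bernoulli with
  logit(P(x=1|z)) = logit(baseline_prob) + log_odds_ratio * z;
* a latent event time drawn from a Weibull proportional-hazards model
  with hazard h(t | x, z) = gamma * t**(gamma-1) * exp(b0 + b1*x + b2*z),
  administratively censored at ``tau``.

All sampling takes an explicit :class:`numpy.random.Generator` (or a seed)
so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ConfounderModel",
    "ExposureModel",
    "WeibullOutcomeModel",
    "FollowUpDesign",
    "Scenario",
    "Cohort",
    "sample_confounder",
    "sample_exposure",
    "invert_survival",
    "generate_cohort",
]

RngLike = Union[np.random.Generator, np.random.SeedSequence, int, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ConfounderModel:
    """Marginal Bernoulli model for the binary confounder ``z``."""

    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(
                f"prevalence must be in [0, 1], got {self.prevalence}"
            )


@dataclass(frozen=True)
class ExposureModel:
    """Logistic model for the binary exposure ``x`` given the confounder.

    P(x=1 | z) = expit(logit(baseline_prob) + log_odds_ratio * z).
    """

    baseline_prob: float
    log_odds_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError(
                f"baseline_prob must be in (0, 1), got {self.baseline_prob}"
            )
        if not math.isfinite(self.log_odds_ratio):
            raise ValueError("log_odds_ratio must be finite")

    def prob_given(self, z: np.ndarray) -> np.ndarray:
        """P(x=1 | z) for a vector of confounder indicators."""
        logit0 = math.log(self.baseline_prob / (1.0 - self.baseline_prob))
        eta = logit0 + self.log_odds_ratio * np.asarray(z, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class WeibullOutcomeModel:
    """Weibull proportional-hazards outcome model.

    Hazard convention: h(t | x, z) = gamma * t**(gamma-1) * exp(lp) with
    linear predictor lp = beta0 + beta1*x + beta2*z; exp(beta0) is the
    baseline event rate per time unit when gamma == 1.
    """

    beta0: float
    beta1: float
    beta2: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        for name in ("beta0", "beta1", "beta2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def linear_predictor(self, x, z) -> np.ndarray:
        return (
            self.beta0
            + self.beta1 * np.asarray(x, dtype=float)
            + self.beta2 * np.asarray(z, dtype=float)
        )


@dataclass(frozen=True)
class FollowUpDesign:
    """Administrative censoring at a fixed follow-up time ``tau`` (years)."""

    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class Scenario:
    """Complete description of one simulated study design."""

    confounder: ConfounderModel
    exposure: ExposureModel
    outcome: WeibullOutcomeModel
    followup: FollowUpDesign
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"cohort size n must be >= 2, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def with_null_exposure(self) -> "Scenario":
        """Copy of the scenario with the exposure effect switched off."""
        return replace(self, outcome=replace(self.outcome, beta1=0.0))

    def with_n(self, n: int) -> "Scenario":
        return replace(self, n=int(n))


_COHORT_COLUMNS = ("id", "z", "x", "time", "event")


@dataclass(frozen=True)
class Cohort:
    """One simulated analytic sample.

    ``time`` is the observed follow-up in years; ``event`` is 1 for an
    observed death and 0 for administrative censoring.
    """

    subject_id: np.ndarray
    z: np.ndarray
    x: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "subject_id": np.asarray(self.subject_id),
            "z": np.asarray(self.z),
            "x": np.asarray(self.x),
            "time": np.asarray(self.time, dtype=float),
            "event": np.asarray(self.event),
        }
        n = len(arrays["subject_id"])
        for name, arr in arrays.items():
            if arr.ndim != 1 or len(arr) != n:
                raise ValueError(f"{name} must be a length-{n} 1-d vector")
            object.__setattr__(self, name if name != "subject_id" else "subject_id", arr)
        for name in ("z", "x", "event"):
            if not np.isin(arrays[name], (0, 1)).all():
                raise ValueError(f"{name} must be binary (0/1)")
        if not (arrays["time"] > 0).all():
            raise ValueError("all observed times must be positive")

    def __len__(self) -> int:
        return len(self.subject_id)

    @property
    def n_events(self) -> int:
        return int(np.sum(self.event))

    @property
    def person_time(self) -> float:
        return float(np.sum(self.time))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.asarray(self.subject_id, dtype=int),
                "z": np.asarray(self.z, dtype=int),
                "x": np.asarray(self.x, dtype=int),
                "time": np.asarray(self.time, dtype=float),
                "event": np.asarray(self.event, dtype=int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        missing = set(_COHORT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        return cls(
            subject_id=frame["id"].to_numpy(dtype=int),
            z=frame["z"].to_numpy(dtype=int),
            x=frame["x"].to_numpy(dtype=int),
            time=frame["time"].to_numpy(dtype=float),
            event=frame["event"].to_numpy(dtype=int),
        )

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(Path(path)))


def sample_confounder(model: ConfounderModel, n: int, rng: RngLike) -> np.ndarray:
    """Draw ``n`` independent confounder indicators."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(rng)
    return (rng.random(n) < model.prevalence).astype(np.int8)


def sample_exposure(model: ExposureModel, z: np.ndarray, rng: RngLike) -> np.ndarray:
    """Draw exposure indicators given confounder indicators ``z``."""
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("z must be a binary (0/1) vector")
    rng = _as_rng(rng)
    return (rng.random(len(z)) < model.prob_given(z)).astype(np.int8)


def invert_survival(u, linear_predictor, gamma: float):
    """Invert the Weibull survival function S(t) = exp(-exp(lp) * t**gamma).

    Given a survival probability ``u`` in (0, 1), returns the unique time
    ``t`` with S(t) = u, i.e. t = (-ln(u) / exp(lp))**(1/gamma). Accepts
    scalars or arrays (broadcast); strictly decreasing in ``u``.
    """
    u = np.asarray(u, dtype=float)
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("survival probability u must lie strictly in (0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)
    t = (-np.log(u) / np.exp(lp)) ** (1.0 / gamma)
    return t if t.ndim else float(t)


def generate_cohort(scenario: Scenario, rng: RngLike) -> Cohort:
    """Generate one cohort from the scenario's data-generating mechanism.

    Draws z, then x given z, then one uniform per subject treated as the
    survival probability S (U and 1-U are equidistributed), inverts it to
    a latent event time, and applies administrative censoring at tau.
    """
    rng = _as_rng(rng)
    n = scenario.n
    z = sample_confounder(scenario.confounder, n, rng)
    x = sample_exposure(scenario.exposure, z, rng)
    u = rng.random(n)
    # rng.random() can return exactly 0.0 (S=0 <=> t=inf); nudge into (0,1)
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    lp = scenario.outcome.linear_predictor(x, z)
    latent = invert_survival(u, lp, scenario.outcome.gamma)
    tau = scenario.followup.tau
    event = (latent <= tau).astype(np.int8)
    time = np.minimum(latent, tau)
    return Cohort(
        subject_id=np.arange(1, n + 1),
        z=z,
        x=x,
        time=time,
        event=event,
    )
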