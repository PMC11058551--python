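"""Closed-form quantities implied by a scenario.

Because both covariates are binary and censoring is purely administrative,
every population quantity reduces to a 4-row covariate-pattern table: no
numeric integration is needed anywhere. These exact values serve as
calibration targets and independent test oracles for the simulator and
the fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .dgm import Cohort, Scenario, WeibullOutcomeModel

__all__ = [
    "PatternProbability",
    "pattern_table",
    "expected_events",
    "true_survival",
    "exponential_mle_oracle",
]

PATTERNS = ((0, 0), (0, 1), (1, 0), (1, 1))  # (z, x) order


@dataclass(frozen=True)
class PatternProbability:
    """Joint probability and event probability for one (z, x) pattern."""

    z: int
    x: int
    joint_prob: float
    event_prob: float
    linear_predictor: float


def true_survival(model: WeibullOutcomeModel, t, x: int, z: int):
    """Exact S(t | x, z) = exp(-exp(lp) * t**gamma) under the model."""
    t = np.asarray(t, dtype=float)
    lp = float(model.linear_predictor(x, z))
    out = np.exp(-math.exp(lp) * t**model.gamma)
    return out if out.ndim else float(out)


def pattern_table(scenario: Scenario) -> List[PatternProbability]:
    """The 4 covariate patterns with joint and event-by-tau probabilities."""
    pz1 = scenario.confounder.prevalence
    tau = scenario.followup.tau
    rows = []
    for z, x in PATTERNS:
        pz = pz1 if z == 1 else 1.0 - pz1
        px1 = float(scenario.exposure.prob_given(np.array([z]))[0])
        px = px1 if x == 1 else 1.0 - px1
        lp = float(scenario.outcome.linear_predictor(x, z))
        event_prob = 1.0 - float(true_survival(scenario.outcome, tau, x, z))
        rows.append(
            PatternProbability(
                z=z, x=x, joint_prob=pz * px, event_prob=event_prob, linear_predictor=lp
            )
        )
    return rows


def pattern_frame(scenario: Scenario) -> pd.DataFrame:
    """Pattern table as a data frame (CSV-ready: z,x,joint_prob,event_prob)."""
    rows = pattern_table(scenario)
    return pd.DataFrame(
        {
            "z": [r.z for r in rows],
            "x": [r.x for r in rows],
            "joint_prob": [r.joint_prob for r in rows],
            "event_prob": [r.event_prob for r in rows],
        }
    )


def expected_events(scenario: Scenario) -> float:
    """Exact expected number of deaths by tau in a cohort of size n."""
    return scenario.n * sum(r.joint_prob * r.event_prob for r in pattern_table(scenario))


def exponential_mle_oracle(cohort: Cohort) -> pd.DataFrame:
    """Saturated constant-rate MLEs per covariate pattern.

    Rate = events / person-time in each (z, x) cell — the closed-form MLE
    of the saturated exponential model — plus rate ratios against the
    (z=0, x=0) cell. A cell with zero events yields rate 0 flagged as a
    boundary estimate; a cell with zero person-time is an error.
    """
    z = np.asarray(cohort.z)
    x = np.asarray(cohort.x)
    t = np.asarray(cohort.time, dtype=float)
    d = np.asarray(cohort.event)
    rows = []
    for zi, xi in PATTERNS:
        mask = (z == zi) & (x == xi)
        pt = float(t[mask].sum())
        ev = int(d[mask].sum())
        if pt <= 0:
            raise ValueError(f"pattern (z={zi}, x={xi}) has zero person-time")
        rows.append(
            {
                "z": zi,
                "x": xi,
                "events": ev,
                "person_time": pt,
                "rate": ev / pt,
                "boundary": ev == 0,
            }
        )
    table = pd.DataFrame(rows)
    ref = table.loc[(table.z == 0) & (table.x == 0), "rate"].iloc[0]
    table["rate_ratio"] = table["rate"] / ref if ref > 0 else np.nan
    return table
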