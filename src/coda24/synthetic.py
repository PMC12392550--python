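"""Synthetic two-timepoint cohort generator.

Emulates the statistical structure the association models assume, so every
pipeline stage can be exercised and calibrated without access to cohort data:

* per-child compositions are logistic-normal — ilr coordinates drawn from a
  bivariate normal around the ilr image of a target mean composition, then
  inverted. Drawing in ilr space makes the downstream linear-in-ilr models
  correctly specified, so parameter recovery is exact in expectation;
* two timepoints roughly nine months apart; no second visit once a child
  has passed the age-censoring limit (48 months) and an additional
  independent dropout probability;
* outcomes follow a linear model in (ilr1, ilr2, age, sex) with a
  child-level random intercept (sd ``tau``) and record-level noise
  (sd ``sigma``).

Defaults are anchored to a real infant/toddler cohort's printed summaries:
mean composition near (224, 401, 807) min/day of PA/SB/sleep, first-visit
ages 0-48 months drawn from four yearly bins with weights (47, 52, 43, 19),
45.5% girls, a follow-up gap of 8.7 +/- ~1 months, and outcome scales shaped
like a 0-72 raw gross-motor score, a raw social-emotional score, and a BMI
z-score around +0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_TOTAL,
    Behavior,
    Composition,
    Rotation,
    close,
    ilr_array,
    ilr_inverse_array,
)
from .diary import DiaryEvent

__all__ = [
    "OutcomeModel",
    "CohortParams",
    "SyntheticCohort",
    "simulate_compositions",
    "simulate_cohort",
    "make_diary_fixture",
]

#: Generator rotation: ilr1 pivots on sleep, the dominant behavior.
GENERATOR_ROTATION = Rotation.SLEEP


@dataclass(frozen=True)
class OutcomeModel:
    """True linear outcome model in generator-rotation ilr coordinates."""

    intercept: float
    beta_ilr1: float
    beta_ilr2: float
    beta_age: float
    beta_sex: float
    tau: float  # child random-intercept sd
    sigma: float  # record-level residual sd

    def fixed_effect(
        self, ilr1: np.ndarray, ilr2: np.ndarray, age: np.ndarray, sex: np.ndarray
    ) -> np.ndarray:
        return (
            self.intercept
            + self.beta_ilr1 * ilr1
            + self.beta_ilr2 * ilr2
            + self.beta_age * age
            + self.beta_sex * sex
        )


def _default_outcomes() -> dict[str, OutcomeModel]:
    # gm_raw: a 0-72 motor score rising ~1.1 points/month with a genuine
    # composition effect whose per-rotation ilr1 coefficients sit in the
    # magnitude class of the reported motor associations (sleep-pivot ~ +8.5,
    # SB-pivot ~ -9.4, PA-pivot near 0).
    # zbmi: BMI z-score near +0.7 with a weaker composition effect.
    # se_raw: a null outcome - age and sex only.
    return {
        "gm_raw": OutcomeModel(27.0, 8.5, 6.0, 1.1, 0.5, tau=4.5, sigma=4.0),
        "zbmi": OutcomeModel(0.45, 1.3, 0.5, 0.015, -0.1, tau=0.55, sigma=0.55),
        "se_raw": OutcomeModel(40.0, 0.0, 0.0, 3.0, 2.0, tau=12.0, sigma=10.0),
    }


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth parameters for a simulated cohort."""

    n_children: int = 160
    age_bin_edges: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0)
    age_bin_weights: tuple[float, ...] = (47.0, 52.0, 43.0, 19.0)
    sex_prob_girl: float = 0.455
    followup_gap_months: float = 8.7
    followup_gap_jitter: float = 1.1  # uniform half-width
    censor_age_months: float = 48.0
    dropout_prob: float = 0.13
    mean_composition: Composition = field(
        default_factory=lambda: close((224.3, 401.0, 807.0))
    )
    ilr_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (0.045, -0.012),
        (-0.012, 0.130),
    )
    age_slope_ilr: tuple[float, float] = (0.0, 0.0)  # optional drift per month
    outcomes: Mapping[str, OutcomeModel] = field(default_factory=_default_outcomes)
    total: float = DEFAULT_TOTAL
    rotation: Rotation = GENERATOR_ROTATION

    def __post_init__(self) -> None:
        cov = np.asarray(self.ilr_cov, dtype=float)
        if cov.shape != (2, 2) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("ilr covariance must be a 2x2 positive-definite matrix")
        if not 0 <= self.sex_prob_girl <= 1:
            raise ValueError("sex probability must lie in [0, 1]")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout probability must lie in [0, 1]")
        if len(self.age_bin_weights) != len(self.age_bin_edges) - 1:
            raise ValueError("need one weight per age bin")
        for om in self.outcomes.values():
            if om.sigma < 0 or om.tau < 0:
                raise ValueError("outcome noise sds must be nonnegative")


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated records plus the ground truth that generated them."""

    records: pd.DataFrame
    params: CohortParams
    seed: int

    def truth(self) -> dict:
        """Ground-truth parameters as a JSON-serializable dict."""
        return {
            "seed": self.seed,
            "rotation": self.params.rotation.value,
            "n_children": self.params.n_children,
            "mean_composition": list(self.params.mean_composition.as_array()),
            "ilr_cov": [list(r) for r in self.params.ilr_cov],
            "outcomes": {
                k: vars(v).copy() for k, v in self.params.outcomes.items()
            },
        }


def _mean_matched_location(params: "CohortParams") -> np.ndarray:
    """ilr-space location whose logistic-normal *arithmetic* part means equal
    the target mean composition.

    exp is convex, so placing the normal location at the ilr image of the
    target would bias the minute-scale means away from it (Jensen). A short
    deterministic fixed point on a Gauss-Hermite quadrature of the part
    expectations removes that bias.
    """
    key = (
        tuple(params.mean_composition.as_array()),
        params.ilr_cov,
        params.rotation,
        params.total,
    )
    if key in _LOCATION_CACHE:
        return _LOCATION_CACHE[key]
    cov = np.asarray(params.ilr_cov, dtype=float)
    nodes, wts = np.polynomial.hermite_e.hermegauss(21)
    L = np.linalg.cholesky(cov)
    zgrid = np.array([(a, b) for a in nodes for b in nodes])
    w = np.array([wa * wb for wa in wts for wb in wts])
    w /= w.sum()
    target = ilr_array(params.mean_composition.as_array(), params.rotation)[0]
    mu = target.copy()
    for _ in range(30):
        parts = ilr_inverse_array(mu + zgrid @ L.T, params.rotation, params.total)
        mean_parts = w @ parts
        mu = mu + (target - ilr_array(mean_parts, params.rotation)[0])
    _LOCATION_CACHE[key] = mu
    return mu


_LOCATION_CACHE: dict = {}


def simulate_compositions(
    n: int, params: CohortParams | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n logistic-normal compositions; returns (n, 3) minutes in
    (PA, SB, sleep) order, each row summing to the configured total.

    The normal location is mean-matched (see ``_mean_matched_location``) so
    the sample part means converge to the configured mean composition."""
    params = params or CohortParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mu = _mean_matched_location(params)
    cov = np.asarray(params.ilr_cov, dtype=float)
    z = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    return ilr_inverse_array(z, rotation=params.rotation, total=params.total)


def simulate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> SyntheticCohort:
    """Simulate a two-timepoint cohort under the documented generative model.

    Each child gets a first-timepoint record; a second follows after the
    jittered follow-up gap unless the child would exceed the age-censoring
    limit or drops out at random. Compositions are drawn independently per
    record around the population mean; outcomes share a child-level random
    intercept across timepoints.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    n = params.n_children
    if n <= 0:
        raise ValueError("n_children must be positive")

    edges = np.asarray(params.age_bin_edges, dtype=float)
    w = np.asarray(params.age_bin_weights, dtype=float)
    bins = rng.choice(len(w), size=n, p=w / w.sum())
    age1 = rng.uniform(edges[bins], edges[bins + 1])
    sex = (rng.random(n) < params.sex_prob_girl).astype(int)  # 1 = girl
    gap = params.followup_gap_months + rng.uniform(
        -params.followup_gap_jitter, params.followup_gap_jitter, size=n
    )
    age2 = age1 + gap
    has_t2 = (age2 <= params.censor_age_months) & (
        rng.random(n) >= params.dropout_prob
    )
    if not np.any(age1 <= params.censor_age_months):
        raise ValueError("age censoring removes the entire cohort")

    b_child = {
        name: rng.normal(0.0, om.tau, size=n) for name, om in params.outcomes.items()
    }

    rows = []
    for t, ages, present in ((1, age1, np.ones(n, bool)), (2, age2, has_t2)):
        idx = np.flatnonzero(present)
        minutes = simulate_compositions(len(idx), params, rng)
        z = ilr_array(minutes, params.rotation)
        if any(params.age_slope_ilr):
            z = z + np.outer(ages[idx], np.asarray(params.age_slope_ilr))
            minutes = ilr_inverse_array(z, params.rotation, params.total)
        rec = pd.DataFrame(
            {
                "child_id": [f"c{i + 1:04d}" for i in idx],
                "timepoint": t,
                "age_months": ages[idx],
                "sex": sex[idx],
                "pa_min": minutes[:, 0],
                "sb_min": minutes[:, 1],
                "sleep_min": minutes[:, 2],
            }
        )
        for name, om in params.outcomes.items():
            eps = rng.normal(0.0, om.sigma, size=len(idx))
            rec[name] = (
                om.fixed_effect(z[:, 0], z[:, 1], ages[idx], sex[idx])
                + b_child[name][idx]
                + eps
            )
        rows.append(rec)
    records = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["child_id", "timepoint"], kind="stable")
        .reset_index(drop=True)
    )
    return SyntheticCohort(records=records, params=params, seed=seed)


def make_diary_fixture(
    target: Composition,
    n_days: int = 7,
    invalid_days: int | Sequence[int] = 0,
    child_id: str = "c0001",
    seed: int = 0,
) -> list[DiaryEvent]:
    """Diary events whose aggregation reproduces ``target`` on each valid day.

    Valid days split the target minutes across realistic categories (two
    play events whose jittered durations still sum exactly to the PA total).
    Invalid days inflate the 'I don't know' category well past the 60-minute
    allowance, shrinking the informative coverage below 23 hours.
    """
    if n_days < 1:
        raise ValueError("need at least one day")
    if isinstance(invalid_days, int):
        if invalid_days < 0 or invalid_days > n_days:
            raise ValueError(
                f"cannot mark {invalid_days} of {n_days} days invalid"
            )
        bad = set(range(1, invalid_days + 1))
    else:
        bad = {int(d) for d in invalid_days}
        if not bad <= set(range(1, n_days + 1)):
            raise ValueError(f"invalid day indices {sorted(bad)} outside 1..{n_days}")
    rng = np.random.default_rng(seed)
    events: list[DiaryEvent] = []
    for day in range(1, n_days + 1):
        pa, sb, sleep = target.pa, target.sb, target.sleep
        if day in bad:
            # steal 120 min (well past the 60-min allowance) from the
            # informative categories, proportionally, into 'I don't know'
            scale = (target.total - 120.0) / target.total
            pa, sb, sleep = pa * scale, sb * scale, sleep * scale
            events.append(
                DiaryEvent(child_id, day, 120.0, "I don't know")
            )
        split = rng.uniform(0.3, 0.7)
        events += [
            DiaryEvent(child_id, day, sleep, "sleeping"),
            DiaryEvent(child_id, day, pa * split, "playing", "active"),
            DiaryEvent(child_id, day, pa * (1 - split), "active transport"),
            DiaryEvent(child_id, day, sb * 0.25, "eating/drinking"),
            DiaryEvent(child_id, day, sb * 0.25, "screen use"),
            DiaryEvent(child_id, day, sb * 0.5, "sitting/lying calmly"),
        ]
    return events
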