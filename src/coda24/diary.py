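"""Time-use diary preprocessing.

Parents log their child's day as a sequence of events in an eleven-category
time-use diary app. This module maps those events onto the three movement
behaviors (PA, SB, sleep), applies the day- and child-level validity rules,
and screens derived variables for outliers:

* a day is *valid* when at least 23 hours (1380 min) are covered after
  dropping the three non-informative categories ('other activity',
  'I don't know', 'my child was with someone else');
* a child enters analysis with a minimum of two valid days; the per-behavior
  mean over valid days, closed to a common day length, is the child's
  composition;
* screened variables (ilr coordinates and outcomes) are flagged when their
  z-score falls strictly outside [-3, 3].

The category -> behavior mapping is configuration, not code: the app's full
intensity/posture classification lives in a separate validation study, so the
package ships a documented stand-in mapping (``data/default_mapping.yaml``)
and accepts any user mapping with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .composition import DEFAULT_TOTAL, Behavior, Composition, close

__all__ = [
    "APP_CATEGORIES",
    "EXCLUDED_CATEGORIES",
    "MIN_VALID_MINUTES",
    "DiaryEvent",
    "DayRecord",
    "BehaviorMapping",
    "Rejection",
    "load_mapping",
    "default_mapping",
    "aggregate_days",
    "child_mean_composition",
    "outlier_screen",
    "read_diary_csv",
    "prepare_compositions",
]

#: The closed vocabulary of diary categories offered by the app.
APP_CATEGORIES = (
    "personal care",
    "eating/drinking",
    "sitting/lying calmly",
    "screen use",
    "passive transport",
    "active transport",
    "playing",
    "sleeping",
    "other activity",
    "I don't know",
    "my child was with someone else",
)

#: Categories that never count toward behavior minutes or day coverage.
EXCLUDED_CATEGORIES = frozenset(
    {"other activity", "I don't know", "my child was with someone else"}
)

#: A valid day covers at least 23 hours of informative categories.
MIN_VALID_MINUTES = 1380.0

EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class DiaryEvent:
    child_id: str
    day_index: int
    duration: float  # minutes
    category: str
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError(
                f"event duration must be positive, got {self.duration!r} "
                f"(child {self.child_id}, day {self.day_index})"
            )
        if self.category not in APP_CATEGORIES:
            raise ValueError(
                f"unknown diary category {self.category!r}; "
                f"expected one of {sorted(APP_CATEGORIES)}"
            )


@dataclass(frozen=True)
class DayRecord:
    child_id: str
    day_index: int
    minutes: Mapping[Behavior, float]
    coverage: float
    valid: bool
    excluded_minutes: float = 0.0


class MappingError(ValueError):
    """A diary (category, qualifier) pair with no behavior assignment."""


@dataclass
class BehaviorMapping:
    """(category, qualifier) -> behavior lookup with category-level fallback.

    A rule keyed ``(category, None)`` applies to any qualifier of that
    category unless a more specific ``(category, qualifier)`` rule exists.
    The three non-informative categories are forced to EXCLUDED regardless of
    the configured rules.
    """

    rules: dict[tuple[str, str | None], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (cat, qual), behavior in self.rules.items():
            if cat not in APP_CATEGORIES:
                raise MappingError(f"mapping references unknown category {cat!r}")
            if behavior != EXCLUDED:
                Behavior(behavior)  # raises on unknown label
        for cat in EXCLUDED_CATEGORIES:
            self.rules[(cat, None)] = EXCLUDED

    def resolve(self, category: str, qualifier: str | None = None) -> str:
        if category in EXCLUDED_CATEGORIES:
            return EXCLUDED
        if (category, qualifier) in self.rules:
            return self.rules[(category, qualifier)]
        if (category, None) in self.rules:
            return self.rules[(category, None)]
        raise MappingError(
            f"no behavior rule for category={category!r}, qualifier={qualifier!r}"
        )


def load_mapping(path: str | Path) -> BehaviorMapping:
    """Load a YAML mapping: list of {category, qualifier (optional), behavior}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "rules" not in raw:
        raise MappingError(f"mapping file {path} must contain a top-level 'rules' list")
    rules: dict[tuple[str, str | None], str] = {}
    for row in raw["rules"]:
        cat = row["category"]
        qual = row.get("qualifier") or None
        behavior = str(row["behavior"]).upper()
        rules[(cat, qual)] = behavior
    return BehaviorMapping(rules)


def default_mapping() -> BehaviorMapping:
    """The package's provisional stand-in mapping (see module docstring)."""
    ref = resources.files("coda24").joinpath("data/default_mapping.yaml")
    with resources.as_file(ref) as path:
        return load_mapping(path)


def aggregate_days(
    events: Iterable[DiaryEvent], mapping: BehaviorMapping
) -> list[DayRecord]:
    """Sum event minutes into per-(child, day) behavior totals.

    Coverage counts only informative (non-EXCLUDED) minutes; validity is
    coverage >= 23 h. Days with no events produce no record. Unmapped pairs
    raise a MappingError naming the pair so configs fail loudly.
    """
    buckets: dict[tuple[str, int], dict[str, float]] = {}
    for ev in events:
        behavior = mapping.resolve(ev.category, ev.qualifier)
        key = (ev.child_id, ev.day_index)
        day = buckets.setdefault(
            key, {b.value: 0.0 for b in Behavior} | {EXCLUDED: 0.0}
        )
        day[behavior if behavior == EXCLUDED else Behavior(behavior).value] += ev.duration
    records = []
    for (child, day_index), sums in sorted(buckets.items()):
        coverage = sum(sums[b.value] for b in Behavior)
        records.append(
            DayRecord(
                child_id=child,
                day_index=day_index,
                minutes={b: sums[b.value] for b in Behavior},
                coverage=coverage,
                valid=coverage >= MIN_VALID_MINUTES,
                excluded_minutes=sums[EXCLUDED],
            )
        )
    return records


@dataclass(frozen=True)
class Rejection:
    child_id: str
    reason: str


def child_mean_composition(
    days: Sequence[DayRecord],
    min_valid_days: int = 2,
    total: float = DEFAULT_TOTAL,
) -> Composition | Rejection:
    """Mean daily composition over a child's valid days, closed to ``total``.

    Children with fewer than ``min_valid_days`` valid days are rejected, as
    are children whose valid days contain a zero behavior total (the ilr map
    is undefined at the boundary of the simplex).
    """
    if not days:
        raise ValueError("no day records supplied")
    ids = {d.child_id for d in days}
    if len(ids) != 1:
        raise ValueError(f"day records mix children: {sorted(ids)}")
    child = next(iter(ids))
    valid = [d for d in days if d.valid]
    if len(valid) < min_valid_days:
        return Rejection(
            child, f"insufficient valid days ({len(valid)} < {min_valid_days})"
        )
    means = {
        b: float(np.mean([d.minutes[b] for d in valid])) for b in Behavior
    }
    if any(v <= 0 for v in means.values()):
        zero = [b.value for b, v in means.items() if v <= 0]
        return Rejection(child, f"zero part in mean day: {', '.join(zero)}")
    return close((means[Behavior.PA], means[Behavior.SB], means[Behavior.SLEEP]), total)


def outlier_screen(
    values: Sequence[float], lo: float = -3.0, hi: float = 3.0
) -> np.ndarray:
    """Flag values whose z-score lies strictly outside [lo, hi].

    Uses the sample standard deviation (n-1); a constant list (sd = 0) flags
    nothing. NaNs are never flagged and are excluded from mean/sd.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("outlier screening needs at least two observed values")
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    flags = np.zeros(v.shape, dtype=bool)
    if sd == 0:
        return flags
    z = (v - mean) / sd
    flags[finite] = (z[finite] < lo) | (z[finite] > hi)
    return flags


def read_diary_csv(path: str | Path) -> list[DiaryEvent]:
    """Read events from CSV with columns child_id, day_index, duration_min,
    category, qualifier (qualifier may be blank)."""
    df = pd.read_csv(path, dtype={"child_id": str, "qualifier": str})
    required = {"child_id", "day_index", "duration_min", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"diary CSV {path} missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        qual = getattr(row, "qualifier", None)
        if qual is not None and (pd.isna(qual) or qual == ""):
            qual = None
        events.append(
            DiaryEvent(
                child_id=str(row.child_id),
                day_index=int(row.day_index),
                duration=float(row.duration_min),
                category=str(row.category),
                qualifier=qual,
            )
        )
    return events


def prepare_compositions(
    events: Iterable[DiaryEvent],
    mapping: BehaviorMapping | None = None,
    min_valid_days: int = 2,
    total: float = DEFAULT_TOTAL,
) -> tuple[pd.DataFrame, list[Rejection]]:
    """Diary events -> per-child mean compositions plus a rejection log.

    Returns a DataFrame (child_id, pa_min, sb_min, sleep_min, n_valid_days)
    with one row per accepted child, and the list of rejected children with
    reasons.
    """
    mapping = mapping or default_mapping()
    day_records = aggregate_days(events, mapping)
    by_child: dict[str, list[DayRecord]] = {}
    for rec in day_records:
        by_child.setdefault(rec.child_id, []).append(rec)
    rows, rejections = [], []
    for child in sorted(by_child):
        days = by_child[child]
        result = child_mean_composition(days, min_valid_days=min_valid_days, total=total)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            rows.append(
                {
                    "child_id": child,
                    "pa_min": result.pa,
                    "sb_min": result.sb,
                    "sleep_min": result.sleep,
                    "n_valid_days": sum(d.valid for d in days),
                }
            )
    columns = ["child_id", "pa_min", "sb_min", "sleep_min", "n_valid_days"]
    return pd.DataFrame(rows, columns=columns), rejections
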