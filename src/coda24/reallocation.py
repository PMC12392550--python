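"""Compositional isotemporal reallocation.

Given a fitted cross-sectional model, predict how an outcome would change if
a fixed number of minutes were moved between behaviors around a reference
composition, holding the 24-hour total constant:

* proportional: minutes are added to (or taken from) one *focal* behavior
  and taken from (given to) the other two, either split equally or in
  proportion to their baseline minutes;
* one-by-one: minutes move directly from one behavior to another, the third
  held constant.

The predicted change is a linear contrast of the fitted ilr coefficients:
with ``d`` the difference of ilr coordinates (new minus base, padded with
zeros for the covariate terms, which cancel in the difference), the change is
``d @ beta`` with standard error ``sqrt(d' Sigma d)`` and a t-based CI using
the residual degrees of freedom. A change is declared significant when the
95% CI excludes zero. The zero-minute reallocation is exactly zero with a
zero-width interval by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .composition import (
    Behavior,
    Composition,
    close,
    compositional_mean,
    ilr_array,
)
from .models import ModelFit

__all__ = [
    "ReallocationSpec",
    "ReallocationEstimate",
    "InfeasibleReallocation",
    "build_grid",
    "apply_reallocation",
    "predict_delta",
    "reallocation_curves",
    "one_by_one_table",
    "ORDERED_PAIRS",
]

#: The six ordered (from, to) behavior pairs, in conventional table order.
ORDERED_PAIRS: tuple[tuple[Behavior, Behavior], ...] = (
    (Behavior.PA, Behavior.SB),
    (Behavior.PA, Behavior.SLEEP),
    (Behavior.SB, Behavior.PA),
    (Behavior.SB, Behavior.SLEEP),
    (Behavior.SLEEP, Behavior.PA),
    (Behavior.SLEEP, Behavior.SB),
)


class InfeasibleReallocation(ValueError):
    """The requested shift would push a behavior to zero or below."""

    def __init__(self, behavior: Behavior, minutes: float):
        self.behavior = behavior
        self.minutes = minutes
        super().__init__(
            f"reallocation drives {behavior.value} to {minutes:.1f} min"
        )


@dataclass(frozen=True)
class ReallocationSpec:
    """One point on a reallocation grid.

    For ``proportional`` the ``delta`` is added to ``focal`` and drawn from
    the other two behaviors; for ``one_by_one`` ``delta`` minutes move from
    ``from_behavior`` to ``to_behavior``.
    """

    scheme: Literal["proportional", "one_by_one"]
    delta: float
    focal: Behavior | None = None
    from_behavior: Behavior | None = None
    to_behavior: Behavior | None = None
    split: Literal["equal", "proportional_to_base"] | tuple = "equal"

    def __post_init__(self) -> None:
        if self.scheme == "proportional":
            if self.focal is None:
                raise ValueError("proportional spec requires a focal behavior")
        elif self.scheme == "one_by_one":
            if self.from_behavior is None or self.to_behavior is None:
                raise ValueError("one_by_one spec requires a (from, to) pair")
            if self.from_behavior == self.to_behavior:
                raise ValueError("from and to behaviors must differ")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def label(self) -> str:
        if self.scheme == "proportional":
            return f"proportional:{self.focal.value}"
        return f"{self.from_behavior.value}->{self.to_behavior.value}"


@dataclass(frozen=True)
class ReallocationEstimate:
    spec: ReallocationSpec
    base: Composition
    new: Composition
    change: float
    ci_low: float
    ci_high: float
    significant: bool


def build_grid(
    scheme: Literal["proportional", "one_by_one"],
    increment: float = 10.0,
    lo: float = -60.0,
    hi: float = 60.0,
    split: Literal["equal", "proportional_to_base"] = "equal",
) -> list[ReallocationSpec]:
    """Full reallocation grid in ``increment``-minute steps over [lo, hi].

    Each proportional curve (one per focal behavior) and each one-by-one
    curve (one per ordered pair; the negative half mirrors the reversed pair
    but is kept so curves plot symmetrically) passes through delta = 0.
    """
    if not (lo < 0 < hi):
        raise ValueError("grid must straddle zero (lo < 0 < hi)")
    for bound in (lo, hi):
        if abs(round(bound / increment) * increment - bound) > 1e-9:
            raise ValueError(
                f"increment {increment} does not divide grid bound {bound}"
            )
    deltas = np.arange(round(lo / increment), round(hi / increment) + 1) * increment
    specs: list[ReallocationSpec] = []
    if scheme == "proportional":
        for focal in Behavior:
            specs += [
                ReallocationSpec("proportional", float(d), focal=focal, split=split)
                for d in deltas
            ]
    elif scheme == "one_by_one":
        for frm, to in ORDERED_PAIRS:
            specs += [
                ReallocationSpec(
                    "one_by_one", float(d), from_behavior=frm, to_behavior=to
                )
                for d in deltas
            ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return specs


def apply_reallocation(base: Composition, spec: ReallocationSpec) -> Composition:
    """Shift minutes per the spec; the day total is conserved exactly."""
    minutes = {b: base.part(b) for b in Behavior}
    if spec.scheme == "proportional":
        others = [b for b in Behavior if b != spec.focal]
        if spec.split == "equal":
            shares = {b: 0.5 for b in others}
        elif spec.split == "proportional_to_base":
            tot = sum(minutes[b] for b in others)
            shares = {b: minutes[b] / tot for b in others}
        else:
            # explicit ((behavior, weight), ...) pairs over the two non-focal
            # behaviors; weights must sum to 1
            shares = {Behavior(b): float(w) for b, w in spec.split}
            if set(shares) != set(others) or abs(sum(shares.values()) - 1) > 1e-12:
                raise ValueError(
                    "custom split must weight exactly the two non-focal "
                    "behaviors and sum to 1"
                )
        minutes[spec.focal] += spec.delta
        for b in others:
            minutes[b] -= spec.delta * shares[b]
    else:
        minutes[spec.from_behavior] -= spec.delta
        minutes[spec.to_behavior] += spec.delta
    for b, v in minutes.items():
        if v <= 0:
            raise InfeasibleReallocation(b, v)
    return Composition(
        minutes[Behavior.PA], minutes[Behavior.SB], minutes[Behavior.SLEEP], base.total
    )


def predict_delta(
    fit: ModelFit,
    base: Composition,
    spec: ReallocationSpec,
    level: float = 0.95,
) -> ReallocationEstimate:
    """Predicted outcome change for one reallocation, with its CI.

    Only the two ilr terms contribute: age and sex take the same value under
    both compositions, so their terms cancel in the prediction difference.
    """
    if fit.model_class != "linear":
        raise ValueError(
            "reallocation predictions are defined for cross-sectional linear "
            "fits; mixed-model reallocation is out of scope"
        )
    if "ilr1" not in fit.term_names:
        raise ValueError("fit must include ilr coordinates")
    new = apply_reallocation(base, spec)
    z = ilr_array(
        np.vstack([new.as_array(), base.as_array()]), fit.rotation
    )
    d = z[0] - z[1]
    beta = fit.params[["ilr1", "ilr2"]].to_numpy()
    cov = fit.cov_params.loc[["ilr1", "ilr2"], ["ilr1", "ilr2"]].to_numpy()
    if spec.delta == 0:
        return ReallocationEstimate(spec, base, new, 0.0, 0.0, 0.0, False)
    change = float(d @ beta)
    se = float(np.sqrt(d @ cov @ d))
    q = st.t.ppf(0.5 + level / 2, fit.df_resid)
    lo, hi = change - q * se, change + q * se
    return ReallocationEstimate(spec, base, new, change, lo, hi, not (lo <= 0 <= hi))


def reallocation_curves(
    fit: ModelFit,
    compositions: Sequence[Composition] | Composition,
    scheme: Literal["proportional", "one_by_one"] = "one_by_one",
    increment: float = 10.0,
    lo: float = -60.0,
    hi: float = 60.0,
    split: Literal["equal", "proportional_to_base"] = "equal",
    reference: Literal["arithmetic", "geometric"] = "arithmetic",
    level: float = 0.95,
) -> pd.DataFrame:
    """Evaluate a full reallocation grid around the sample reference
    composition.

    ``compositions`` is the analysis sample (the reference is its closed
    arithmetic mean by default, geometric optionally) or a single
    pre-computed reference composition. Grid points that would push a
    behavior to zero are reported with ``feasible = False`` and NaN
    estimates rather than raised.
    """
    if isinstance(compositions, Composition):
        base = compositions
    else:
        base = compositional_mean(compositions, method=reference)
    rows = []
    for spec in build_grid(scheme, increment, lo, hi, split):
        row = {
            "scheme": spec.scheme,
            "curve": spec.label(),
            "focal": spec.focal.value if spec.focal else "",
            "from": spec.from_behavior.value if spec.from_behavior else "",
            "to": spec.to_behavior.value if spec.to_behavior else "",
            "delta_min": spec.delta,
        }
        try:
            est = predict_delta(fit, base, spec, level)
            row |= {
                "estimate": est.change,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "significant": est.significant,
                "feasible": True,
            }
        except InfeasibleReallocation:
            row |= {
                "estimate": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "significant": False,
                "feasible": False,
            }
        rows.append(row)
    return pd.DataFrame(rows)


def one_by_one_table(
    fits: dict[str, ModelFit],
    compositions_by_outcome: dict[str, Sequence[Composition]],
    delta: float = 10.0,
    reference: Literal["arithmetic", "geometric"] = "arithmetic",
) -> pd.DataFrame:
    """Wide table of one-by-one reallocations at a single delta: one row per
    outcome, one column per ordered behavior pair, cells 'est [lo, hi]'."""
    rows = {}
    for outcome, fit in fits.items():
        base = compositional_mean(
            compositions_by_outcome[outcome], method=reference
        )
        cells = {}
        for frm, to in ORDERED_PAIRS:
            spec = ReallocationSpec(
                "one_by_one", delta, from_behavior=frm, to_behavior=to
            )
            try:
                est = predict_delta(fit, base, spec)
                cells[f"{frm.value} to {to.value}"] = (
                    f"{est.change:.2f} [{est.ci_low:.2f}, {est.ci_high:.2f}]"
                )
            except InfeasibleReallocation:
                cells[f"{frm.value} to {to.value}"] = "infeasible"
        rows[outcome] = cells
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_reallocation_curves(curves: pd.DataFrame, outcome_label: str = "outcome"):
    """Estimate line with shaded CI band, one panel per curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(dict.fromkeys(curves["curve"]))
    ncol = 3
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), sharex=True, squeeze=False
    )
    for ax, name in zip(axes.ravel(), names):
        sub = curves[(curves["curve"] == name) & curves["feasible"]]
        ax.fill_between(sub["delta_min"], sub["ci_low"], sub["ci_high"], alpha=0.25)
        ax.plot(sub["delta_min"], sub["estimate"], lw=1.5)
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(name, fontsize=9)
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    for ax in axes[-1]:
        ax.set_xlabel("reallocated minutes")
    for row in axes:
        row[0].set_ylabel(f"predicted change in {outcome_label}")
    fig.tight_layout()
    return fig
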