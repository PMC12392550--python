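"""Aitchison-geometry kernel for three-part time-use compositions.

A day is partitioned exhaustively into physical activity (PA), sedentary
behavior (SB) and sleep. Minutes in the three behaviors carry only relative
information, so all modelling happens in isometric log-ratio (ilr) *pivot*
coordinates: for a chosen reference behavior ``r`` with the remaining two
behaviors ``a, b`` in canonical order,

    ilr1 = sqrt(2/3) * ln( x_r / sqrt(x_a * x_b) )
    ilr2 = sqrt(1/2) * ln( x_a / x_b )

ilr1 captures the reference behavior relative to the (geometric mean of the)
other two; ilr2 captures the remaining pair against each other. Three
rotations — one per reference behavior — are orthonormal re-coordinatizations
of the same two-dimensional simplex, so model fit statistics are invariant to
the choice; only which behavior ilr1 speaks about changes.

The canonical remaining-pair order follows the cycle PA -> SB -> SLEEP -> PA
with the reference removed, e.g. reference SB leaves (SLEEP, PA).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Behavior",
    "Rotation",
    "Composition",
    "IlrCoordinates",
    "DEFAULT_TOTAL",
    "close",
    "ilr",
    "ilr_array",
    "ilr_inverse",
    "ilr_inverse_array",
    "compositional_mean",
    "rotation_basis",
]

#: Default closure constant: minutes in one day.
DEFAULT_TOTAL = 1440.0

_SQ23 = math.sqrt(2.0 / 3.0)
_SQ12 = math.sqrt(1.0 / 2.0)


class Behavior(str, enum.Enum):
    """The three mutually exclusive, exhaustive movement behaviors."""

    PA = "PA"
    SB = "SB"
    SLEEP = "SLEEP"


_CYCLE = (Behavior.PA, Behavior.SB, Behavior.SLEEP)


class Rotation(str, enum.Enum):
    """Choice of ilr reference behavior (the pivot of ilr1)."""

    PA = "PA"
    SB = "SB"
    SLEEP = "SLEEP"

    @property
    def reference(self) -> Behavior:
        return Behavior(self.value)

    @property
    def remaining(self) -> tuple[Behavior, Behavior]:
        """The non-reference pair in canonical cycle order.

        Walk the cycle PA -> SB -> SLEEP starting just after the reference;
        deterministic, so every rotation has a single well-defined basis.
        """
        i = _CYCLE.index(self.reference)
        return (_CYCLE[(i + 1) % 3], _CYCLE[(i + 2) % 3])

    @property
    def order(self) -> tuple[int, int, int]:
        """Column indices of (reference, first remaining, second remaining)
        within the canonical (PA, SB, SLEEP) layout."""
        ref = _CYCLE.index(self.reference)
        a, b = (_CYCLE.index(p) for p in self.remaining)
        return (ref, a, b)


def rotation_basis(rotation: Rotation) -> np.ndarray:
    """Orthonormal clr-plane basis (2 x 3) implied by a rotation.

    Rows are the clr images of the two ilr axes in canonical (PA, SB, SLEEP)
    column order; they have unit norm, zero dot product, and zero row sums.
    """
    ref, a, b = Rotation(rotation).order
    basis = np.zeros((2, 3))
    basis[0, ref] = _SQ23
    basis[0, a] = basis[0, b] = -_SQ23 / 2.0
    basis[1, a] = _SQ12
    basis[1, b] = -_SQ12
    return basis


@dataclass(frozen=True)
class Composition:
    """Strictly positive minutes/day in (PA, SB, sleep), closed to ``total``."""

    pa: float
    sb: float
    sleep: float
    total: float = DEFAULT_TOTAL

    def __post_init__(self) -> None:
        for name in ("pa", "sb", "sleep", "total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"composition part {name!r} must be strictly positive "
                    f"and finite, got {v!r}"
                )
        s = self.pa + self.sb + self.sleep
        if abs(s - self.total) > 1e-9 * self.total:
            raise ValueError(
                f"parts sum to {s}, not the closure total {self.total}; "
                "use close() to construct closed compositions"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.pa, self.sb, self.sleep])

    def part(self, behavior: Behavior) -> float:
        return {
            Behavior.PA: self.pa,
            Behavior.SB: self.sb,
            Behavior.SLEEP: self.sleep,
        }[Behavior(behavior)]


@dataclass(frozen=True)
class IlrCoordinates:
    """A composition's image under one rotation's pivot coordinates."""

    ilr1: float
    ilr2: float
    rotation: Rotation

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ilr1) and math.isfinite(self.ilr2)):
            raise ValueError("ilr coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.ilr1, self.ilr2])


def close(
    parts: Sequence[float] | Composition, total: float = DEFAULT_TOTAL
) -> Composition:
    """Rescale three positive parts to sum to ``total``.

    Closure discards the (arbitrary) recorded day length so that minute-based
    statements like "move 10 min from SB to PA" mean the same thing for every
    child.
    """
    if isinstance(parts, Composition):
        parts = (parts.pa, parts.sb, parts.sleep)
    pa, sb, sleep = (float(p) for p in parts)
    if not (math.isfinite(total) and total > 0):
        raise ValueError(f"closure total must be positive and finite, got {total!r}")
    for name, v in (("pa", pa), ("sb", sb), ("sleep", sleep)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(
                f"part {name!r} must be strictly positive and finite, got {v!r}"
            )
    k = total / (pa + sb + sleep)
    # renormalize exactly so the dataclass invariant holds at float precision
    scaled = np.array([pa, sb, sleep]) * k
    scaled *= total / scaled.sum()
    return Composition(scaled[0], scaled[1], scaled[2], total)


def ilr(c: Composition, rotation: Rotation = Rotation.PA) -> IlrCoordinates:
    """Pivot ilr coordinates of one composition under a rotation."""
    rotation = Rotation(rotation)
    ref, a, b = rotation.order
    x = c.as_array()
    z1 = _SQ23 * math.log(x[ref] / math.sqrt(x[a] * x[b]))
    z2 = _SQ12 * math.log(x[a] / x[b])
    return IlrCoordinates(z1, z2, rotation)


def ilr_array(minutes: np.ndarray, rotation: Rotation = Rotation.PA) -> np.ndarray:
    """Vectorized pivot ilr: (n, 3) strictly positive minutes in canonical
    (PA, SB, SLEEP) order -> (n, 2) coordinates."""
    x = np.asarray(minutes, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != 3:
        raise ValueError("expected three parts per row (PA, SB, SLEEP)")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all parts must be strictly positive and finite")
    ref, a, b = Rotation(rotation).order
    z1 = _SQ23 * (np.log(x[:, ref]) - 0.5 * (np.log(x[:, a]) + np.log(x[:, b])))
    z2 = _SQ12 * (np.log(x[:, a]) - np.log(x[:, b]))
    return np.column_stack([z1, z2])


def ilr_inverse(
    z: IlrCoordinates | Sequence[float],
    total: float = DEFAULT_TOTAL,
    rotation: Rotation | None = None,
) -> Composition:
    """Map ilr coordinates back to a composition closed to ``total``."""
    if isinstance(z, IlrCoordinates):
        rotation = z.rotation
        coords = z.as_array()
    else:
        if rotation is None:
            raise ValueError("rotation required when passing raw coordinates")
        coords = np.asarray(z, dtype=float)
    parts = ilr_inverse_array(coords[None, :], rotation=rotation, total=total)[0]
    return Composition(parts[0], parts[1], parts[2], total)


def ilr_inverse_array(
    coords: np.ndarray,
    rotation: Rotation = Rotation.PA,
    total: float = DEFAULT_TOTAL,
) -> np.ndarray:
    """Vectorized inverse pivot ilr: (n, 2) -> (n, 3) canonical minutes."""
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    basis = rotation_basis(rotation)
    logx = z @ basis  # clr plane, canonical order
    x = np.exp(logx - logx.max(axis=1, keepdims=True))
    return x / x.sum(axis=1, keepdims=True) * total


def compositional_mean(
    samples: Iterable[Composition],
    method: Literal["arithmetic", "geometric"] = "arithmetic",
    total: float = DEFAULT_TOTAL,
) -> Composition:
    """Per-part arithmetic or geometric mean of compositions, re-closed.

    The geometric mean is the Aitchison center (the ilr-space mean mapped
    back); the arithmetic mean is the everyday minutes-scale average. Both are
    offered because reallocation results are reported around a reference
    composition and the choice is a documented analysis setting.
    """
    arr = np.array([c.as_array() for c in samples], dtype=float)
    if arr.size == 0:
        raise ValueError("compositional_mean requires a nonempty sample")
    if method == "arithmetic":
        m = arr.mean(axis=0)
    elif method == "geometric":
        m = np.exp(np.log(arr).mean(axis=0))
    else:
        raise ValueError(f"unknown mean method {method!r}")
    return close(m, total)
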