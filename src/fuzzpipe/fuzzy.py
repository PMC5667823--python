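"""Trapezoidal fuzzy sets, standard partitions and t-norm conjunction.

Prior knowledge about extracted objects ("valid nuclei occupy 449--2016
voxels") is encoded as trapezoidal membership functions

    mu(x; a, b, c, d) = max(min((x - a)/(b - a), 1, (d - x)/(d - c)), 0),

parameterised by the breakpoint vector theta = (a, b, c, d).  Degenerate
edges (b == a or d == c) drop the corresponding term from the inner
minimum, which realises rectangular membership functions and singletons.
Memberships of several features describing one linguistic term (e.g.
"correct object") are combined with a t-norm; the complement of a
combined term is 1 - mu.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "TrapezoidParams",
    "FuzzySet",
    "Partition",
    "TNormKind",
    "evaluate_trapezoid",
    "combine_conjunction",
    "complement",
    "fit_trapezoid_from_quantiles",
]


@dataclass(frozen=True)
class TrapezoidParams:
    """Breakpoints of a trapezoidal membership function, a <= b <= c <= d."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c, self.d)):
            raise ValueError("trapezoid breakpoints must be finite")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"breakpoints must satisfy a <= b <= c <= d, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


class TNormKind(str, Enum):
    """Fuzzy conjunction operator: minimum, product or bounded difference."""

    MINIMUM = "minimum"
    PRODUCT = "product"
    BOUNDED_DIFFERENCE = "bounded_difference"


@dataclass(frozen=True)
class FuzzySet:
    """A linguistic term over one feature axis.

    Parameters
    ----------
    name
        Linguistic term label, e.g. ``"correct"``, ``"too_small"``.
    params
        Trapezoid breakpoints in the feature's units.
    feature
        Name of the feature column the set evaluates.
    """

    name: str
    params: TrapezoidParams
    feature: str

    def __call__(self, x):
        return evaluate_trapezoid(self.params, x)


@dataclass(frozen=True)
class Partition:
    """Ordered family of fuzzy sets over one axis forming a standard partition.

    In a standard partition at most two neighbouring sets overlap and the
    memberships sum to 1 everywhere inside the covered range; adjacent
    trapezoids therefore share their transition edges (d_i == b_{i+1} and
    c_i == a_{i+1} is the usual construction).
    """

    sets: tuple[FuzzySet, ...]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("partition needs at least one fuzzy set")
        feats = {s.feature for s in self.sets}
        if len(feats) > 1:
            raise ValueError("all sets of a partition must share one feature")

    @property
    def feature(self) -> str:
        return self.sets[0].feature

    def memberships(self, x) -> np.ndarray:
        """Membership of ``x`` in every term; shape (n_terms,) + shape(x)."""
        return np.stack([s(x) for s in self.sets])

    def coverage_range(self) -> tuple[float, float]:
        """Interval on which the partition is expected to sum to one."""
        return (min(s.params.b for s in self.sets), max(s.params.c for s in self.sets))


def evaluate_trapezoid(params: TrapezoidParams, x):
    """Evaluate the trapezoidal membership function at ``x``.

    ``x`` may be a scalar or an array; the result is clipped to [0, 1].
    A degenerate rising edge (b == a) or falling edge (d == c) is treated
    as an infinitely steep transition, i.e. the term is dropped from the
    inner minimum rather than evaluated as 0/0.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("membership evaluation requires finite inputs")
    a, b, c, d = params.as_tuple()
    out = np.ones_like(arr)
    # near-degenerate edges can overflow the slope; the clip below bounds it
    with np.errstate(over="ignore"):
        if b > a:
            out = np.minimum(out, (arr - a) / (b - a))
        else:  # rectangular edge: zero strictly left of the plateau
            out = np.where(arr < a, 0.0, out)
        if d > c:
            out = np.minimum(out, (d - arr) / (d - c))
        else:
            out = np.where(arr > d, 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def combine_conjunction(degrees, kind: TNormKind | str = TNormKind.MINIMUM):
    """Fold membership degrees with a t-norm (fuzzy logical AND).

    ``degrees`` is a non-empty sequence of values in [0, 1]; arrays are
    combined elementwise.  Features that should not contribute are
    disabled upstream by supplying the constant 1 (the identity element
    of every t-norm).
    """
    kind = TNormKind(kind)
    degs = [np.asarray(d, dtype=float) for d in degrees]
    if len(degs) == 0:
        raise ValueError("cannot combine an empty list of membership degrees")
    for d in degs:
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("membership degrees must lie in [0, 1]")
    if kind is TNormKind.MINIMUM:
        out = degs[0]
        for d in degs[1:]:
            out = np.minimum(out, d)
    elif kind is TNormKind.PRODUCT:
        out = degs[0]
        for d in degs[1:]:
            out = out * d
    else:  # bounded difference: max(0, sum - (n - 1))
        out = sum(degs) - (len(degs) - 1)
        out = np.maximum(out, 0.0)
    if all(np.ndim(d) == 0 for d in degs):
        return float(out)
    return out


def complement(degree):
    """Complement 1 - mu of a (combined) membership degree."""
    arr = np.asarray(degree, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("membership degrees must lie in [0, 1]")
    out = 1.0 - arr
    if np.ndim(degree) == 0:
        return float(out)
    return out


def fit_trapezoid_from_quantiles(
    samples: Iterable[float],
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    method: str = "linear",
) -> TrapezoidParams:
    """Parameterise a trapezoid from an empirical feature distribution.

    The observed minimum and maximum become ``a`` and ``d``; the
    ``lower_q`` and ``upper_q`` empirical quantiles (linear interpolation
    by default) become ``b`` and ``c``, so everything outside the observed
    range gets membership zero and the central quantile span membership
    one.  ``b`` and ``c`` are clamped into [a, d] to preserve ordering.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to fit a trapezoid")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    a = float(x.min())
    d = float(x.max())
    if a == d:
        warnings.warn("constant samples: fitted trapezoid degenerates to a singleton")
        return TrapezoidParams(a, a, a, a)
    b = float(np.quantile(x, lower_q, method=method))
    c = float(np.quantile(x, upper_q, method=method))
    b = min(max(b, a), d)
    c = min(max(c, b), d)
    return TrapezoidParams(a, b, c, d)
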