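"""Tract-length estimation from marker inclusion/exclusion bounds.

A gene-conversion/hDNA tract is only observed through the markers it covers:
its true length lies between ``a`` (the span of the outermost included
markers; the marker footprint for single-marker tracts) and ``b`` (the span
of the nearest excluded flanking markers).  Lengths are modeled as
exponential with rate lambda = -ln(p), the continuous counterpart of a
per-base extension probability ``p`` (default 0.99717, mean ~353 bp); the
point estimate for a tract is the conditional expectation of that
distribution truncated to [a, b]:

    E[L | a <= L <= b] = 1/lambda + (a e^{-la} - b e^{-lb}) / (e^{-la} - e^{-lb})

For ``p`` this close to 1 the continuous form differs from the discrete
geometric by well under a base pair.  Trans tracts are split at the
strand-phase switch into two independent halves, each estimated separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .tract_analysis import TractCall

__all__ = [
    "TractBounds",
    "ExtensionModel",
    "TractLengthError",
    "estimate_tract_length",
    "split_trans_tract",
    "summarize_lengths",
    "LengthSummary",
    "tract_bounds",
]


class TractLengthError(ValueError):
    pass


@dataclass(frozen=True)
class TractBounds:
    """Minimum (a) and maximum (b) possible tract length in bp."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0 < self.a:
            raise TractLengthError("minimum length a must be positive")
        if self.a > self.b:
            raise TractLengthError(f"invalid bounds: a={self.a} > b={self.b}")


@dataclass(frozen=True)
class ExtensionModel:
    """Per-base tract extension probability p (0 < p < 1)."""

    p: float = 0.99717

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise TractLengthError("extension probability must be in (0, 1)")

    @property
    def rate(self) -> float:
        return -math.log(self.p)


def estimate_tract_length(bounds: TractBounds, model: ExtensionModel) -> float:
    """Expected length of an exponential tract truncated to [a, b].

    Returns ``a`` when the bounds are degenerate (a == b); approaches the
    interval midpoint as p -> 1 (the truncated density flattens to uniform).
    """
    a, b = bounds.a, bounds.b
    if a == b:
        return float(a)
    lam = model.rate
    t = lam * (b - a)
    if t < 1e-9:
        # flat-density limit; the correction term is O(t) * (b - a)
        return (a + b) / 2.0
    # algebraically equal to 1/lam + (a e^{-la} - b e^{-lb})/(e^{-la} - e^{-lb}),
    # rearranged around expm1 to stay stable as p -> 1
    em1 = -math.expm1(-t)  # 1 - e^{-t}
    return b + (b - a) * (1.0 / t - 1.0 / em1)


def tract_bounds(tract: TractCall) -> TractBounds:
    """Bounds for a whole (cis or undetermined) tract from its marker spans."""
    return TractBounds(a=float(tract.span_min), b=float(tract.span_max))


def split_trans_tract(tract: TractCall) -> tuple[TractBounds, TractBounds]:
    """Independent bounds for the two halves of a trans tract.

    The inner boundary of each half sits at the halfway point between the
    facing markers of the two opposite-strand runs; outer boundaries use the
    tract's excluded flanking markers as usual.
    """
    if tract.cis_trans != "trans" or not tract.donor_runs or len(tract.donor_runs) < 2:
        raise TractLengthError("split_trans_tract requires a trans-classified tract")
    runs = tract.donor_runs
    first, second = runs[0], runs[-1]
    mid = (first[-1].position + second[0].position) / 2.0
    a1 = float(first[-1].position - first[0].position) or float(first[0].footprint)
    a2 = float(second[-1].position - second[0].position) or float(second[0].footprint)
    b1 = mid - tract.left_excluded_pos
    b2 = tract.right_excluded_pos - mid
    return TractBounds(a1, max(a1, b1)), TractBounds(a2, max(a2, b2))


class LengthSummary(NamedTuple):
    n: int
    mean: float
    sem: float


def summarize_lengths(
    estimates: Iterable[float], sem_if_single: float = float("nan")
) -> LengthSummary:
    """Sample size, arithmetic mean, and standard error of the mean."""
    values = np.asarray(list(estimates), dtype=float)
    if values.size == 0:
        raise TractLengthError("no length estimates to summarize")
    if values.size == 1:
        return LengthSummary(1, float(values[0]), sem_if_single)
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return LengthSummary(int(values.size), float(values.mean()), sem)
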