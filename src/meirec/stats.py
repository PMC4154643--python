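"""Exact and resampling statistics for recombination-tract comparisons.

Thin, validated wrappers around scipy's implementations: a two-sided
Fisher's exact test on 2x2 tables (sum of hypergeometric probabilities no
larger than the observed table's, with the conventional 1 + 1e-7 relative
tie tolerance), the closed-form probability of zero successes in n binomial
trials, and two-sample tract-length comparisons (Welch or paired t, with a
seeded permutation alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "StatsError",
    "fisher_exact_two_sided",
    "binomial_zero_probability",
    "compare_tract_lengths",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise StatsError("contingency counts must be non-negative integers")
        if sum(counts) == 0:
            raise StatsError("contingency table is empty")

    @classmethod
    def from_rows(cls, table: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = table
        return cls(int(a), int(b), int(c), int(d))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    res = _sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(res.pvalue)


def binomial_zero_probability(n: int, q: float) -> float:
    """Probability of zero successes in ``n`` trials with success prob ``q``."""
    if n < 0:
        raise StatsError("n must be >= 0")
    if not 0.0 <= q <= 1.0:
        raise StatsError("q must be in [0, 1]")
    return float((1.0 - q) ** n)


def _permutation_p_unpaired(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    na = a.size
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:na].mean() - pooled[na:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _permutation_p_paired(
    diff: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    observed = abs(diff.mean())
    hits = 0
    for _ in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=diff.size)
        if abs((diff * signs).mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def compare_tract_lengths(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: Literal["unpaired", "paired"] = "unpaired",
    method: Literal["t", "permutation"] = "t",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided p-value comparing two sets of tract-length estimates.

    ``unpaired`` uses Welch's unequal-variance t test (independent tract
    sets, e.g. CO vs NCO); ``paired`` a paired t test (e.g. short vs long
    halves of the same trans tracts).  ``method='permutation'`` replaces the
    t reference with a seeded label-shuffle (unpaired) or sign-flip (paired)
    null with ``n_perm`` resamples.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least two values")
    if mode == "paired" and a.size != b.size:
        raise StatsError("paired mode requires equal-length groups")
    if method == "t":
        if mode == "unpaired":
            if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                return 1.0
            return float(_sps.ttest_ind(a, b, equal_var=False).pvalue)
        diff = a - b
        if np.allclose(diff, 0):
            return 1.0
        return float(_sps.ttest_rel(a, b).pvalue)
    if method == "permutation":
        if n_perm < 1:
            raise StatsError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        if mode == "unpaired":
            return float(_permutation_p_unpaired(a.copy(), b.copy(), n_perm, rng))
        return float(_permutation_p_paired(a - b, n_perm, rng))
    raise StatsError(f"unknown method {method!r}")
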