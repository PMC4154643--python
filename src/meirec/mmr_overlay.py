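"""Mismatch-repair overlays applied to simulated recombinant duplexes.

Two pathways act on heteroduplex DNA:

* **Canonical (long-patch) MMR** is nick-directed: for each contiguous hDNA
  region, the nicked strand is excised and resynthesized from the other
  strand across the whole region, so every mismatch in the region is
  repaired in the same direction.  Products without nicks (dHJ dissolution)
  escape canonical MMR entirely.
* **Short-patch MMR** is NER-dependent: each mismatch is independently
  recognized with probability ``repair_prob`` and repaired by excising a
  short patch extending 22-24 nt 5' and 5-6 nt 3' of the lesion on one
  strand (chosen by ``strand_bias``).  Mismatches close enough to sit in one
  excision patch are co-repaired; distant mismatches are repaired
  independently, producing the patchy tracts seen when canonical MMR is
  absent.

Genotypes map onto pathway availability: wild type runs canonical MMR first
and short-patch on any leftovers; an *Msh6* mutant has short-patch only; an
*Xpc*; *Msh6* double mutant has neither (up to an optional residual-repair
probability, default 0), leaving hDNA intact.

Whether a repaired site ends up converted or restored is an emergent
consequence of which strand was excised, never a separate parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .marker_map import MarkerMap
from .recomb_sim import (
    RecombinantDuplex,
    copy_interval_from,
    hdna_intervals,
)

__all__ = [
    "ShortPatchParams",
    "MMRGenotype",
    "GENOTYPES",
    "apply_canonical_mmr",
    "apply_short_patch_mmr",
    "apply_genotype",
]

MMRGenotype = Literal["wild_type", "Msh6", "Xpc_Msh6"]
GENOTYPES = ("wild_type", "Msh6", "Xpc_Msh6")


@dataclass(frozen=True)
class ShortPatchParams:
    """NER excision-window geometry and per-mismatch repair probability.

    Window extents are drawn uniformly per repair event from the given
    choices (nt 5' and 3' of the lesion on the excised strand).  The default
    ``repair_prob`` 0.82 is the observed fraction of hDNA markers repaired
    when only short-patch MMR is active; ``strand_bias`` is the probability
    that the top strand is the excised one.
    """

    window_5p_choices: tuple[int, ...] = (22, 23, 24)
    window_3p_choices: tuple[int, ...] = (5, 6)
    repair_prob: float = 0.82
    strand_bias: float = 0.5

    def __post_init__(self) -> None:
        if not all(22 <= w <= 24 for w in self.window_5p_choices):
            raise ValueError("5' window choices outside 22..24 nt")
        if not all(5 <= w <= 6 for w in self.window_3p_choices):
            raise ValueError("3' window choices outside 5..6 nt")
        if not 0.0 <= self.repair_prob <= 1.0:
            raise ValueError("repair_prob outside [0, 1]")
        if not 0.0 <= self.strand_bias <= 1.0:
            raise ValueError("strand_bias outside [0, 1]")

    @property
    def max_copatch_span(self) -> int:
        return max(self.window_5p_choices) + max(self.window_3p_choices)


def _marker_is_het(duplex: RecombinantDuplex, pos: int) -> bool:
    return duplex.parent_at(0, pos) != duplex.parent_at(1, pos)


def apply_canonical_mmr(
    duplex: RecombinantDuplex, rng: np.random.Generator
) -> RecombinantDuplex:
    """Nick-directed long-patch repair of every nick-associated hDNA region.

    The strand holding the nearest nick is rewritten to the other strand's
    parental origin across the whole region (ties between strands broken at
    random).  A chromatid with no nicks at all is returned unchanged.
    """
    nicks = duplex.nicks
    if not nicks[0] and not nicks[1]:
        return duplex
    top, bottom = duplex.strands
    for start, end in hdna_intervals(duplex):
        dists = []
        for si in (0, 1):
            for n in nicks[si]:
                d = 0 if start <= n <= end else min(abs(n - start), abs(n - end))
                dists.append((d, si))
        best = min(d for d, _ in dists)
        strands_at_best = sorted({si for d, si in dists if d == best})
        if len(strands_at_best) == 2:
            excised = int(rng.integers(0, 2))
        else:
            excised = strands_at_best[0]
        if excised == 0:
            top = copy_interval_from(top, bottom, start, end)
        else:
            bottom = copy_interval_from(bottom, top, start, end)
    return duplex.with_strands(top, bottom)


def apply_short_patch_mmr(
    duplex: RecombinantDuplex,
    mmap: MarkerMap,
    params: ShortPatchParams,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    """Independent short-patch repair of mismatched markers.

    Mismatched markers are visited in random order; each still-heteroduplex
    marker triggers an excision event with probability ``repair_prob``.  The
    patch covers the triggering lesion together with any still-heteroduplex
    markers within one patch span (w5 + w3 nt, 27-30 bp) of it -- nearby
    mismatches form a single helix distortion and are excised as one lesion
    cluster -- plus the w5/w3 margins in the excised strand's 5'->3' frame
    (margins flip for the bottom strand).  The excised interval is rewritten
    from the template strand, so all markers inside one patch are repaired
    co-directionally, while markers farther apart than a patch span are
    repaired independently.
    """
    working = duplex
    markers = [m for m in mmap.markers if _marker_is_het(working, m.position)]
    if not markers:
        return working
    order = rng.permutation(len(markers))
    top, bottom = working.strands
    current = working
    for idx in order:
        m = markers[int(idx)]
        if not _marker_is_het(current, m.position):
            continue
        if rng.random() >= params.repair_prob:
            continue
        excise_top = rng.random() < params.strand_bias
        w5 = int(rng.choice(params.window_5p_choices))
        w3 = int(rng.choice(params.window_3p_choices))
        span = w5 + w3
        cluster = [
            c
            for c in markers
            if abs(c.position - m.position) <= span and _marker_is_het(current, c.position)
        ]
        lo = min(c.position for c in cluster)
        hi = max(c.position + c.footprint - 1 for c in cluster)
        if excise_top:
            start, end = lo - w5, hi + w3 + 1
            new_top = copy_interval_from(current.top, current.bottom, start, end)
            current = current.with_strands(new_top, current.bottom)
        else:
            start, end = lo - w3, hi + w5 + 1
            new_bottom = copy_interval_from(current.bottom, current.top, start, end)
            current = current.with_strands(current.top, new_bottom)
    return current


def apply_genotype(
    duplex: RecombinantDuplex,
    genotype: MMRGenotype,
    mmap: MarkerMap,
    params: ShortPatchParams,
    rng: np.random.Generator,
    residual_repair_prob: float = 0.0,
) -> RecombinantDuplex:
    """Apply the repair pathways available under ``genotype``."""
    if genotype == "wild_type":
        repaired = apply_canonical_mmr(duplex, rng)
        return apply_short_patch_mmr(repaired, mmap, params, rng)
    if genotype == "Msh6":
        return apply_short_patch_mmr(duplex, mmap, params, rng)
    if genotype == "Xpc_Msh6":
        if residual_repair_prob <= 0.0:
            return duplex
        residual = ShortPatchParams(
            window_5p_choices=params.window_5p_choices,
            window_3p_choices=params.window_3p_choices,
            repair_prob=residual_repair_prob,
            strand_bias=params.strand_bias,
        )
        return apply_short_patch_mmr(duplex, mmap, residual, rng)
    raise ValueError(f"unknown genotype {genotype!r}")
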