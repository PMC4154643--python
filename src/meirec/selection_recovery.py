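"""Purine selection of ry+ recombinants and the sequencing-level observation.

The assay recovers recombinants between two loss-of-function point mutations
carried on opposite parental chromosomes (the map's two selection sites).
Dietary purine kills larvae without a functional copy of the gene.  Because
the gene product acts non-cell-autonomously, a larva survives if *any*
single strand of the recovered chromatid is wild type at both selection
sites: after replication, heteroduplex positions segregate into different
cell lineages, and a lineage descended from a fully wild-type strand rescues
the whole animal (hDNA spanning a mutant site gives a surviving mosaic).

Sequencing is modeled as error-free; coverage gaps enter only through an
explicit marker mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .marker_map import MarkerMap
from .recomb_sim import Parent, RecombinantDuplex

__all__ = [
    "ObservedRecombinant",
    "wildtype_parent_at_sites",
    "survives_purine",
    "observe_recombinant",
    "write_observed_tsv",
    "read_observed_tsv",
]


@dataclass(frozen=True)
class ObservedRecombinant:
    """Per-strand parental allele calls at each covered marker.

    ``calls`` maps marker position -> (top-strand parent, bottom-strand
    parent), ordered by position.
    """

    calls: tuple[tuple[int, Parent, Parent], ...]
    event_id: str = "event"
    survived: bool | None = None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.calls)

    def call_at(self, position: int) -> tuple[Parent, Parent]:
        for p, t, b in self.calls:
            if p == position:
                return (t, b)
        raise KeyError(position)


def wildtype_parent_at_sites(
    mmap: MarkerMap, ry531_parent: Parent = "P1"
) -> dict[int, Parent]:
    """Which parent carries the functional allele at each selection site.

    The parent carrying the downstream mutation (ry531, at the larger
    coordinate) is wild type at the upstream site and vice versa.
    """
    s_lo, s_hi = sorted(mmap.selection_sites)
    other: Parent = "P2" if ry531_parent == "P1" else "P1"
    return {s_lo: ry531_parent, s_hi: other}


def survives_purine(
    duplex: RecombinantDuplex,
    mmap: MarkerMap,
    ry531_parent: Parent = "P1",
) -> bool:
    """True iff some single strand is wild type at both selection sites."""
    wt = wildtype_parent_at_sites(mmap, ry531_parent)
    for si in (0, 1):
        if all(duplex.parent_at(si, site) == parent for site, parent in wt.items()):
            return True
    return False


def observe_recombinant(
    duplex: RecombinantDuplex,
    mmap: MarkerMap,
    coverage_mask: Iterable[int] = (),
    event_id: str = "event",
    survived: bool | None = None,
) -> ObservedRecombinant:
    """Noiseless per-strand calls at every marker not hidden by the mask."""
    masked = set(coverage_mask)
    calls = tuple(
        (m.position, duplex.parent_at(0, m.position), duplex.parent_at(1, m.position))
        for m in mmap.markers
        if m.position not in masked
    )
    return ObservedRecombinant(calls=calls, event_id=event_id, survived=survived)


def write_observed_tsv(
    observations: Iterable[ObservedRecombinant], path: str | Path
) -> None:
    rows = [
        (o.event_id, pos, top, bottom, o.survived)
        for o in observations
        for pos, top, bottom in o.calls
    ]
    df = pd.DataFrame(rows, columns=["event_id", "position", "top", "bottom", "survived"])
    df.to_csv(path, sep="\t", index=False)


def read_observed_tsv(path: str | Path) -> list[ObservedRecombinant]:
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "position", "top", "bottom"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observed table missing column(s): {sorted(missing)}")
    out = []
    for eid, grp in df.groupby("event_id", sort=False):
        grp = grp.sort_values("position")
        calls = tuple(
            (int(r.position), str(r.top), str(r.bottom)) for r in grp.itertuples()
        )
        survived = None
        if "survived" in grp.columns and grp["survived"].notna().all():
            survived = bool(grp["survived"].iloc[0])
        out.append(ObservedRecombinant(calls=calls, event_id=str(eid), survived=survived))
    return out
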