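"""Polymorphic marker maps for a selected recombination locus.

A recombination assay locus (modeled on the *Drosophila* *rosy* gene) is
described by an ordered set of polymorphic markers -- SNPs and small indels
that distinguish the two parental chromosomes -- plus two *selection sites*:
the positions of the mutant alleles used to select wild-type recombinants.
Coordinates are integer base pairs relative to an anchor (an EcoRI site for
the default map) and may be negative.  Point positions are inclusive;
intervals elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Marker",
    "MarkerMap",
    "MarkerTableError",
    "MarkerValidationError",
    "load_marker_table",
    "write_marker_table",
    "adjacent_distances",
    "rosy_marker_map",
]


class MarkerTableError(ValueError):
    """Malformed marker table (missing columns, unparseable fields)."""


class MarkerValidationError(ValueError):
    """Structurally valid table that violates map invariants."""


@dataclass(frozen=True, order=True)
class Marker:
    """One polymorphic site.

    ``footprint`` is the bp extent occupied by the marker: 1 for SNPs, the
    indel length otherwise.  An indel occupies ``[position, position +
    footprint)``; distances between markers are measured between ``position``
    fields.
    """

    position: int
    kind: str = field(compare=False, default="snp")
    footprint: int = field(compare=False, default=1)
    allele_p1: str = field(compare=False, default="A")
    allele_p2: str = field(compare=False, default="G")

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "indel"):
            raise MarkerValidationError(f"unknown marker kind {self.kind!r}")
        if self.footprint < 1:
            raise MarkerValidationError("footprint must be >= 1")
        if (self.footprint == 1) != (self.kind == "snp"):
            raise MarkerValidationError(
                f"footprint {self.footprint} inconsistent with kind {self.kind!r} "
                f"at position {self.position}"
            )
        if self.allele_p1 == self.allele_p2:
            raise MarkerValidationError(
                f"marker at {self.position} has identical parental alleles"
            )


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker list plus the two selection-site positions.

    ``locus_bounds`` is a closed interval containing every marker and both
    selection sites; the simulator treats it as the modeled extent of the
    locus.
    """

    markers: tuple[Marker, ...]
    selection_sites: tuple[int, int] = (-468, 3312)
    locus_bounds: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        sites = tuple(int(s) for s in self.selection_sites)
        if len(sites) != 2:
            raise MarkerValidationError("exactly two selection sites are required")
        object.__setattr__(self, "selection_sites", sites)
        pos = [m.position for m in markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise MarkerValidationError(
                "marker positions must be strictly increasing without duplicates"
            )
        if self.locus_bounds is None:
            span = pos + list(sites)
            fp = max([m.footprint for m in markers], default=1)
            object.__setattr__(
                self, "locus_bounds", (min(span) - 100, max(span) + fp + 100)
            )
        else:
            object.__setattr__(
                self, "locus_bounds", (int(self.locus_bounds[0]), int(self.locus_bounds[1]))
            )
        lo, hi = self.locus_bounds
        if lo >= hi:
            raise MarkerValidationError("locus_bounds must be a nonempty interval")
        for p in pos:
            if not lo <= p <= hi:
                raise MarkerValidationError(f"marker at {p} outside locus bounds {self.locus_bounds}")
        for s in sites:
            if not lo <= s <= hi:
                raise MarkerValidationError(
                    f"selection site {s} outside locus bounds {self.locus_bounds}"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.markers)

    def marker_at(self, position: int) -> Marker:
        for m in self.markers:
            if m.position == position:
                return m
        raise KeyError(position)

    def with_bounds(self, bounds: tuple[int, int]) -> "MarkerMap":
        return replace(self, locus_bounds=bounds)


_COLUMNS = ["position", "kind", "footprint", "allele_p1", "allele_p2", "is_selection_site"]


def load_marker_table(path: str | Path) -> MarkerMap:
    """Read a marker map from a tab-separated table.

    Expected columns: position, kind, footprint, allele_p1, allele_p2,
    is_selection_site.  Rows flagged as selection sites define
    ``selection_sites`` and are not included in the marker list.  An optional
    ``# locus_bounds=lo,hi`` comment line pins the locus bounds.
    """
    path = Path(path)
    bounds = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "locus_bounds=" in line:
                lo, hi = line.split("locus_bounds=")[1].strip().split(",")
                bounds = (int(lo), int(hi))
            if not line.startswith("#"):
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MarkerTableError(f"cannot parse marker table {path}: {exc}") from exc
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise MarkerTableError(f"marker table missing column(s): {', '.join(missing)}")
    if "is_selection_site" not in df.columns:
        df["is_selection_site"] = False
    sel = df[df["is_selection_site"].astype(bool)]
    body = df[~df["is_selection_site"].astype(bool)]
    if len(sel) != 2:
        raise MarkerValidationError(
            f"expected exactly 2 selection-site rows, found {len(sel)}"
        )
    positions = body["position"].astype(int).tolist()
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise MarkerValidationError("marker table positions unsorted or duplicated")
    markers = tuple(
        Marker(
            position=int(r.position),
            kind=str(r.kind),
            footprint=int(r.footprint),
            allele_p1=str(r.allele_p1),
            allele_p2=str(r.allele_p2),
        )
        for r in body.itertuples()
    )
    sites = tuple(int(p) for p in sel["position"])
    return MarkerMap(markers=markers, selection_sites=sites, locus_bounds=bounds)


def write_marker_table(mmap: MarkerMap, path: str | Path) -> None:
    """Write a MarkerMap as TSV; load_marker_table round-trips it exactly."""
    rows = []
    for m in mmap.markers:
        rows.append((m.position, m.kind, m.footprint, m.allele_p1, m.allele_p2, False))
    for s in mmap.selection_sites:
        rows.append((s, "snp", 1, ".", "..", True))
    rows.sort(key=lambda r: (r[0], not r[5]))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        lo, hi = mmap.locus_bounds
        fh.write(f"# locus_bounds={lo},{hi}\n")
        df.to_csv(fh, sep="\t", index=False)


def adjacent_distances(mmap: MarkerMap) -> list[tuple[tuple[Marker, Marker], int]]:
    """Distances between consecutive markers, one entry per adjacent pair."""
    out = []
    for a, b in zip(mmap.markers, mmap.markers[1:]):
        out.append(((a, b), b.position - a.position))
    return out


def rosy_marker_map() -> MarkerMap:
    """Synthetic default map emulating the *rosy* assay locus.

    Positions are relative to the anchor restriction site; the two selection
    sites sit at -468 and 3312 (~3.8 kb apart).  The marker spacing mirrors
    the features described for the real locus -- nearest SNPs 150-200 bp on
    either side of the 3312 site, nearest SNP 400 bp downstream of the -468
    site with small indels upstream of it, and several marker pairs closer
    than 21 bp -- but the exact published polymorphism list is not reproduced.
    """
    snp = lambda pos, a, b: Marker(pos, "snp", 1, a, b)
    indel = lambda pos, fp, a, b: Marker(pos, "indel", fp, a, b)
    markers = (
        snp(-1400, "A", "G"),
        snp(-1100, "T", "C"),
        indel(-850, 3, "ACT", "A"),
        indel(-690, 2, "TG", "T"),
        snp(-68, "C", "T"),
        snp(230, "G", "A"),
        snp(612, "A", "C"),
        snp(626, "G", "T"),
        snp(955, "T", "A"),
        snp(1240, "C", "G"),
        snp(1705, "A", "G"),
        snp(1717, "C", "A"),
        snp(2040, "T", "C"),
        snp(2281, "G", "A"),
        snp(2299, "T", "G"),
        snp(2600, "A", "T"),
        snp(2905, "C", "T"),
        snp(3137, "G", "C"),
        snp(3490, "A", "G"),
        snp(3770, "T", "C"),
        snp(4080, "C", "A"),
        snp(4333, "G", "T"),
        snp(4600, "A", "C"),
    )
    return MarkerMap(markers=markers, selection_sites=(-468, 3312), locus_bounds=(-1500, 4700))
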