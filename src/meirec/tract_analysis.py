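"""Reconstruction and classification of hDNA/conversion tracts.

Works purely from the sequencing-level view (per-strand parental calls at
each marker); the DSB position is never assumed.  Each marker is homoduplex
for one parent or heteroduplex; a *tract* is a maximal run of markers that
differ from the flanking (background) parental phase.  Tracts carry
inclusion bounds (outermost included markers), exclusion bounds (nearest
non-included markers), display bounds at the halfway points between the
two, and labels: crossover context, cis/trans strand phase, patchiness, and
per-marker repair outcomes (converted / restored / unrepaired).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .marker_map import Marker, MarkerMap
from .selection_recovery import ObservedRecombinant
from .recomb_sim import Parent

__all__ = [
    "MarkerState",
    "TractCall",
    "PairClass",
    "TractAnalysisError",
    "call_marker_states",
    "classify_crossover",
    "find_hdna_tracts",
    "score_marker_outcomes",
    "classify_cis_trans",
    "is_patchy",
    "co_repair_pairs",
    "classify_pair",
    "bin_pairs_by_distance",
    "mismatch_spectrum",
    "analyze_observed",
    "EventAnalysis",
]

MarkerState = Literal["hom_P1", "hom_P2", "het"]
Outcome = Literal["converted", "restored", "unrepaired"]


class TractAnalysisError(ValueError):
    pass


def _hom(parent: Parent) -> MarkerState:
    return "hom_P1" if parent == "P1" else "hom_P2"


def _hom_parent(state: MarkerState) -> Parent:
    if state == "hom_P1":
        return "P1"
    if state == "hom_P2":
        return "P2"
    raise TractAnalysisError("heteroduplex state has no single parent")


def call_marker_states(obs: ObservedRecombinant) -> dict[int, MarkerState]:
    """Position -> state; heteroduplex iff the two strand calls differ."""
    out: dict[int, MarkerState] = {}
    for pos, top, bottom in obs.calls:
        out[pos] = "het" if top != bottom else _hom(top)
    return out


def classify_crossover(
    states: dict[int, MarkerState], mmap: MarkerMap | None = None
) -> Literal["CO", "NCO"]:
    """CO iff the two outermost covered markers are homoduplex for
    different parents; heteroduplex flanks cannot be classified."""
    if not states:
        raise TractAnalysisError("no marker states to classify")
    positions = sorted(states)
    left, right = states[positions[0]], states[positions[-1]]
    if left == "het" or right == "het":
        raise TractAnalysisError("outermost marker is heteroduplex; flanks must resolve")
    return "CO" if left != right else "NCO"


@dataclass
class TractCall:
    """One maximal heteroduplex/conversion run.

    ``span_min`` is the bp distance between the outermost included marker
    positions (the marker footprint for single-marker tracts); ``span_max``
    the distance between the nearest excluded flanking markers (locus/
    coverage edges when absent); display bounds use the halfway-point
    convention between last included and first excluded marker.
    """

    markers: tuple[Marker, ...]
    states: tuple[MarkerState, ...]
    left_background: Parent
    right_background: Parent
    left_excluded_pos: float
    right_excluded_pos: float
    co_context: Literal["CO", "NCO", "unknown"] = "unknown"
    outcomes: tuple[Outcome, ...] | None = None
    cis_trans: Literal["cis", "trans", "undetermined"] | None = None
    patchy: bool | None = None
    donor_runs: tuple[tuple[Marker, ...], ...] | None = None
    donor_run_strands: tuple[str, ...] | None = None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.markers)

    @property
    def span_min(self) -> float:
        if len(self.markers) == 1:
            return float(self.markers[0].footprint)
        return float(self.markers[-1].position - self.markers[0].position)

    @property
    def span_max(self) -> float:
        return float(self.right_excluded_pos - self.left_excluded_pos)

    @property
    def display_bounds(self) -> tuple[float, float]:
        return (
            (self.left_excluded_pos + self.markers[0].position) / 2.0,
            (self.markers[-1].position + self.right_excluded_pos) / 2.0,
        )


def find_hdna_tracts(
    states: dict[int, MarkerState], mmap: MarkerMap
) -> list[TractCall]:
    """Maximal runs of non-background markers bounded by background markers.

    Background phase comes from the outermost covered markers (each side
    scored against its own flank, which differ for crossovers).  A single
    background-homoduplex marker flanked by non-background markers on both
    sides stays inside the tract (an internal restoration); two or more
    consecutive background markers split tracts.
    """
    positions = sorted(states)
    if len(positions) < 2:
        return []
    covered = [m for m in mmap.markers if m.position in states]
    if len(covered) != len(positions):
        raise TractAnalysisError("observed positions missing from marker map")
    left_state, right_state = states[positions[0]], states[positions[-1]]
    if left_state == "het" or right_state == "het":
        raise TractAnalysisError("outermost marker is heteroduplex; flanks must resolve")
    left_bg, right_bg = _hom_parent(left_state), _hom_parent(right_state)
    n = len(covered)
    li = next(
        (i for i in range(n) if states[covered[i].position] != _hom(left_bg)), None
    )
    ri = next(
        (i for i in range(n - 1, -1, -1) if states[covered[i].position] != _hom(right_bg)),
        None,
    )
    if li is None or ri is None or li > ri:
        return []
    lo_bound, hi_bound = mmap.locus_bounds

    def make_tract(i0: int, i1: int) -> TractCall:
        ms = tuple(covered[i0 : i1 + 1])
        left_excl = covered[i0 - 1].position if i0 > 0 else float(lo_bound)
        right_excl = covered[i1 + 1].position if i1 < n - 1 else float(hi_bound)
        return TractCall(
            markers=ms,
            states=tuple(states[m.position] for m in ms),
            left_background=left_bg,
            right_background=right_bg,
            left_excluded_pos=float(left_excl),
            right_excluded_pos=float(right_excl),
            co_context="CO" if left_bg != right_bg else "NCO",
        )

    if left_bg != right_bg:
        # crossover: the region between the two flank scans is one tract
        return [make_tract(li, ri)]
    bg_state = _hom(left_bg)
    nonbg = [i for i in range(li, ri + 1) if states[covered[i].position] != bg_state]
    tracts = []
    start = prev = nonbg[0]
    for i in nonbg[1:]:
        if i - prev > 2:  # >= 2 consecutive background markers between runs
            tracts.append(make_tract(start, prev))
            start = i
        prev = i
    tracts.append(make_tract(start, prev))
    return tracts


def _background_for(tract: TractCall, marker: Marker) -> Parent:
    """Background parent for a marker: its own side's flank (nearer flank for
    crossovers, ties to the left)."""
    if tract.left_background == tract.right_background:
        return tract.left_background
    d_left = marker.position - tract.left_excluded_pos
    d_right = tract.right_excluded_pos - marker.position
    return tract.left_background if d_left <= d_right else tract.right_background


def score_marker_outcomes(
    tract: TractCall,
    states: dict[int, MarkerState] | None = None,
    background: Parent | None = None,
) -> tuple[Outcome, ...]:
    """Per-marker repair outcome relative to the background phase.

    Heteroduplex -> unrepaired; homoduplex of the non-background parent ->
    converted; homoduplex of the background parent inside the tract ->
    restored.
    """
    out: list[Outcome] = []
    for m, s in zip(tract.markers, tract.states):
        bg = background if background is not None else _background_for(tract, m)
        if s == "het":
            out.append("unrepaired")
        elif _hom_parent(s) != bg:
            out.append("converted")
        else:
            out.append("restored")
    tract.outcomes = tuple(out)
    return tract.outcomes


def classify_cis_trans(
    tract: TractCall, obs: ObservedRecombinant
) -> Literal["cis", "trans", "undetermined"]:
    """Strand-phase arrangement of the unrepaired (heteroduplex) markers.

    cis: the donor allele sits on one strand at every heteroduplex marker;
    trans: adjacent runs with the donor allele on opposite strands (the
    signature of both break ends having been extended by synthesis);
    undetermined: fewer than two heteroduplex markers.
    """
    het = [
        (m, obs.call_at(m.position))
        for m, s in zip(tract.markers, tract.states)
        if s == "het"
    ]
    if len(het) < 2:
        tract.cis_trans = "undetermined"
        tract.donor_runs = tuple((m,) for m, _ in het)
        tract.donor_run_strands = None
        return tract.cis_trans
    # run structure is invariant to which parent is used as reference, so a
    # fixed reference (the parent opposite the left flank) works for both
    # NCO and CO tracts without assuming a DSB position
    donor: Parent = "P2" if tract.left_background == "P1" else "P1"
    strands = []
    for m, (top, _bottom) in het:
        strands.append((m, "top" if top == donor else "bottom"))
    runs: list[list[Marker]] = [[strands[0][0]]]
    run_strands = [strands[0][1]]
    for m, st in strands[1:]:
        if st == run_strands[-1]:
            runs[-1].append(m)
        else:
            runs.append([m])
            run_strands.append(st)
    tract.donor_runs = tuple(tuple(r) for r in runs)
    tract.donor_run_strands = tuple(run_strands)
    tract.cis_trans = "trans" if len(runs) >= 2 else "cis"
    return tract.cis_trans


def is_patchy(outcomes: Sequence[Outcome]) -> bool:
    """A tract mixing repaired and unrepaired markers, or conversions with
    restorations."""
    s = set(outcomes)
    repaired = {"converted", "restored"} & s
    return bool(repaired and "unrepaired" in s) or len(repaired) == 2


@dataclass(frozen=True)
class PairClass:
    distance: int
    label: Literal["co_repaired", "not_co_repaired", "excluded"]


def classify_pair(a: Outcome, b: Outcome) -> str:
    """Adjacent-marker pair rule: co-repaired when both converted or both
    restored; not co-repaired when repaired discordantly or only one
    repaired; pairs with both unrepaired are not counted."""
    if a == "unrepaired" and b == "unrepaired":
        return "excluded"
    if a == b:
        return "co_repaired"
    return "not_co_repaired"


def co_repair_pairs(tract: TractCall) -> list[PairClass]:
    """Classify every adjacent marker pair within a tract."""
    if tract.outcomes is None:
        score_marker_outcomes(tract)
    out = []
    for (m1, o1), (m2, o2) in zip(
        zip(tract.markers, tract.outcomes), zip(tract.markers[1:], tract.outcomes[1:])
    ):
        out.append(PairClass(m2.position - m1.position, classify_pair(o1, o2)))
    return out


def bin_pairs_by_distance(
    pairs: Iterable[PairClass], bin_edges: Sequence[float] = (21,)
) -> pd.DataFrame:
    """Per-distance-bin co-repair counts and percentages (excluded pairs dropped).

    ``bin_edges`` are interior edges; the default single edge 21 bp gives the
    classes < 21 bp (within NER-patch range) and >= 21 bp.
    """
    edges = [float("-inf")] + sorted(float(e) for e in bin_edges) + [float("inf")]
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        if lo == float("-inf"):
            labels.append(f"<{hi:g}")
        elif hi == float("inf"):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"[{lo:g},{hi:g})")
    counts = {lab: {"co_repaired": 0, "not_co_repaired": 0} for lab in labels}
    for p in pairs:
        if p.label == "excluded":
            continue
        for (lo, hi), lab in zip(zip(edges, edges[1:]), labels):
            if lo <= p.distance < hi:
                counts[lab][p.label] += 1
                break
    rows = []
    for lab in labels:
        co = counts[lab]["co_repaired"]
        nc = counts[lab]["not_co_repaired"]
        total = co + nc
        pct = 100.0 * co / total if total else float("nan")
        rows.append((lab, co, nc, total, pct))
    return pd.DataFrame(
        rows, columns=["bin", "co_repaired", "not_co_repaired", "counted", "pct_co_repaired"]
    )


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT.get(c.upper(), "N") for c in reversed(s))


def mismatch_type(marker: Marker, top_parent: Parent | None = None) -> str:
    """Mismatch formed at a heteroduplex marker.

    The physical mismatch pairs one allele's base against the complement of
    the other's, so an A/G SNP forms either A:C or G:T depending on which
    strand carries which allele.  ``top_parent`` (the parent whose allele is
    on the top strand) selects the orientation; when unknown both
    possibilities are reported as an ambiguous pair.  Indels form a loop
    whose size is the marker footprint.
    """
    if marker.kind == "indel":
        return f"loop{marker.footprint}"
    a, b = marker.allele_p1.upper(), marker.allele_p2.upper()
    m1 = ":".join(sorted((a, _COMPLEMENT.get(b, "N"))))  # P1 allele on top
    m2 = ":".join(sorted((b, _COMPLEMENT.get(a, "N"))))  # P2 allele on top
    if top_parent is None:
        return "|".join(sorted({m1, m2}))
    return m1 if top_parent == "P1" else m2


def mismatch_spectrum(
    tracts: Iterable[TractCall], mmap: MarkerMap
) -> pd.DataFrame:
    """Repaired/unrepaired tallies per mismatch type across tracts.

    The mismatch orientation can be inferred only for markers in trans
    tracts (donor strand known per run); elsewhere the ambiguous pair of
    possible mismatches is reported.
    """
    tally: dict[str, dict[str, int]] = {}
    for t in tracts:
        if t.outcomes is None:
            score_marker_outcomes(t)
        donor_strand_at: dict[int, str] = {}
        if t.cis_trans == "trans" and t.donor_runs and t.donor_run_strands:
            for run, strand in zip(t.donor_runs, t.donor_run_strands):
                for m in run:
                    donor_strand_at[m.position] = strand
        for m, s, o in zip(t.markers, t.states, t.outcomes):
            top_parent: Parent | None = None
            if s == "het" and m.position in donor_strand_at:
                donor: Parent = "P2" if _background_for(t, m) == "P1" else "P1"
                recipient: Parent = "P1" if donor == "P2" else "P2"
                top_parent = donor if donor_strand_at[m.position] == "top" else recipient
            key = mismatch_type(m, top_parent)
            rec = tally.setdefault(key, {"repaired": 0, "unrepaired": 0})
            rec["repaired" if o in ("converted", "restored") else "unrepaired"] += 1
    rows = [
        (k, v["repaired"], v["unrepaired"], v["repaired"] + v["unrepaired"])
        for k, v in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["mismatch", "repaired", "unrepaired", "total"])


@dataclass
class EventAnalysis:
    event_id: str
    co_label: Literal["CO", "NCO", "undetermined"]
    tracts: list[TractCall]
    pairs: list[PairClass]


def analyze_observed(obs: ObservedRecombinant, mmap: MarkerMap) -> EventAnalysis:
    """Full per-event analysis: states, CO/NCO, tracts, labels, pair classes."""
    states = call_marker_states(obs)
    try:
        label = classify_crossover(states, mmap)
    except TractAnalysisError:
        label = "undetermined"
    if label == "undetermined":
        return EventAnalysis(obs.event_id, label, [], [])
    tracts = find_hdna_tracts(states, mmap)
    pairs: list[PairClass] = []
    for t in tracts:
        score_marker_outcomes(t)
        classify_cis_trans(t, obs)
        t.patchy = is_patchy(t.outcomes) if len(t.outcomes) >= 2 else False
        pairs.extend(co_repair_pairs(t))
    return EventAnalysis(obs.event_id, label, tracts, pairs)
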