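"""Strand-level simulator of meiotic DSB-repair products.

Each simulated product is the single recovered recombinant chromatid: a DNA
duplex whose two strands (top = 5'->3' left-to-right, bottom = 5'->3'
right-to-left) are mosaics of parental-origin segments.  A double-strand
break on the recipient chromatid (default parent P1) is repaired using the
homologous donor chromatid (P2) under one of several mechanistic models:

* ``sdsa`` -- one-ended synthesis-dependent strand annealing.  The extended
  invading strand re-anneals to the other break end, leaving a single
  heteroduplex (hDNA) tract on one side of the break, with nicks.  NCO only.
* ``two_end_engagement`` -- both break ends engage the same donor chromatid
  and are extended by synthesis; junctions stay unligated.  Helicase
  disassembly yields an NCO with *trans* hDNA (donor-derived sequence on
  opposite strands on the two sides of the break) and nicks; nuclease
  cleavage across from the existing nicks yields a CO with a single hDNA
  tract spanning the break and no full-conversion tract.
* ``two_ended_sdsa`` -- observationally equivalent to the NCO branch of
  two-end engagement (trans hDNA, nicks present); kept as a named alias
  because the two mechanisms cannot be distinguished from product structure.
* ``dhj_resolution`` -- a ligated double Holliday junction cleaved into a CO.
  One cleavage orientation gives a single hDNA tract; the other puts a tract
  of MMR-independent full gene conversion adjacent to the hDNA.
* ``dhj_dissolution`` -- helicase/topoisomerase unwinding of a ligated dHJ:
  an NCO with trans hDNA and *no* nicks.
* ``gap_repair`` -- the break is widened to a double-strand gap before
  repair; synthesis across the gap on both strands gives a full-conversion
  tract containing no hDNA.

Resection and synthesis tract lengths are geometric (a per-bp continuation
probability), independently per side.  Tract extents are clipped to the open
interval between the outermost markers so that the flanking CO/NCO
classification markers always resolve, as events must in the real assay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .marker_map import Marker, MarkerMap

__all__ = [
    "Parent",
    "Segment",
    "DSBEvent",
    "Truth",
    "RecombinantDuplex",
    "ModelConfig",
    "SimulationError",
    "MODEL_NAMES",
    "other_parent",
    "strand_parent_at",
    "hdna_intervals",
    "validate_duplex",
    "sample_dsb",
    "make_sdsa_nco",
    "make_two_ended_sdsa",
    "make_two_end_engagement",
    "make_dhj_resolution",
    "make_dhj_dissolution_nco",
    "make_gap_repair_nco",
    "simulate_meiosis",
    "duplex_segments_frame",
    "duplex_to_fasta",
]

Parent = Literal["P1", "P2"]
#: (start, end, parent) with a half-open [start, end) interval.
Segment = tuple[int, int, Parent]
Strand = tuple[Segment, ...]

MODEL_NAMES = (
    "sdsa",
    "two_ended_sdsa",
    "two_end_engagement",
    "dhj_resolution",
    "dhj_dissolution",
    "gap_repair",
)


class SimulationError(ValueError):
    pass


def other_parent(parent: Parent) -> Parent:
    return "P2" if parent == "P1" else "P1"


# ---------------------------------------------------------------------------
# strand bookkeeping


def _merge(segments: Iterable[Segment]) -> Strand:
    out: list[Segment] = []
    for a, b, p in segments:
        if b <= a:
            continue
        if out and out[-1][2] == p and out[-1][1] == a:
            out[-1] = (out[-1][0], b, p)
        else:
            out.append((a, b, p))
    return tuple(out)


def build_strand(
    bounds: tuple[int, int], base: Parent, pieces: Sequence[tuple[int, int, Parent]] = ()
) -> Strand:
    """A strand covering ``bounds`` with parent ``base`` except in ``pieces``."""
    lo, hi = bounds
    clipped = sorted(
        (max(lo, a), min(hi, b), p) for a, b, p in pieces if min(hi, b) > max(lo, a)
    )
    cur, out = lo, []
    for a, b, p in clipped:
        if a < cur:
            raise SimulationError("overlapping strand pieces")
        if a > cur:
            out.append((cur, a, base))
        out.append((a, b, p))
        cur = b
    if cur < hi:
        out.append((cur, hi, base))
    return _merge(out)


def strand_parent_at(strand: Strand, pos: int) -> Parent:
    for a, b, p in strand:
        if a <= pos < b:
            return p
    raise KeyError(f"position {pos} outside strand extent")


def copy_interval_from(strand: Strand, template: Strand, start: int, end: int) -> Strand:
    """Rewrite ``strand`` over [start, end) with the template strand's origins."""
    if end <= start:
        return strand
    out: list[Segment] = []
    for a, b, p in strand:
        if b <= start or a >= end:
            out.append((a, b, p))
        else:
            if a < start:
                out.append((a, start, p))
            if b > end:
                out.append((end, b, p))
    for a, b, p in template:
        a2, b2 = max(a, start), min(b, end)
        if b2 > a2:
            out.append((a2, b2, p))
    out.sort()
    return _merge(out)


@dataclass(frozen=True)
class DSBEvent:
    """A double-strand break with per-side resection and synthesis extents."""

    position: int
    resect_left: int = 0
    resect_right: int = 0
    synth_left: int = 0
    synth_right: int = 0

    def __post_init__(self) -> None:
        for name in ("resect_left", "resect_right", "synth_left", "synth_right"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Truth:
    """Ground-truth event metadata attached to a simulated product."""

    model: str
    dsb: DSBEvent
    label: Literal["CO", "NCO"]
    donor: Parent = "P2"
    detail: tuple[tuple[str, object], ...] = ()


@dataclass(frozen=True)
class RecombinantDuplex:
    """The recovered chromatid: two strands of parental-origin segments.

    Both strands tile ``bounds`` (half-open) without gaps or overlaps.
    ``nicks`` holds unligated backbone positions per strand (top, bottom).
    """

    strands: tuple[Strand, Strand]
    nicks: tuple[tuple[int, ...], tuple[int, ...]]
    bounds: tuple[int, int]
    truth: Truth | None = None

    @property
    def top(self) -> Strand:
        return self.strands[0]

    @property
    def bottom(self) -> Strand:
        return self.strands[1]

    def parent_at(self, strand_index: int, pos: int) -> Parent:
        return strand_parent_at(self.strands[strand_index], pos)

    def with_strands(self, top: Strand, bottom: Strand) -> "RecombinantDuplex":
        return dataclasses.replace(self, strands=(tuple(top), tuple(bottom)))


def validate_duplex(duplex: RecombinantDuplex) -> None:
    lo, hi = duplex.bounds
    for strand in duplex.strands:
        cur = lo
        for a, b, _ in strand:
            if a != cur or b <= a:
                raise SimulationError("strand does not tile locus bounds")
            cur = b
        if cur != hi:
            raise SimulationError("strand does not tile locus bounds")


def hdna_intervals(duplex: RecombinantDuplex) -> list[tuple[int, int]]:
    """Maximal intervals where the two strands have different parental origin."""
    points = sorted(
        {x for strand in duplex.strands for a, b, _ in strand for x in (a, b)}
    )
    out: list[list[int]] = []
    for a, b in zip(points, points[1:]):
        if duplex.parent_at(0, a) != duplex.parent_at(1, a):
            if out and out[-1][1] == a:
                out[-1][1] = b
            else:
                out.append([a, b])
    return [(a, b) for a, b in out]


# ---------------------------------------------------------------------------
# model configuration and DSB sampling


@dataclass(frozen=True)
class ModelConfig:
    """Mechanistic-model parameters.

    ``resect_ext_prob`` and ``synth_ext_prob`` are per-bp continuation
    probabilities of the geometric resection/synthesis length distributions
    (mean 1/(1-p)); the synthesis default 0.99717 puts the simulated hDNA
    tract-length scale (~353 bp mean) on the same per-base extension prior
    used by the tract-length estimator.  ``resolution_bias`` is the
    probability that dHJ cleavage takes the orientation yielding a single
    hDNA tract; ``engagement_co_prob`` the probability that a two-end
    engagement intermediate is nicked into a CO rather than disassembled.
    """

    model: str = "two_end_engagement"
    resect_ext_prob: float = 0.995
    synth_ext_prob: float = 0.99717
    resolution_bias: float = 0.5
    engagement_co_prob: float = 0.5
    recipient: Parent = "P1"
    seed: int | None = None
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in (
            "resect_ext_prob",
            "synth_ext_prob",
            "resolution_bias",
            "engagement_co_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.synth_ext_prob >= 1.0 or self.resect_ext_prob >= 1.0:
            raise SimulationError("extension probabilities must be < 1")
        if self.model not in MODEL_NAMES:
            raise SimulationError(f"unknown model {self.model!r}")
        if self.weights is not None:
            bad = set(self.weights) - set(MODEL_NAMES)
            if bad:
                raise SimulationError(f"unknown model(s) in weights: {sorted(bad)}")
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.weights.values()):
                raise SimulationError("model weights must be non-negative and sum to 1")

    def effective_weights(self) -> dict[str, float]:
        return dict(self.weights) if self.weights is not None else {self.model: 1.0}


def _geometric(p_ext: float, rng: np.random.Generator) -> int:
    """Length >= 1 with per-bp continuation probability ``p_ext``."""
    if p_ext <= 0.0:
        return 1
    return int(rng.geometric(1.0 - p_ext))


def sample_dsb(mmap: MarkerMap, config: ModelConfig, rng: np.random.Generator) -> DSBEvent:
    """Draw a DSB: position uniform over the locus, geometric side extents."""
    lo, hi = mmap.locus_bounds
    pos = int(rng.integers(lo, hi + 1))
    return DSBEvent(
        position=pos,
        resect_left=_geometric(config.resect_ext_prob, rng),
        resect_right=_geometric(config.resect_ext_prob, rng),
        synth_left=_geometric(config.synth_ext_prob, rng),
        synth_right=_geometric(config.synth_ext_prob, rng),
    )


# ---------------------------------------------------------------------------
# product constructors


def _tract_window(mmap: MarkerMap) -> tuple[int, int]:
    """Open interval between the outermost markers; switch points are clipped
    here so flanking markers always retain parental phase."""
    if mmap.markers:
        return (mmap.markers[0].position + 1, mmap.markers[-1].position)
    return mmap.locus_bounds


def _clip(v: int, window: tuple[int, int]) -> int:
    return min(max(v, window[0]), window[1])


def make_sdsa_nco(
    dsb: DSBEvent,
    donor: Parent,
    mmap: MarkerMap,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    """One-ended SDSA: NCO with a single hDNA tract on one side of the break."""
    recipient = other_parent(donor)
    w = _tract_window(mmap)
    x = _clip(dsb.position, w)
    invade_left = bool(rng.integers(0, 2))
    if invade_left:
        # left-end top strand invades; donor-templated synthesis to the right
        s_end = _clip(dsb.position + dsb.synth_right, w)
        top = build_strand(mmap.locus_bounds, recipient, [(x, s_end, donor)])
        bottom = build_strand(mmap.locus_bounds, recipient)
        nicks = ((s_end,), (_clip(dsb.position - dsb.resect_left, w),))
        side = "right"
    else:
        s_start = _clip(dsb.position - dsb.synth_left, w)
        top = build_strand(mmap.locus_bounds, recipient)
        bottom = build_strand(mmap.locus_bounds, recipient, [(s_start, x, donor)])
        nicks = ((_clip(dsb.position + dsb.resect_right, w),), (s_start,))
        side = "left"
    truth = Truth("sdsa", dsb, "NCO", donor, (("hdna_side", side),))
    return RecombinantDuplex((top, bottom), nicks, mmap.locus_bounds, truth)


def _trans_nco_strands(
    dsb: DSBEvent, donor: Parent, mmap: MarkerMap, rng: np.random.Generator
) -> tuple[Strand, Strand, int, int, bool]:
    """Donor-derived synthesis on opposite strands on the two sides of the DSB.

    Returns (top, bottom, left, right, top_has_right_side).
    """
    recipient = other_parent(donor)
    w = _tract_window(mmap)
    x = _clip(dsb.position, w)
    left = _clip(dsb.position - dsb.synth_left, w)
    right = _clip(dsb.position + dsb.synth_right, w)
    top_right = bool(rng.integers(0, 2))
    if top_right:
        top = build_strand(mmap.locus_bounds, recipient, [(x, right, donor)])
        bottom = build_strand(mmap.locus_bounds, recipient, [(left, x, donor)])
    else:
        top = build_strand(mmap.locus_bounds, recipient, [(left, x, donor)])
        bottom = build_strand(mmap.locus_bounds, recipient, [(x, right, donor)])
    return top, bottom, left, right, top_right


def make_two_end_engagement(
    dsb: DSBEvent,
    mmap: MarkerMap,
    config: ModelConfig,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    """Two-end engagement: CO (nicked) or NCO (disassembled) from one intermediate."""
    donor = other_parent(config.recipient)
    recipient = config.recipient
    w = _tract_window(mmap)
    left = _clip(dsb.position - dsb.synth_left, w)
    right = _clip(dsb.position + dsb.synth_right, w)
    if rng.random() < config.engagement_co_prob:
        # nicking across from the unligated junctions: CO whose single hDNA
        # tract spans the break; no full-conversion tract.
        if rng.integers(0, 2):
            top = build_strand(mmap.locus_bounds, recipient, [(left, mmap.locus_bounds[1], donor)])
            bottom = build_strand(mmap.locus_bounds, recipient, [(right, mmap.locus_bounds[1], donor)])
            nicks = ((left,), (right,))
        else:
            top = build_strand(mmap.locus_bounds, donor, [(right, mmap.locus_bounds[1], recipient)])
            bottom = build_strand(mmap.locus_bounds, donor, [(left, mmap.locus_bounds[1], recipient)])
            nicks = ((right,), (left,))
        truth = Truth("two_end_engagement", dsb, "CO", donor, (("branch", "co"),))
        return RecombinantDuplex((top, bottom), nicks, mmap.locus_bounds, truth)
    top, bottom, left, right, top_right = _trans_nco_strands(dsb, donor, mmap, rng)
    # the nick on each strand sits where its newly synthesized 3' end meets
    # the resected recipient strand
    nicks = ((right,), (left,)) if top_right else ((left,), (right,))
    truth = Truth("two_end_engagement", dsb, "NCO", donor, (("branch", "nco"),))
    return RecombinantDuplex((top, bottom), nicks, mmap.locus_bounds, truth)


def make_two_ended_sdsa(
    dsb: DSBEvent,
    mmap: MarkerMap,
    config: ModelConfig,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    """Two-ended SDSA: same observable product as the two-end-engagement NCO."""
    donor = other_parent(config.recipient)
    top, bottom, left, right, top_right = _trans_nco_strands(dsb, donor, mmap, rng)
    nicks = ((right,), (left,)) if top_right else ((left,), (right,))
    truth = Truth("two_ended_sdsa", dsb, "NCO", donor)
    return RecombinantDuplex((top, bottom), nicks, mmap.locus_bounds, truth)


def make_dhj_resolution(
    dsb: DSBEvent,
    mmap: MarkerMap,
    config: ModelConfig,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    """dHJ cleavage into a CO.

    With probability ``resolution_bias`` the junctions are cut in the
    orientation leaving a single hDNA tract; otherwise the product carries a
    full-conversion tract adjacent to the hDNA.  Nicks mark the cleavage
    points.
    """
    donor = other_parent(config.recipient)
    recipient = config.recipient
    w = _tract_window(mmap)
    x = _clip(dsb.position, w)
    left = _clip(dsb.position - dsb.synth_left, w)
    right = _clip(dsb.position + dsb.synth_right, w)
    lo, hi = mmap.locus_bounds
    open_orientation = rng.random() < config.resolution_bias
    if open_orientation:
        top = build_strand((lo, hi), recipient, [(left, hi, donor)])
        bottom = build_strand((lo, hi), recipient, [(right, hi, donor)])
        nicks = ((left, x), (right, x))
        detail = (("orientation", "single_hdna"),)
    else:
        # recipient flank | full conversion [left, x) | hDNA [x, right) | donor flank
        top = build_strand((lo, hi), recipient, [(left, hi, donor)])
        bottom = build_strand(
            (lo, hi), recipient, [(left, x, donor), (right, hi, donor)]
        )
        nicks = ((left,), (x, right))
        detail = (("orientation", "conversion_adjacent"),)
    truth = Truth("dhj_resolution", dsb, "CO", donor, detail)
    return RecombinantDuplex((top, bottom), nicks, (lo, hi), truth)


def make_dhj_dissolution_nco(
    dsb: DSBEvent,
    mmap: MarkerMap,
    rng: np.random.Generator,
    donor: Parent = "P2",
) -> RecombinantDuplex:
    """dHJ dissolution: NCO with trans hDNA and no nicks."""
    top, bottom, _, _, _ = _trans_nco_strands(dsb, donor, mmap, rng)
    truth = Truth("dhj_dissolution", dsb, "NCO", donor)
    return RecombinantDuplex((top, bottom), ((), ()), mmap.locus_bounds, truth)


def make_gap_repair_nco(
    dsb: DSBEvent,
    mmap: MarkerMap,
    rng: np.random.Generator,
    donor: Parent = "P2",
) -> RecombinantDuplex:
    """Double-strand gap repair: NCO with a full-conversion tract, no hDNA.

    The break is widened by the resection extents on both strands; synthesis
    across the gap copies the donor on both strands.
    """
    recipient = other_parent(donor)
    w = _tract_window(mmap)
    gap_start = _clip(dsb.position - dsb.resect_left, w)
    gap_end = _clip(dsb.position + dsb.resect_right, w)
    top = build_strand(mmap.locus_bounds, recipient, [(gap_start, gap_end, donor)])
    bottom = build_strand(mmap.locus_bounds, recipient, [(gap_start, gap_end, donor)])
    nicks = ((gap_end,), (gap_start,))
    truth = Truth("gap_repair", dsb, "NCO", donor)
    return RecombinantDuplex((top, bottom), nicks, mmap.locus_bounds, truth)


def _dispatch(
    model: str,
    dsb: DSBEvent,
    mmap: MarkerMap,
    config: ModelConfig,
    rng: np.random.Generator,
) -> RecombinantDuplex:
    donor = other_parent(config.recipient)
    if model == "sdsa":
        return make_sdsa_nco(dsb, donor, mmap, rng)
    if model == "two_ended_sdsa":
        return make_two_ended_sdsa(dsb, mmap, config, rng)
    if model == "two_end_engagement":
        return make_two_end_engagement(dsb, mmap, config, rng)
    if model == "dhj_resolution":
        return make_dhj_resolution(dsb, mmap, config, rng)
    if model == "dhj_dissolution":
        return make_dhj_dissolution_nco(dsb, mmap, rng, donor)
    if model == "gap_repair":
        return make_gap_repair_nco(dsb, mmap, rng, donor)
    raise SimulationError(f"unknown model {model!r}")


def simulate_meiosis(
    mmap: MarkerMap,
    config: ModelConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[RecombinantDuplex]:
    """Simulate ``n`` independent recombinant chromatids.

    Models are drawn from ``config.weights`` (default: all mass on
    ``config.model``).  Reproducible under a fixed ``config.seed`` when no
    generator is passed.
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = config.effective_weights()
    names = sorted(weights)
    probs = np.array([weights[m] for m in names], dtype=float)
    out = []
    for _ in range(n):
        model = names[int(rng.choice(len(names), p=probs))]
        dsb = sample_dsb(mmap, config, rng)
        out.append(_dispatch(model, dsb, mmap, config, rng))
    return out


# ---------------------------------------------------------------------------
# export


def duplex_segments_frame(products: Sequence[RecombinantDuplex]):
    """Per-strand segment table (one row per segment) for a list of products."""
    import pandas as pd

    rows = []
    for i, d in enumerate(products):
        for si, name in enumerate(("top", "bottom")):
            for a, b, p in d.strands[si]:
                rows.append((i, name, a, b, p))
    return pd.DataFrame(rows, columns=["event_id", "strand", "start", "end", "parent"])


def duplex_to_fasta(
    duplex: RecombinantDuplex, mmap: MarkerMap, event_id: str = "event"
) -> str:
    """Schematic FASTA: background 'a' with parental marker alleles substituted.

    Both strands are written in top-strand sense; indel alleles are inserted
    verbatim, so sequence lengths are approximate for indel-bearing strands.
    """
    lo, _ = mmap.locus_bounds
    records = []
    for si, name in enumerate(("top", "bottom")):
        seq = []
        cursor = lo
        for m in mmap.markers:
            seq.append("a" * (m.position - cursor))
            allele = m.allele_p1 if duplex.parent_at(si, m.position) == "P1" else m.allele_p2
            seq.append(allele)
            cursor = m.position + m.footprint
        records.append(f">{event_id}|{name}\n{''.join(seq)}")
    return "\n".join(records) + "\n"
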