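# Methods

## The product model

A simulated recombinant is the single chromatid recovered from one meiosis:
a DNA duplex over the locus interval, each strand a tiling of half-open
segments labeled with parental origin (P1 or P2), plus per-strand lists of
nick positions and ground-truth event metadata. Heteroduplex DNA (hDNA) is
simply the set of intervals where the two strands' origins differ; markers
(SNPs and small indels at fixed coordinates) turn those intervals into
observable mismatches. Coordinates are integer base pairs relative to an
anchor site and may be negative; point positions are inclusive, intervals
half-open.

Only the recovered chromatid is modeled — no four-strand tetrad
bookkeeping — because the assay this emulates recovers one chromatid per
event. Multi-chromatid intermediates, sister-template switching,
heteroduplex rejection and crossover interference are out of scope.

## Mechanistic models

Each repair model is a deterministic construction given a sampled DSB
(position uniform over the locus; resection and synthesis lengths
geometric with per-bp continuation probabilities, independently per side):

* **sdsa** — single hDNA tract on one side of the break (the extended
  invading strand), nicks present; always NCO.
* **two_end_engagement** — both ends extended by synthesis on the same
  donor chromatid with unligated junctions. Disassembly (probability
  1 − `engagement_co_prob`) gives an NCO with *trans* hDNA and a nick on
  each strand; nicking gives a CO with a single hDNA tract spanning the
  break and no full-conversion tract.
* **two_ended_sdsa** — alias for the NCO branch above; the two mechanisms
  are observationally equivalent at the product level, so the simulator
  makes that equivalence explicit.
* **dhj_resolution** — always CO. With probability `resolution_bias` the
  cleavage orientation leaves a single hDNA tract; otherwise the product
  carries a full-conversion tract adjacent to the hDNA (recipient flank |
  conversion | hDNA | donor flank). Nicks mark cleavage points.
* **dhj_dissolution** — NCO with *trans* hDNA and no nicks.
* **gap_repair** — the break widens to a gap (resection extents on both
  strands); donor-templated synthesis across it yields a full-conversion
  tract containing no hDNA; always NCO.

Tract/switch coordinates are clipped to the open interval between the two
outermost markers. This mirrors the assay — events are classifiable only
when the flanking CO/NCO markers resolve — and makes the ground-truth
label provably equal to the flank-phase classification for every noiseless
product. Asymmetric resection/synthesis is supported through independent
per-side draws; defaults are symmetric.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `synth_ext_prob` | 0.99717 /bp | geometric continuation of synthesis; sets the hDNA tract scale (mean 1/(1−p) ≈ 353 bp) and matches the estimator's extension prior |
| `resect_ext_prob` | 0.995 /bp | resection scale (mean 200 bp); affects nick/gap placement only |
| `resolution_bias` | 0.5 | dHJ cleavage orientation (0.5 = the classical unbiased DSBR assumption) |
| `engagement_co_prob` | 0.5 | CO vs NCO fate of the two-end engagement intermediate |
| `repair_prob` (r) | 0.82 | per-mismatch short-patch repair probability (the observed repaired fraction when only short-patch MMR is active) |
| `strand_bias` | 0.5 | probability the top strand is excised per short-patch event |
| NER windows | 22–24 nt 5′, 5–6 nt 3′ | excision margins, drawn uniformly per event |
| `p_extend` (p) | 0.99717 | per-base extension probability in the length estimator |

## Mismatch repair overlays

**Canonical MMR** is nick-directed and long-patch: each contiguous hDNA
region with an associated nick has the nicked strand rewritten from the
other strand across the whole region, so all its mismatches resolve in the
same direction. The nearest nick decides the excised strand; ties between
strands are broken at random. Regions on chromatids with nicks but none
near the region are still repaired by the globally nearest nick (excision
tracts are long), so a nick-bearing chromatid never retains hDNA; products
with no nicks at all (dissolution) escape untouched. Conversion versus
restoration is an emergent consequence of which strand is excised, never a
separate parameter.

**Short-patch MMR** visits mismatched markers in random order; each
still-heteroduplex marker triggers an excision with probability r. The
excised strand is drawn with `strand_bias`; the patch margins (w5 nt 5′,
w3 nt 3′, flipping orientation on the bottom strand) are drawn uniformly
from the NER ranges. Mismatches within one patch span (w5 + w3, i.e.
27–30 bp) of the trigger are treated as a single helix-distortion lesion
and excised in the same patch — this is the mechanistic reading under
which co-repair is certain for pairs closer than the minimum patch span
and repairs are independent beyond the maximum span, reproducing the
closed form r/(2(2 − r)) for distant pairs. Already-repaired sites are
never re-excised, and rewriting always copies the template strand, so
repair can only shrink the hDNA interval set.

Genotypes: wild type = canonical then short-patch on leftovers; *Msh6* =
short-patch only; *Xpc*;*Msh6* = no repair (an optional residual
probability, default 0, models leftover maternal activity). Per-mismatch-
type repair efficiencies are deliberately uniform.

## Selection and observation

A recombinant survives purine selection iff at least one single strand
carries the wild-type allele at both selection sites; replication
segregates heteroduplex strands into different cell lineages and the gene
product is non-cell-autonomous, so a mosaic with one fully functional
strand lives. The recipient chromatid (default P1) carries the downstream
mutation; which parent is recipient is configurable. Sequencing is modeled
error-free — coverage gaps enter only through an explicit marker mask.

## Tract reconstruction

Marker states derive from the two strand calls (heteroduplex iff they
differ). The CO/NCO call compares the outermost covered markers and
refuses heteroduplex flanks. Tracts are maximal runs of markers differing
from the flanking background phase, each side of a crossover scored
against its own flank (nearer flank, ties left). A single background
marker between non-background neighbors stays inside the tract as an
internal restoration — the one observable patchy-tract geometry — while
two or more consecutive background markers split tracts; with one DSB per
chromatid the distinction only matters after partial repair. Cis/trans
uses the runs of the strand carrying the donor allele among heteroduplex
markers (single-marker tracts are undetermined and excluded from the
tally); the run structure is invariant to the choice of reference parent,
so no DSB coordinate is ever assumed. Span bounds follow the
inclusion/exclusion convention (minimum = outermost included markers or
the single marker's footprint; maximum = nearest excluded markers, locus
bounds at the map edge) with display bounds at halfway points.

Mismatch types are reported as the ambiguous pair of possible base-base
mismatches (e.g. A:C|G:T for an A/G SNP) except in trans tracts, where the
donor-strand runs identify the orientation; indels are loops sized by the
marker footprint.

## Tract length estimation

Lengths are modeled as exponential with rate λ = −ln p — the continuous
counterpart of the geometric per-base extension model; at p ≈ 0.997 the
two differ by well under a base pair, and the continuous closed form is
exact. The estimate is the conditional *expectation* of the truncated
distribution (the mode of a truncated exponential is always the lower
bound, which is not a useful "most likely length"); it is computed through
`expm1` for stability, returns `a` for degenerate bounds, and switches to
the interval midpoint when λ(b − a) < 1e-9 (the flat-density limit).
Single-marker tracts use the same formula with a = the marker footprint.
Trans tracts are split at the midpoint between the facing markers of the
two phase runs, each half bounded by its own outer excluded marker and the
split point.

Parameter-recovery simulations show the bounds-based mean matches the true
mean of detected tracts within sampling error on maps with ≲ 100 bp
spacing; at several-hundred-bp spacing the estimate is biased a few
percent low relative to the (detection-enriched) true mean, because wide
exclusion bounds only approximate the exact censoring event. Conclusions
of CO-vs-NCO comparisons are stable for p anywhere in [0.990, 0.999].

## Statistics

Fisher's exact test (two-sided, hypergeometric tail with the conventional
1 + 1e-7 relative tie tolerance) backs all 2×2 comparisons; the test suite
cross-checks it against an exact rational-arithmetic enumeration oracle.
Tract-length comparisons default to Welch's t (unpaired, e.g. CO vs NCO)
or a paired t (e.g. short vs long halves of the same trans tracts, which
share an event), each with a seeded permutation alternative. The
zero-successes binomial probability (1 − q)^n is exposed in closed form.
No multiple-testing correction is applied.

## The default marker map

`rosy_marker_map()` is a synthetic stand-in for the assayed *rosy* locus:
23 markers over ~6 kb with selection sites at −468 and 3312, nearest SNPs
150–200 bp around the downstream site, a 400 bp gap downstream of the
upstream site with small indels above it, and three marker pairs closer
than 21 bp. It reproduces the locus's descriptive features, not its exact
polymorphism list, so analyses of real data should load their own map
(`load_marker_table`).

## What passing tests do and do not show

The generator produces noiseless, single-event, error-free products on a
known map. Green tests therefore demonstrate internal consistency of the
models, repair rules, selection logic and estimators — not robustness to
sequencing error, PCR recombination artifacts, multiple events per
chromatid, or marker maps with very different densities. Problem sizes in
the test and acceptance runs (2,000 products per model signature, 10,000
simulated marker pairs, 5,000 meioses for selection enrichment, 1,000
products for the classification round trip) were chosen so that binomial
sampling error is small against the tested effect sizes.
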