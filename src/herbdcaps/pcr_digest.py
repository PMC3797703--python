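"""In-silico PCR and restriction digestion.

``build_amplicon`` anneals a forward/reverse primer pair onto a concrete
template, enforcing any primer/template mismatches into the product (the
dCAPS trick), and appending non-homologous 5' tails.  ``digest`` cuts an
amplicon with a restriction enzyme and reports fragment lengths under both
strand conventions; ``classify_pattern`` merges the fragment patterns of a
diploid sample's two alleles into the gel lane pattern a genotyper reads.

Single best-footprint semantics: each primer must anneal at a unique best
position within the policy, mirroring a single-product assay.  Templates
that support two equally good footprints raise ``PrimingError`` rather
than silently multiplying products.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Collection, Sequence

from . import seqcore
from .seqcore import Enzyme, InputError, find_sites, revcomp

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .assay import Primer


class PrimingError(InputError):
    """Non-specific priming or incompatible primer orientations."""


@dataclass(frozen=True)
class AnnealingPolicy:
    """How tolerant annealing is.

    ``max_mismatches`` bounds total primer/template mismatches in the
    homologous part; ``min_three_prime_match`` is the number of 3'-terminal
    bases that must pair perfectly (polymerases do not extend from a
    mismatched 3' end).
    """

    max_mismatches: int = 1
    min_three_prime_match: int = 1


DEFAULT_POLICY = AnnealingPolicy()


@dataclass(frozen=True)
class Annealing:
    """A primer bound to a template footprint (1-based, closed, top strand)."""

    primer: "Primer"
    start: int
    end: int
    #: (primer position, template position) pairs, 1-based; primer position
    #: counts from the primer 5' end including any tail.
    mismatches: tuple[tuple[int, int], ...]


def _anneal_scan(template: str, primer: "Primer",
                 policy: AnnealingPolicy) -> Annealing | None:
    """Locate the unique best footprint of *primer* on *template*.

    Returns None when no footprint satisfies the policy; raises
    ``PrimingError`` when two footprints tie for fewest mismatches.
    """
    core = primer.core.upper()
    tail_len = len(primer.tail)
    tu = template.upper()
    n, k = len(tu), len(core)
    if k > n:
        return None
    # Compare the primer core in top-strand sense.
    top_sense = core if primer.orientation == "forward" else revcomp(core)
    candidates: list[tuple[int, int]] = []  # (n_mismatches, start0)
    for i in range(n - k + 1):
        window = tu[i:i + k]
        mm = [j for j in range(k) if window[j] != top_sense[j]]
        if len(mm) > policy.max_mismatches:
            continue
        # 3'-terminal perfect match: rightmost core bases for a forward
        # primer, leftmost top-strand positions for a reverse primer.
        t = policy.min_three_prime_match
        if primer.orientation == "forward":
            terminal = range(k - t, k)
        else:
            terminal = range(0, t)
        if any(j in mm for j in terminal):
            continue
        candidates.append((len(mm), i))
    if not candidates:
        return None
    candidates.sort()
    best_mm = candidates[0][0]
    best = [c for c in candidates if c[0] == best_mm]
    if len(best) > 1:
        raise PrimingError(
            f"non-specific priming: {primer.name} anneals equally well at "
            f"positions {[c[1] + 1 for c in best]}"
        )
    i = best[0][1]
    mm_top0 = [j for j in range(k) if tu[i + j] != top_sense[j]]
    pairs = []
    for j in mm_top0:
        if primer.orientation == "forward":
            ppos = tail_len + j + 1
        else:
            # reverse primer position 1 (after tail) pairs the footprint's
            # rightmost top-strand base
            ppos = tail_len + (k - j)
        pairs.append((ppos, i + j + 1))
    return Annealing(primer, i + 1, i + k, tuple(sorted(pairs)))


PROVENANCE_TEMPLATE = "template"
PROVENANCE_ENFORCED = "primer-enforced"
PROVENANCE_TAIL = "tail"


@dataclass(frozen=True)
class Amplicon:
    """Double-stranded PCR product, represented by its top strand.

    ``provenance`` records, per top-strand position, whether the base came
    from the template, was enforced by a primer mismatch, or belongs to a
    non-homologous primer tail.
    """

    seq: str
    provenance: tuple[str, ...]
    fwd: Annealing
    rev: Annealing

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.provenance):
            raise InputError("provenance must annotate every position")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def enforced_positions(self) -> tuple[int, ...]:
        """1-based amplicon positions carrying a primer-enforced base."""
        return tuple(
            i + 1 for i, p in enumerate(self.provenance)
            if p == PROVENANCE_ENFORCED
        )

    def template_to_amplicon(self, template_pos: int) -> int:
        """Map a template coordinate into 1-based amplicon coordinates."""
        return template_pos - self.fwd.start + 1 + len(self.fwd.primer.tail)


def build_amplicon(template: str, fwd: "Primer", rev: "Primer",
                   policy: AnnealingPolicy = DEFAULT_POLICY) -> Amplicon | None:
    """Simulate PCR of *template* with a forward/reverse primer pair.

    Returns None when either primer fails to anneal under *policy*
    (amplification failure).  Mismatched primer bases are substituted into
    the product ("primer-enforced"); lowercase 5' tails are appended
    verbatim (forward) or as reverse complement (reverse) at the product
    ends.
    """
    seqcore.validate_sequence(template, concrete=True)
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise PrimingError(
            "build_amplicon needs one forward and one reverse primer "
            f"(got {fwd.orientation}/{rev.orientation})"
        )
    af = _anneal_scan(template, fwd, policy)
    ar = _anneal_scan(template, rev, policy)
    if af is None or ar is None:
        return None
    if ar.end < af.end or ar.start < af.start:
        raise PrimingError(
            f"primers face away from each other: forward footprint "
            f"[{af.start}, {af.end}], reverse footprint [{ar.start}, {ar.end}]"
        )

    region = list(template.upper()[af.start - 1:ar.end])
    prov = [PROVENANCE_TEMPLATE] * len(region)
    enforced: dict[int, str] = {}  # 0-based region index -> enforced base
    for ppos, tpos in af.mismatches:
        enforced[tpos - af.start] = fwd.seq[ppos - 1].upper()
    for ppos, tpos in ar.mismatches:
        # a reverse-primer base appears complemented on the top strand
        enforced[tpos - af.start] = seqcore.complement(rev.seq[ppos - 1]).upper()
    for idx, base in enforced.items():
        region[idx] = base
        prov[idx] = PROVENANCE_ENFORCED

    fwd_tail = fwd.tail.upper()
    rev_tail = revcomp(rev.tail).upper()
    seq = fwd_tail + "".join(region) + rev_tail
    provenance = (
        (PROVENANCE_TAIL,) * len(fwd_tail)
        + tuple(prov)
        + (PROVENANCE_TAIL,) * len(rev_tail)
    )
    return Amplicon(seq, provenance, af, ar)


# ---------------------------------------------------------------------------
# Digestion

@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one amplicon with one enzyme.

    Fragment lengths are reported under both strand conventions: cuts on
    the top strand (``cut_top`` offsets) and cuts on the bottom strand
    (``cut_bottom`` offsets, still measured in top-strand coordinates).
    For a dCAPS assay whose mismatch-bearing primer is the reverse primer,
    the bottom strand is the primer strand and gel sizes are conventionally
    quoted from it.
    """

    enzyme: Enzyme
    length: int
    sites: tuple[int, ...]
    top_fragments: tuple[int, ...]
    bottom_fragments: tuple[int, ...]

    @property
    def classification(self) -> str:
        return "undigested" if not self.sites else "digested"

    def fragments_for(self, dcaps_orientation: str) -> tuple[int, ...]:
        """Fragment lengths on the dCAPS primer's strand."""
        if dcaps_orientation == "reverse":
            return self.bottom_fragments
        return self.top_fragments


def _fragments(length: int, cuts: Collection[int]) -> tuple[int, ...]:
    """Fragment lengths given cut boundaries ('cut after position b')."""
    bounds = sorted(b for b in cuts if 0 < b < length)
    edges = [0, *bounds, length]
    frags = [b - a for a, b in zip(edges, edges[1:])]
    return tuple(sorted(frags, reverse=True))


def digest(a: Amplicon | str, e: Enzyme) -> DigestResult:
    """Cut amplicon *a* at every recognition site of *e*."""
    seq = a.seq if isinstance(a, Amplicon) else a
    sites = find_sites(seq, e)
    top = _fragments(len(seq), [p + e.cut_top - 1 for p in sites])
    bottom = _fragments(len(seq), [p + e.cut_bottom - 1 for p in sites])
    return DigestResult(e, len(seq), tuple(sites), top, bottom)


# ---------------------------------------------------------------------------
# Lane patterns

@dataclass(frozen=True)
class GelModel:
    """Crude electrophoresis resolution model, disabled by default.

    When enabled, bands closer than ``min_separation`` nt co-migrate (the
    larger length represents the band) and fragments shorter than
    ``min_size`` run off the gel.  The study reads lanes qualitatively, so
    the default leaves band sets untouched.
    """

    enabled: bool = False
    min_separation: int = 10
    min_size: int = 20


def apply_gel(bands: Collection[int], gel: GelModel) -> frozenset[int]:
    if not gel.enabled:
        return frozenset(bands)
    kept = sorted((b for b in bands if b >= gel.min_size), reverse=True)
    merged: list[int] = []
    for b in kept:
        if merged and merged[-1] - b < gel.min_separation:
            continue
        merged.append(b)
    return frozenset(merged)


def write_digest_results(rows: Sequence[tuple[str, DigestResult]],
                         path) -> None:
    """Write (sample, result) pairs as CSV, fragments as '+'-joined sizes."""
    import csv as _csv

    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample", "enzyme", "fragments_primer_strand",
                         "fragments_top_strand", "classification"])
        for sample, res in rows:
            writer.writerow([
                sample, res.enzyme.name,
                "+".join(map(str, res.bottom_fragments)),
                "+".join(map(str, res.top_fragments)),
                res.classification,
            ])


#: Lane pattern labels: SS = homozygous wild (sensitive), RS = heterozygous,
#: RR = homozygous mutant (resistant), fail = no amplification.
LANE_SS = "SS"
LANE_RS = "RS"
LANE_RR = "RR"
LANE_FAIL = "fail"
LANE_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LanePattern:
    label: str
    bands: frozenset[int] = field(default_factory=frozenset)


def classify_pattern(allele_fragments: Sequence[Collection[int] | None],
                     wild_fragments: Collection[int] = (85, 42),
                     uncut_length: int = 127,
                     gel: GelModel = GelModel()) -> LanePattern:
    """Merge 0-2 allele fragment patterns into a diploid lane pattern.

    ``None`` entries are failed alleles; no amplicon at all is a failed
    lane.  Band sets matching neither the digested, undigested, nor mixed
    reference pattern are labelled ambiguous.
    """
    present = [f for f in allele_fragments if f is not None]
    if len(allele_fragments) > 2:
        raise InputError("a diploid sample has at most two alleles")
    if not present:
        return LanePattern(LANE_FAIL)
    bands = apply_gel(Counter(b for f in present for b in f), gel)
    wild = apply_gel(wild_fragments, gel)
    uncut = apply_gel([uncut_length], gel)
    if bands == wild:
        return LanePattern(LANE_SS, bands)
    if bands == uncut:
        return LanePattern(LANE_RR, bands)
    if bands == wild | uncut:
        return LanePattern(LANE_RS, bands)
    return LanePattern(LANE_AMBIGUOUS, bands)
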