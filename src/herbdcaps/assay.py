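"""dCAPS assay representation, validation, and design enumeration.

A dCAPS assay genotypes a SNP that does not itself alter a restriction
site: one PCR primer carries deliberate mismatches that, together with the
diagnostic base of one allele, complete a recognition site in the
amplicon.  Digestion then cleaves amplicons from that allele only, and the
genotype is read from the band pattern.

The packaged study assay targets ACCase codon 1781 of Alopecurus
myosuroides: a 40-nt reverse primer with a 10-nt non-homologous tail and a
single mismatch at its penultimate position creates an NspI site (RCATGY)
only when the wild-type codon ATA is present; either resistant leucine
codon (CTA or TTA) destroys the site, so resistant alleles stay uncut.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import pcr_digest, seqcore
from .pcr_digest import AnnealingPolicy, DEFAULT_POLICY, PrimingError, build_amplicon, digest
from .seqcore import Enzyme, InputError, iupac_match, revcomp, validate_sequence


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide primer, written 5'->3'.

    A lowercase prefix marks a non-homologous 5' tail (the convention used
    when tailed dCAPS primers are printed); the remaining uppercase part is
    the template-homologous core.  For a reverse primer the core pairs with
    the top strand as its reverse complement and the 3' terminus sits at
    the *left* (5'-most) end of the top-strand footprint.
    """

    name: str
    seq: str
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise InputError(
                f"primer {self.name}: orientation must be forward/reverse"
            )
        validate_sequence(self.seq, concrete=True)
        core = self.core
        if not core:
            raise InputError(f"primer {self.name}: no homologous (uppercase) part")
        if any(ch.islower() for ch in core):
            raise InputError(
                f"primer {self.name}: lowercase tail must be a 5' prefix"
            )

    @property
    def tail(self) -> str:
        """Maximal lowercase (non-homologous) 5' prefix."""
        i = 0
        while i < len(self.seq) and self.seq[i].islower():
            i += 1
        return self.seq[:i]

    @property
    def core(self) -> str:
        """Template-homologous part (everything after the tail)."""
        return self.seq[len(self.tail):]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SnpSpec:
    """A codon-level SNP to genotype.

    ``position`` is the 1-based template (top-strand) coordinate of the
    codon's first base.  The diagnostic position is the first base at
    which the wild codon differs from every mutant codon.
    """

    codon: int
    position: int
    wild_codon: str
    mutant_codons: tuple[str, ...]

    def __post_init__(self) -> None:
        validate_sequence(self.wild_codon, concrete=True)
        for m in self.mutant_codons:
            validate_sequence(m, concrete=True)
            if len(m) != len(self.wild_codon):
                raise InputError("all codon alleles must have equal length")
        try:
            self.diagnostic_offset  # noqa: B018 - validates existence
        except StopIteration:
            raise InputError(
                "no position distinguishes the wild codon from every mutant"
            ) from None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.wild_codon, *self.mutant_codons)

    @property
    def diagnostic_offset(self) -> int:
        """0-based offset within the codon of the diagnostic base."""
        return next(
            i for i in range(len(self.wild_codon))
            if all(self.wild_codon[i] != m[i] for m in self.mutant_codons)
        )

    @property
    def diagnostic_position(self) -> int:
        """Template coordinate of the diagnostic base."""
        return self.position + self.diagnostic_offset

    def apply(self, template: str, codon_allele: str) -> str:
        """Template sequence carrying *codon_allele* at the SNP codon."""
        if codon_allele not in self.alleles:
            raise InputError(f"unknown allele codon {codon_allele!r}")
        i = self.position - 1
        return template[:i] + codon_allele + template[i + len(codon_allele):]

    def allele_templates(self, template: str) -> dict[str, str]:
        """One template per allele, differing only at the SNP codon."""
        return {a: self.apply(template, a) for a in self.alleles}


@dataclass(frozen=True)
class AssayDesign:
    """A primer pair + enzyme with its allele->fragment-pattern contract.

    ``forward`` is the fully homologous partner primer (forward-oriented
    in the packaged assay; when a design puts the mismatch-bearing dCAPS
    primer on the forward strand, the partner is the reverse primer).
    """

    forward: Primer
    dcaps: Primer
    enzyme: Enzyme
    snp: SnpSpec
    max_amplicon: int = 300
    # annotations filled by the designer / characterizer
    amplicon_length: int | None = None
    diagnostic_interval: tuple[int, int] | None = None
    wild_fragments: tuple[int, ...] | None = None
    n_mismatches: int | None = None
    fragment_diff: int | None = None

    @property
    def primer_pair(self) -> tuple[Primer, Primer]:
        """(forward, reverse) pair in build_amplicon order."""
        if self.dcaps.orientation == "reverse":
            return (self.forward, self.dcaps)
        return (self.dcaps, self.forward)

    def expected_patterns(self) -> dict[str, frozenset[int]]:
        """Reference band sets per genotype class (needs annotations)."""
        if self.wild_fragments is None or self.amplicon_length is None:
            raise InputError("design has not been characterized yet")
        wild = frozenset(self.wild_fragments)
        uncut = frozenset([self.amplicon_length])
        return {"SS": wild, "RR": uncut, "RS": wild | uncut}


@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[Check, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> tuple[Check, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def __str__(self) -> str:
        return "\n".join(
            f"[{'ok' if c.passed else 'FAIL'}] {c.name}"
            + (f": {c.detail}" if c.detail else "")
            for c in self.checks
        )


def _check_templates_differ_only_at_snp(templates: Mapping[str, str],
                                        snp: SnpSpec) -> None:
    seqs = list(templates.values())
    lo, hi = snp.position - 1, snp.position - 1 + len(snp.wild_codon)
    for s in seqs[1:]:
        if len(s) != len(seqs[0]) or (
            s[:lo] != seqs[0][:lo] or s[hi:] != seqs[0][hi:]
        ):
            raise InputError("allele templates must differ only at the SNP codon")


def validate_assay(design: AssayDesign, templates: Mapping[str, str],
                   policy: AnnealingPolicy = DEFAULT_POLICY) -> ValidationReport:
    """Check an assay's allele->fragment-pattern contract in silico.

    *templates* maps allele codon -> full template sequence (one entry per
    allele of ``design.snp``; sequences identical outside the SNP codon).
    Every check is reported with pass/fail rather than raised, so a design
    that fails to amplify on some allele yields a readable report.
    """
    if set(templates) != set(design.snp.alleles):
        raise InputError(
            f"templates must cover alleles {design.snp.alleles}, got "
            f"{tuple(templates)}"
        )
    _check_templates_differ_only_at_snp(templates, design.snp)

    fwd, rev = design.primer_pair
    checks: list[Check] = []
    amplicons: dict[str, pcr_digest.Amplicon] = {}
    for allele, template in templates.items():
        try:
            amp = build_amplicon(template, fwd, rev, policy)
        except PrimingError as exc:
            amp = None
            detail = str(exc)
        else:
            detail = "primer failed annealing policy" if amp is None else ""
        checks.append(Check(f"amplification[{allele}]", amp is not None, detail))
        if amp is not None:
            amplicons[allele] = amp

    wild = design.snp.wild_codon
    diag_amp = None
    if wild in amplicons:
        diag_amp = amplicons[wild].template_to_amplicon(
            design.snp.diagnostic_position
        )

    site_map: dict[str, tuple[list[int], list[int]]] = {}
    for allele, amp in amplicons.items():
        sites = seqcore.find_sites(amp.seq, design.enzyme)
        L = design.enzyme.site_length
        dpos = amp.template_to_amplicon(design.snp.diagnostic_position)
        diagnostic = [p for p in sites if p <= dpos <= p + L - 1]
        site_map[allele] = (diagnostic, [p for p in sites if p not in diagnostic])

    if wild in site_map:
        diagnostic, _ = site_map[wild]
        checks.append(Check(
            "diagnostic-site-on-wild", len(diagnostic) >= 1,
            "" if diagnostic else
            f"no {design.enzyme.name} site overlaps amplicon position {diag_amp}",
        ))
    for allele in design.snp.mutant_codons:
        if allele not in site_map:
            continue
        diagnostic, _ = site_map[allele]
        checks.append(Check(
            f"no-site-on-mutant[{allele}]", not diagnostic,
            f"diagnostic site(s) at {diagnostic}" if diagnostic else "",
        ))
    for allele, (_, spurious) in site_map.items():
        checks.append(Check(
            f"no-spurious-site[{allele}]", not spurious,
            f"non-diagnostic {design.enzyme.name} site(s) at {spurious}"
            if spurious else "",
        ))
    for allele, amp in amplicons.items():
        ok = len(amp) <= design.max_amplicon
        checks.append(Check(
            f"amplicon-size[{allele}]", ok,
            "" if ok else f"{len(amp)} nt exceeds maximum {design.max_amplicon}",
        ))
    return ValidationReport(tuple(checks))


def characterize_assay(design: AssayDesign, templates: Mapping[str, str],
                       policy: AnnealingPolicy = DEFAULT_POLICY) -> AssayDesign:
    """Annotate a valid design with amplicon length and fragment contract."""
    report = validate_assay(design, templates, policy)
    if not report.passed:
        raise InputError(
            "cannot characterize an invalid assay:\n" + str(report)
        )
    fwd, rev = design.primer_pair
    wild_amp = build_amplicon(templates[design.snp.wild_codon], fwd, rev, policy)
    assert wild_amp is not None
    res = digest(wild_amp, design.enzyme)
    wild_frags = res.fragments_for(design.dcaps.orientation)
    site = res.sites[0]
    n_mm = len(wild_amp.fwd.mismatches) + len(wild_amp.rev.mismatches)
    return replace(
        design,
        amplicon_length=len(wild_amp),
        diagnostic_interval=(site, site + design.enzyme.site_length - 1),
        wild_fragments=wild_frags,
        n_mismatches=n_mm,
        fragment_diff=len(wild_amp) - max(wild_frags),
    )


# ---------------------------------------------------------------------------
# Design enumeration

@dataclass(frozen=True)
class DesignConstraints:
    """Search-space bounds for ``design_dcaps``.

    ``max_mismatches`` / ``max_three_prime_distance`` are the classical
    dCAPS design rules (few enforced bases, close to the primer 3' end so
    mispriming cannot silently skip them); ``min_fragment_diff`` requires
    the digested band to be resolvable from the uncut amplicon.  The dCAPS
    primer gets ``core_length`` homologous bases plus the 5' ``tail``; its
    fully homologous partner is anchored at the far template end with
    ``partner_length`` bases.
    """

    max_amplicon: int = 300
    max_mismatches: int = 1
    max_three_prime_distance: int = 3
    min_fragment_diff: int = 0
    core_length: int = 30
    partner_length: int = 25
    tail: str = "gccctagaat"


def _concrete_base(pattern_char: str) -> str:
    """Deterministic concrete base realizing an IUPAC pattern character."""
    return min(seqcore.IUPAC_SETS[pattern_char.upper()])


def design_dcaps(template: str, snp: SnpSpec, enzymes: Sequence[Enzyme],
                 constraints: DesignConstraints = DesignConstraints(),
                 policy: AnnealingPolicy = DEFAULT_POLICY) -> list[AssayDesign]:
    """Enumerate dCAPS designs discriminating *snp* on *template*.

    For every enzyme and every recognition-window placement covering the
    SNP's diagnostic base, primer placements in either orientation are
    tried whose 3' end lies within ``max_three_prime_distance`` nt of the
    window and whose enforced mismatches (never at the 3' terminus)
    complete the site on the wild allele only.  Candidates must pass
    ``validate_assay`` on all alleles.  The result is ranked by fewest
    mismatches, then largest fragment-size difference, then shortest
    amplicon, with remaining ties broken by genomic position, so the order
    is reproducible.
    """
    validate_sequence(template, concrete=True)
    if not enzymes:
        raise InputError("enzyme table is empty")
    if not (1 <= snp.position and
            snp.position + len(snp.wild_codon) - 1 <= len(template)):
        raise InputError("SNP codon lies outside the template")

    cons = constraints
    wild_template = snp.apply(template, snp.wild_codon)
    templates = snp.allele_templates(template)
    D = snp.diagnostic_position
    n = len(template)
    results: list[tuple[tuple, AssayDesign]] = []

    for enzyme in enzymes:
        P = enzyme.recognition.upper()
        L = len(P)
        for w in range(max(1, D - L + 1), min(D, n - L + 1) + 1):
            window = range(w, w + L)
            # wild base at the diagnostic position must itself satisfy the
            # pattern: enforcing it would erase the allele difference.
            if not iupac_match(P[D - w], wild_template[D - 1]):
                continue
            needed = [
                t for t in window
                if not iupac_match(P[t - w], wild_template[t - 1])
            ]
            if D in needed or len(needed) > cons.max_mismatches:
                continue
            # every mutant allele must break the (enforced) site
            def destroyed(mutant: str) -> bool:
                mt = snp.apply(template, mutant)
                for t in window:
                    base = (_concrete_base(P[t - w]) if t in needed
                            else mt[t - 1].upper())
                    if not iupac_match(P[t - w], base):
                        return True
                return False
            if not all(destroyed(m) for m in snp.mutant_codons):
                continue

            for orientation in ("forward", "reverse"):
                d = cons.max_three_prime_distance
                for t3 in range(w - d, w + L + d):
                    cand = _try_candidate(
                        template, wild_template, templates, snp, enzyme,
                        w, needed, orientation, t3, cons, policy,
                    )
                    if cand is None:
                        continue
                    key = (
                        cand.n_mismatches,
                        -cand.fragment_diff,
                        cand.amplicon_length,
                        enzyme.name,
                        w,
                        orientation,
                        t3,
                    )
                    results.append((key, cand))

    results.sort(key=lambda kv: kv[0])
    return [design for _, design in results]


def _try_candidate(template: str, wild_template: str,
                   templates: Mapping[str, str], snp: SnpSpec,
                   enzyme: Enzyme, w: int, needed: Sequence[int],
                   orientation: str, t3: int, cons: DesignConstraints,
                   policy: AnnealingPolicy) -> AssayDesign | None:
    """Build and vet one (window, orientation, 3'-end) design candidate."""
    core = cons.core_length
    n = len(template)
    if orientation == "forward":
        lo, hi = t3 - core + 1, t3
    else:
        lo, hi = t3, t3 + core - 1
    if lo < 1 or hi > n:
        return None
    if any(not (lo <= t <= hi) or t == t3 for t in needed):
        return None
    # footprint in top-strand sense, with enforced bases substituted
    P = enzyme.recognition.upper()
    top = list(wild_template[lo - 1:hi].upper())
    for t in needed:
        top[t - lo] = _concrete_base(P[t - w])
    top_seq = "".join(top)
    core_seq = top_seq if orientation == "forward" else revcomp(top_seq)
    dcaps = Primer("dCAPS", cons.tail.lower() + core_seq, orientation)

    plen = min(cons.partner_length, n)
    if orientation == "reverse":
        partner = Primer("partner-F", template[:plen].upper(), "forward")
        span = hi + len(cons.tail)
    else:
        partner = Primer("partner-R", revcomp(template[n - plen:]).upper(),
                         "reverse")
        span = (n - lo + 1) + len(cons.tail)
    if span > cons.max_amplicon:
        return None
    design = AssayDesign(
        forward=partner,
        dcaps=dcaps,
        enzyme=enzyme,
        snp=snp,
        max_amplicon=cons.max_amplicon,
    )
    try:
        report = validate_assay(design, templates, policy)
    except PrimingError:
        return None
    if not report.passed:
        return None
    design = characterize_assay(design, templates, policy)
    if design.fragment_diff < cons.min_fragment_diff:
        return None
    return design


# ---------------------------------------------------------------------------
# File formats

PRIMER_TABLE_COLUMNS = ("name", "orientation", "sequence")


def read_primer_table(path: str | Path) -> list[Primer]:
    """Read a TSV primer table (case-preserving sequences)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != PRIMER_TABLE_COLUMNS:
            raise InputError(
                f"primer table must have columns {PRIMER_TABLE_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        return [
            Primer(row["name"], row["sequence"], row["orientation"])
            for row in reader
        ]


def write_primer_table(primers: Sequence[Primer], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PRIMER_TABLE_COLUMNS)
        for p in primers:
            writer.writerow([p.name, p.orientation, p.seq])


def design_to_json(design: AssayDesign) -> str:
    """Serialize an assay bundle for downstream stages."""
    doc = {
        "forward": {"name": design.forward.name, "seq": design.forward.seq,
                    "orientation": design.forward.orientation},
        "dcaps": {"name": design.dcaps.name, "seq": design.dcaps.seq,
                  "orientation": design.dcaps.orientation},
        "enzyme": {"name": design.enzyme.name,
                   "recognition": design.enzyme.recognition,
                   "cut_top": design.enzyme.cut_top,
                   "cut_bottom": design.enzyme.cut_bottom},
        "snp": {"codon": design.snp.codon, "position": design.snp.position,
                "wild_codon": design.snp.wild_codon,
                "mutant_codons": list(design.snp.mutant_codons)},
        "max_amplicon": design.max_amplicon,
        "amplicon_length": design.amplicon_length,
        "diagnostic_interval": design.diagnostic_interval,
        "wild_fragments": design.wild_fragments,
        "n_mismatches": design.n_mismatches,
        "fragment_diff": design.fragment_diff,
    }
    return json.dumps(doc, indent=2)


def design_from_json(text: str) -> AssayDesign:
    doc = json.loads(text)
    return AssayDesign(
        forward=Primer(**doc["forward"]),
        dcaps=Primer(**doc["dcaps"]),
        enzyme=Enzyme(**doc["enzyme"]),
        snp=SnpSpec(
            codon=doc["snp"]["codon"], position=doc["snp"]["position"],
            wild_codon=doc["snp"]["wild_codon"],
            mutant_codons=tuple(doc["snp"]["mutant_codons"]),
        ),
        max_amplicon=doc["max_amplicon"],
        amplicon_length=doc["amplicon_length"],
        diagnostic_interval=tuple(doc["diagnostic_interval"])
        if doc["diagnostic_interval"] else None,
        wild_fragments=tuple(doc["wild_fragments"])
        if doc["wild_fragments"] else None,
        n_mismatches=doc["n_mismatches"],
        fragment_diff=doc["fragment_diff"],
    )
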