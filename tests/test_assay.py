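"""Assay validation and dCAPS design enumeration."""

import dataclasses
import itertools

import pytest

from herbdcaps.assay import (
    AssayDesign,
    DesignConstraints,
    Primer,
    SnpSpec,
    design_dcaps,
    design_from_json,
    design_to_json,
    read_primer_table,
    validate_assay,
    write_primer_table,
)
from herbdcaps.seqcore import Enzyme, InputError, revcomp


class TestPrimer:
    def test_printed_primers_round_trip(self, ref):
        p27, pns, p34 = (ref.primers[n] for n in
                         ("ACVII27", "ACVII-NspIR", "ACVII34R"))
        assert (len(p27), len(p27.tail)) == (25, 0)
        assert (len(pns), len(pns.tail), len(pns.core)) == (40, 10, 30)
        assert (len(p34), len(p34.tail)) == (27, 0)
        assert pns.tail == "gccctagaat"

    def test_tail_must_be_prefix(self):
        with pytest.raises(InputError, match="tail"):
            Primer("bad", "ACGTacgtACGT", "forward")

    def test_table_round_trip_preserves_case(self, tmp_path, ref):
        path = tmp_path / "primers.tsv"
        primers = list(ref.primers.values())
        write_primer_table(primers, path)
        assert read_primer_table(path) == primers


class TestSnpSpec:
    def test_diagnostic_position_is_first_codon_base(self, ref):
        assert ref.snp.wild_codon == "ATA"
        assert ref.snp.mutant_codons == ("CTA", "TTA")
        assert ref.snp.diagnostic_offset == 0
        assert ref.snp.diagnostic_position == 87

    def test_requires_a_distinguishing_base(self):
        with pytest.raises(InputError):
            SnpSpec(1, 1, "ATA", ("ATA",))

    def test_allele_templates_differ_only_at_codon(self, ref):
        wild = ref.templates["ATA"]
        alleles = ref.snp.allele_templates(wild)
        for codon, seq in alleles.items():
            assert seq[86:89] == codon
            assert seq[:86] == wild[:86] and seq[89:] == wild[89:]


class TestValidateAssay:
    def test_packaged_assay_passes_all_checks(self, ref):
        report = validate_assay(ref.design, ref.templates)
        assert report.passed, str(report)
        names = {c.name for c in report.checks}
        assert "diagnostic-site-on-wild" in names
        assert {"no-site-on-mutant[CTA]", "no-site-on-mutant[TTA]"} <= names

    def test_reverted_mismatch_fails_wild_site_check(self, ref):
        dcaps = ref.primers["ACVII-NspIR"]
        template = ref.templates["ATA"]
        reverted_core = (dcaps.core[:-2]
                         + revcomp(template[88]).upper() + dcaps.core[-1])
        design = dataclasses.replace(
            ref.design, dcaps=Primer("reverted", dcaps.tail + reverted_core,
                                     "reverse"))
        report = validate_assay(design, ref.templates)
        assert not report.passed
        assert any(c.name == "diagnostic-site-on-wild" for c in report.failures())

    def test_oversized_amplicon_fails_size_check(self, ref):
        design = dataclasses.replace(ref.design, max_amplicon=100)
        report = validate_assay(design, ref.templates)
        failed = {c.name for c in report.failures()}
        assert failed == {f"amplicon-size[{a}]" for a in ref.snp.alleles}

    def test_wrong_allele_keys_raise(self, ref):
        with pytest.raises(InputError):
            validate_assay(ref.design, {"ATA": ref.templates["ATA"]})


class TestDesignDcaps:
    def test_reproduces_printed_assay_geometry(self, ref):
        """m=1, d=3 on the fixture finds the published primer exactly."""
        wild = ref.templates["ATA"]
        designs = design_dcaps(wild, ref.snp, ref.enzymes)
        assert designs, "expected at least one candidate"
        top = designs[0]
        assert top.enzyme.name == "NspI"
        assert top.dcaps.seq == ref.primers["ACVII-NspIR"].seq
        assert top.n_mismatches == 1
        # single mismatch at the penultimate primer position
        assert top.wild_fragments == (85, 42)
        assert top.amplicon_length == 127
        # every returned design passes validation (self-consistency)
        for d in designs:
            assert validate_assay(
                d, ref.snp.allele_templates(wild)).passed

    def test_empty_enzyme_table_is_an_input_error(self, ref):
        with pytest.raises(InputError, match="empty"):
            design_dcaps(ref.templates["ATA"], ref.snp, [])

    def test_impossible_neighbourhood_yields_empty_list(self):
        template = "AAAAAAAAAAAAAAAAAAAAATTAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
        snp = SnpSpec(8, 22, "TTA", ("CTA",))
        enzymes = [Enzyme("EcoRI", "GAATTC", 1, 5),
                   Enzyme("BamHI", "GGATCC", 1, 5)]
        cons = DesignConstraints(core_length=12, partner_length=8, tail="",
                                 max_mismatches=1)
        assert design_dcaps(template, snp, enzymes, cons) == []

    def test_relaxing_constraints_never_shrinks_candidates(self, toy):
        template, snp, enzymes = toy
        keys = {}
        for m, d in [(0, 1), (1, 1), (1, 3), (1, 5)]:
            cons = DesignConstraints(
                core_length=12, partner_length=8, tail="",
                max_mismatches=m, max_three_prime_distance=d)
            keys[(m, d)] = {
                (x.dcaps.seq, x.dcaps.orientation, x.enzyme.name)
                for x in design_dcaps(template, snp, enzymes, cons)
            }
        assert keys[(0, 1)] <= keys[(1, 1)] <= keys[(1, 3)] <= keys[(1, 5)]

    @pytest.fixture
    def toy(self):
        """40-nt template with an EcoRI near-site around a codon SNP.

        Positions 18-23 read GA|ATT|G for the wild codon ATT at 20-22:
        enforcing C at 23 completes GAATTC on the wild allele only (mutant
        codon CTT breaks the site at position 20).
        """
        template = ("TACGCTTCAGTCCGTC"           # 1-16 (aperiodic filler)
                    + "TGA"                      # 17-19 (18-19 = 'GA')
                    + "ATT"                      # codon at 20-22
                    + "G"                        # 23: needs enforcement to C
                    + "CATCCGTTGCAGGTCTA")       # 24-40
        assert len(template) == 40 and template[17:19] == "GA"
        snp = SnpSpec(7, 20, "ATT", ("CTT",))
        return template, snp, [Enzyme("EcoRI", "GAATTC", 1, 5)]

    def test_matches_brute_force_oracle_on_toy(self, toy):
        template, snp, enzymes = toy
        cons = DesignConstraints(core_length=12, partner_length=8, tail="",
                                 max_mismatches=1, max_three_prime_distance=3)
        got = {
            (d.dcaps.seq, d.dcaps.orientation, d.forward.seq,
             d.amplicon_length, d.wild_fragments)
            for d in design_dcaps(template, snp, enzymes, cons)
        }
        expected = brute_force_designs(template, snp, enzymes[0], cons)
        assert got == expected
        assert got, "toy template should admit at least one design"


def brute_force_designs(template, snp, enzyme, cons):
    """Independent enumeration oracle: try every (window, orientation,
    3'-end, mismatch-set) combination with naive string checks."""
    P = enzyme.recognition.upper()
    L = len(P)
    n = len(template)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    match = {"A": "A", "C": "C", "G": "G", "T": "T",
             "R": "AG", "Y": "CT", "N": "ACGT"}
    alleles = {c: snp.apply(template, c).upper() for c in snp.alleles}
    wild = alleles[snp.wild_codon]
    D = snp.diagnostic_position
    out = set()
    for w in range(1, n - L + 2):
        if not (w <= D <= w + L - 1):
            continue
        for orientation in ("forward", "reverse"):
            for t3 in range(1, n + 1):
                if orientation == "forward":
                    lo, hi = t3 - cons.core_length + 1, t3
                else:
                    lo, hi = t3, t3 + cons.core_length - 1
                if lo < 1 or hi > n:
                    continue
                if min(abs(t3 - w), abs(t3 - (w + L - 1))) > \
                        cons.max_three_prime_distance and not \
                        (w <= t3 <= w + L - 1):
                    continue
                # enforceable positions: inside footprint, not the 3' end
                enforceable = [t for t in range(lo, hi + 1) if t != t3]
                for k in range(cons.max_mismatches + 1):
                    for mm in itertools.combinations(enforceable, k):
                        cand = _vet(template, alleles, wild, snp, enzyme,
                                    P, L, w, orientation, t3, lo, hi, mm,
                                    cons, comp, match)
                        if cand:
                            out.add(cand)
    return out


def _vet(template, alleles, wild, snp, enzyme, P, L, w, orientation, t3,
         lo, hi, mm, cons, comp, match):
    # enforced top-strand bases realize the pattern at window positions
    top = list(wild[lo - 1:hi])
    for t in mm:
        if not (w <= t <= w + L - 1):
            return None
        top[t - lo] = min(match[P[t - w]])
    top = "".join(top)
    core = top if orientation == "forward" else \
        "".join(comp[b] for b in reversed(top))
    # per-allele annealing: <=1 total mismatch, 3' base perfect
    products = {}
    for codon, seq in alleles.items():
        window = seq[lo - 1:hi]
        diffs = [i for i in range(len(top)) if top[i] != window[i]]
        term = len(top) - 1 if orientation == "forward" else 0
        if len(diffs) > 1 or term in diffs:
            return None
        if orientation == "reverse":
            product = seq[:lo - 1] + top  # amplicon = template start .. hi
        else:
            product = top + seq[hi:]      # amplicon = lo .. template end
        products[codon] = product
    span = len(products[snp.wild_codon])
    if span > cons.max_amplicon:
        return None
    # site scan per allele
    def sites(seq):
        return [i + 1 for i in range(len(seq) - L + 1)
                if all(seq[i + j] in match[P[j]] for j in range(L))]
    site_shift = lo - 1 if orientation == "forward" else 0
    Dp = snp.diagnostic_position - site_shift
    wild_sites = sites(products[snp.wild_codon])
    diag = [p for p in wild_sites if p <= Dp <= p + L - 1]
    if len(diag) < 1 or len(wild_sites) != len(diag):
        return None
    for codon in snp.mutant_codons:
        if sites(products[codon]):
            return None
    # partner primer and primer-strand fragment sizes (tail empty in toys):
    # a reverse dCAPS primer reads sizes off the bottom strand, a forward
    # one off the top strand
    if orientation == "reverse":
        partner = template[:cons.partner_length].upper()
        cut = [p + enzyme.cut_bottom - 1 for p in diag]
    else:
        partner = "".join(
            comp[b] for b in reversed(template[-cons.partner_length:].upper()))
        cut = [p + enzyme.cut_top - 1 for p in diag]
    frags = tuple(sorted(
        (b - a for a, b in zip([0] + sorted(cut), sorted(cut) + [span])),
        reverse=True))
    if span - max(frags) < cons.min_fragment_diff:
        return None
    return (core, orientation, partner, span, frags)


def test_design_json_round_trip(ref):
    doc = design_to_json(ref.design)
    assert design_from_json(doc) == ref.design
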