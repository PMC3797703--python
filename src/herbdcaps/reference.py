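"""Packaged reference fixture and demo cohort tables.

The study's assay was designed against the Alopecurus myosuroides ACCase
coding sequence.  The package must run self-contained, so
``build_reference_fixture`` constructs a *synthetic* template that is
consistent with every printed constraint of the assay: the printed primer
sequences anneal with the printed geometry, the dCAPS product is 127 nt
with NspI fragments of 85 and 42 nt (primer strand) on the wild allele and
no cut on either resistant allele, and the sequencing product is 175 nt.
Filler bases outside the constrained segments are drawn from a seeded
generator and rejection-sampled so no allele gains a spurious NspI site.

``build_demo_cohort`` produces synthetic specimen/call tables whose margins
equal the study's published cohort totals (734 specimens, 685 genotyped,
428 collected before 1900, 108 before 1850, 56 undated, one confirmed
heterozygote collected in 1888); individual rows are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay as assay_mod
from . import pcr_digest, seqcore
from .assay import AssayDesign, Primer, SnpSpec, characterize_assay, validate_assay
from .pcr_digest import PrimingError, build_amplicon, digest
from .seqcore import NSPI, CodingCoordinateMap, Enzyme, revcomp

ACVII27 = Primer("ACVII27", "CACAAGATGCAGCTAGATAGTGGCG", "forward")
ACVII_NSPIR = Primer(
    "ACVII-NspIR", "gccctagaatAGGCACTGGCAATAGCAGCACTTCCATGCA", "reverse"
)
ACVII34R = Primer("ACVII34R", "TTCCAACAGTTCGTCCAGTAACGAATG", "reverse")

WILD_CODON = "ATA"
MUTANT_CODONS = ("CTA", "TTA")

#: A small default enzyme table: the assay enzyme plus common 6-cutters
#: for design searches.
DEFAULT_ENZYMES = [
    NSPI,
    Enzyme("EcoRI", "GAATTC", 1, 5),
    Enzyme("BamHI", "GGATCC", 1, 5),
    Enzyme("HindIII", "AAGCTT", 1, 5),
    Enzyme("PstI", "CTGCAG", 5, 1),
]

# Geometry of the reconstructed assay on the 175-nt template (1-based):
# the forward primer occupies 1-25, the dCAPS primer core pairs with
# 88-117 (3' terminus at 88, enforced base at 89), the SNP codon sits at
# 87-89, the two template bases completing the recognition site at 85-86,
# and the reverse sequencing primer at 149-175.
_CODON_POS = 87
_REGION_LEN = 175


@dataclass(frozen=True)
class ReferenceFixture:
    """Synthetic templates + the printed primers and enzyme table."""

    templates: dict[str, str]
    primers: dict[str, Primer]
    enzymes: list[Enzyme]
    snp: SnpSpec
    design: AssayDesign
    #: reading-frame bookkeeping: local codon coordinates need a 2-nt
    #: offset to line up with the assay geometry
    coding_map: CodingCoordinateMap

    @property
    def seq_primer(self) -> Primer:
        """Reverse primer of the long sequencing-confirmation amplicon."""
        return self.primers["ACVII34R"]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit templates.fasta, primers.tsv and enzymes.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "templates": out / "templates.fasta",
            "primers": out / "primers.tsv",
            "enzymes": out / "enzymes.tsv",
        }
        seqcore.write_fasta(
            {f"template_{codon}": seq for codon, seq in self.templates.items()},
            paths["templates"],
        )
        assay_mod.write_primer_table(list(self.primers.values()), paths["primers"])
        seqcore.write_enzyme_table(self.enzymes, paths["enzymes"])
        return paths


def _assemble_region(filler1: str, codon: str, filler2: str) -> str:
    """The 175-nt constrained region for one allele codon."""
    dcaps_core_rc = revcomp(ACVII_NSPIR.core).upper()  # pairs local 88-117
    seq_core_rc = revcomp(ACVII34R.core).upper()       # pairs local 149-175
    region = (
        ACVII27.seq                 # 1-25
        + filler1                   # 26-84 (59 nt)
        + "GC"                      # 85-86: complete the site 5' of the codon
        + codon                     # 87-89
        + dcaps_core_rc[2:]         # 90-117 (28 nt; 88-89 belong to the codon)
        + filler2                   # 118-148 (31 nt)
        + seq_core_rc               # 149-175
    )
    assert len(region) == _REGION_LEN
    return region


def _verify_fixture(templates: dict[str, str], snp: SnpSpec) -> bool:
    """Engine-level check of all fixture invariants."""
    for seq in templates.values():
        if seqcore.find_sites(seq, NSPI):
            return False
    try:
        for codon, template in templates.items():
            amp = build_amplicon(template, ACVII27, ACVII_NSPIR)
            if amp is None or len(amp) != 127:
                return False
            res = digest(amp, NSPI)
            if codon == snp.wild_codon:
                if (res.bottom_fragments != (85, 42)
                        or amp.enforced_positions != (89,)):
                    return False
            elif res.classification != "undigested":
                return False
            seq_amp = build_amplicon(template, ACVII27, ACVII34R)
            if seq_amp is None or len(seq_amp) != 175:
                return False
    except PrimingError:
        return False
    return True


def build_reference_fixture(seed: int = 0) -> ReferenceFixture:
    """Deterministically construct the packaged synthetic fixture.

    Filler bases are drawn from a generator seeded with *seed* and
    rejection-sampled until every invariant holds (a handful of draws in
    practice); if sampling somehow exhausts its cap, a fixed low-complexity
    filler is used instead.  Identical seeds give byte-identical templates.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def draw(k: int) -> str:
        return "".join(rng.choice(bases, size=k))

    snp = SnpSpec(1781, _CODON_POS, WILD_CODON, MUTANT_CODONS)

    chosen: dict[str, str] | None = None
    for _ in range(200):
        filler1, filler2 = draw(59), draw(31)
        templates = {
            codon: _assemble_region(filler1, codon, filler2)
            for codon in (WILD_CODON, *MUTANT_CODONS)
        }
        if _verify_fixture(templates, snp):
            chosen = templates
            break
    if chosen is None:
        # deterministic fallback: low-complexity filler free of CATG cores
        f1 = ("AACCTT" * 10)[:59]
        f2 = ("AACCTT" * 6)[:31]
        chosen = {
            codon: _assemble_region(f1, codon, f2)
            for codon in (WILD_CODON, *MUTANT_CODONS)
        }
        if not _verify_fixture(chosen, snp):
            raise RuntimeError("reference fixture construction failed")

    design = AssayDesign(
        forward=ACVII27, dcaps=ACVII_NSPIR, enzyme=NSPI, snp=snp,
        max_amplicon=300,
    )
    design = characterize_assay(design, snp.allele_templates(chosen[WILD_CODON]))
    report = validate_assay(design, {c: chosen[c] for c in snp.alleles})
    if not report.passed:  # pragma: no cover - guarded by _verify_fixture
        raise RuntimeError(f"fixture assay failed validation:\n{report}")
    return ReferenceFixture(
        templates=chosen,
        primers={p.name: p for p in (ACVII27, ACVII_NSPIR, ACVII34R)},
        enzymes=list(DEFAULT_ENZYMES),
        snp=snp,
        design=design,
        coding_map=CodingCoordinateMap(offset=2),
    )


# ---------------------------------------------------------------------------
# Demo cohort

_HERBARIA = (("Geneva", 343), ("Montpellier", 304), ("Dijon", 87))
_OTHER_COUNTRIES = ("Germany", "Switzerland", "Italy", "Spain", "UK",
                    "Belgium", "Netherlands", "Austria", "Sweden", "Portugal")


def build_demo_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic specimen metadata + calls with the study's exact margins.

    734 specimens; 108 dated 1788-1849, 320 dated 1851-1899, 250 dated
    1900-1975, 56 undated; 49 amplification failures of which 12 fall
    before 1851; one sequence-confirmed RS heterozygote dated 1888.
    Individual rows (ids, localities, exact years) are fabricated
    deterministically and stand in for the study's specimen-level table.
    """
    n = 734
    years: list[float] = []
    for i in range(108):
        years.append(1788 + (i * 61) // 107)          # 1788..1849
    for i in range(320):
        years.append(1851 + (i * 48) // 319)          # 1851..1899
    for i in range(250):
        years.append(1900 + (i * 75) // 249)          # 1900..1975
    years.extend([float("nan")] * 56)

    carrier_idx = next(i for i, y in enumerate(years) if y == 1888)

    fail_idx: set[int] = set(range(0, 108, 9))        # 12 pre-1851 failures
    i = 110
    while len(fail_idx) < 49:
        if i != carrier_idx:
            fail_idx.add(i)
        i += 17

    herbarium = [name for name, count in _HERBARIA for _ in range(count)]
    countries: list[str | None] = ["France"] * 380
    for j in range(n - 380 - 96):
        countries.append(_OTHER_COUNTRIES[j % len(_OTHER_COUNTRIES)])
    countries.extend([None] * 96)

    ids = [f"D{i + 1:04d}" for i in range(n)]
    metadata = pd.DataFrame({
        "id": ids,
        "herbarium": herbarium,
        "country": countries,
        "year": years,
    })

    rows = []
    for i, sid in enumerate(ids):
        if i in fail_idx:
            rows.append((sid, "fail", "none", "dcaps:fail"))
        elif i == carrier_idx:
            rows.append((sid, "RS", "sequence-confirmed",
                         "dcaps:RS;dcaps:RS;dcaps-reextract:RS;sequence:A/C"))
        else:
            rows.append((sid, "SS", "none", "dcaps:SS"))
    calls = pd.DataFrame(rows, columns=["id", "call", "status", "evidence"])
    return metadata, calls
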