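"""Nucleotide-sequence primitives for dCAPS assay simulation.

Sequences are plain Python strings over the IUPAC nucleotide alphabet.
Case is preserved as metadata: lowercase marks bases that are not expected
to pair with the template (primer tails, as conventionally printed in
primer tables), but matching and complementation are always
case-insensitive.

Coordinates are 1-based and intervals are closed throughout the package,
matching the inclusive convention of molecular-biology papers ("nucleotides
5257 to 5383" is a 127-nt span).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    """Malformed user input (bad sequence characters, bad tables, ...)."""


class DomainError(ValueError):
    """Arguments outside an operation's mathematical domain."""


#: IUPAC code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONCRETE_BASES = frozenset("ACGT")


def validate_sequence(s: str, *, concrete: bool = False) -> str:
    """Check *s* against the IUPAC alphabet, returning it unchanged.

    With ``concrete=True`` only A/C/G/T are accepted (digestion and
    annealing are defined only on concrete sequences).  Errors name the
    1-based position of the first offending character.
    """
    allowed = CONCRETE_BASES if concrete else IUPAC_SETS.keys()
    for i, ch in enumerate(s):
        if ch.upper() not in allowed:
            kind = "concrete nucleotide" if concrete else "IUPAC nucleotide"
            raise InputError(
                f"invalid {kind} {ch!r} at position {i + 1}"
            )
    return s


def complement(s: str) -> str:
    """Base-wise complement, IUPAC-aware, case preserved per character."""
    validate_sequence(s)
    out = []
    for ch in s:
        comp = _COMPLEMENT[ch.upper()]
        out.append(comp.lower() if ch.islower() else comp)
    return "".join(out)


def revcomp(s: str) -> str:
    """Reverse complement of an IUPAC string; an involution.

    Case travels with each base, so the reverse complement of a tailed
    primer keeps its tail lowercase.
    """
    return complement(s)[::-1]


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if concrete *base* is one of the bases *pattern_char* denotes."""
    return base.upper() in IUPAC_SETS[pattern_char.upper()]


def matches_at(seq: str, pattern: str, start0: int) -> bool:
    """Match an IUPAC *pattern* against concrete *seq* at 0-based *start0*."""
    if start0 < 0 or start0 + len(pattern) > len(seq):
        return False
    return all(
        iupac_match(p, b) for p, b in zip(pattern, seq[start0:start0 + len(pattern)])
    )


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease as a recognition pattern plus cut offsets.

    ``cut_top`` and ``cut_bottom`` follow the REBASE-style "cut after
    offset" convention: the top strand is cleaved after ``cut_top`` bases
    (5'->3' from the site start), the bottom strand after ``cut_bottom``
    bases measured on the same top-strand coordinate.  NspI is
    ``Enzyme("NspI", "RCATGY", 5, 1)``: RCATG^Y on top, R^CATGY on bottom,
    leaving a 4-nt 3' overhang.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        validate_sequence(self.recognition)
        L = len(self.recognition)
        if not (0 <= self.cut_top <= L and 0 <= self.cut_bottom <= L):
            raise InputError(
                f"enzyme {self.name}: cut offsets must lie in [0, {L}]"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def is_palindromic(self) -> bool:
        """True if the recognition pattern equals its own reverse complement."""
        return revcomp(self.recognition).upper() == self.recognition.upper()


NSPI = Enzyme("NspI", "RCATGY", 5, 1)


def find_sites(s: str, e: Enzyme) -> list[int]:
    """All 1-based start positions of *e*'s recognition site in *s*.

    *s* must be concrete (ambiguity codes have no defined digestion).  The
    top strand is scanned directly; for enzymes whose pattern is not its
    own reverse complement the bottom strand is scanned too and positions
    are reported as top-strand window starts, deduplicated.
    """
    validate_sequence(s, concrete=True)
    pattern = e.recognition.upper()
    su = s.upper()
    L = len(pattern)
    hits = {
        i + 1
        for i in range(len(su) - L + 1)
        if matches_at(su, pattern, i)
    }
    if not e.is_palindromic():
        rc = revcomp(pattern)
        hits |= {
            i + 1
            for i in range(len(su) - L + 1)
            if matches_at(su, rc, i)
        }
    return sorted(hits)


@dataclass(frozen=True)
class CodingCoordinateMap:
    """Maps codon indices to nucleotide intervals in a reference frame.

    ``offset`` is the number of nucleotides preceding the reading-frame
    origin in the reference coordinate system, so codon ``c`` occupies the
    closed interval ``[3c - 2 + offset, 3c + offset]``.
    """

    offset: int = 0


def map_codon(c: int, m: CodingCoordinateMap) -> tuple[int, int]:
    """Closed nucleotide interval of codon *c* under map *m* (1-based)."""
    if c < 1:
        raise DomainError(f"codon index must be >= 1, got {c}")
    return (3 * c - 2 + m.offset, 3 * c + m.offset)


# ---------------------------------------------------------------------------
# File formats

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    """Write {id: sequence} pairs as FASTA, 60-column wrapped."""
    items: Iterator[tuple[str, str]]
    items = records.items() if isinstance(records, dict) else iter(records)
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


ENZYME_TABLE_COLUMNS = ("name", "recognition", "cut_top", "cut_bottom")


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Read a TSV enzyme table (header: name recognition cut_top cut_bottom)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != ENZYME_TABLE_COLUMNS:
            raise InputError(
                f"enzyme table must have columns {ENZYME_TABLE_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        out = []
        for row in reader:
            try:
                out.append(Enzyme(row["name"], row["recognition"],
                                  int(row["cut_top"]), int(row["cut_bottom"])))
            except (TypeError, ValueError) as exc:
                raise InputError(f"bad enzyme row {row}: {exc}") from exc
    return out


def write_enzyme_table(enzymes: Sequence[Enzyme], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ENZYME_TABLE_COLUMNS)
        for e in enzymes:
            writer.writerow([e.name, e.recognition, e.cut_top, e.cut_bottom])
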