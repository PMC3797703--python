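"""Specimen-level genotyping procedure with contamination controls.

Herbarium genotyping is paranoid by design: extractions are batched with
blank extractions (no tissue) and PCR negative controls, any amplicon in a
control invalidates the whole batch, and a resistant-looking lane is never
reported as a genotype until it has survived a repeat on the same extract,
a repeat from an independent re-extraction, and direct sequencing of the
diagnostic codon.  ``confirm_workflow`` implements that decision tree;
``run_batch`` applies the control gate and flags candidates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .pcr_digest import LANE_FAIL, LANE_RR, LANE_RS, LANE_SS
from .seqcore import InputError

log = logging.getLogger(__name__)

#: lane patterns that contain undigested (mutant-allele) product
MUTANT_PATTERNS = frozenset({LANE_RS, LANE_RR})

CALLS = ("RR", "RS", "SS", "fail", "invalid")
STATUSES = (
    "none", "dcaps-repeated", "re-extracted", "sequence-confirmed",
    "not-reproduced",
)


class WorkflowConfigError(InputError):
    """Batch layout violating the control scheme."""


class OracleExhausted(RuntimeError):
    """The observation oracle cannot produce more data (no tissue left)."""


@dataclass(frozen=True)
class GenotypeCall:
    specimen_id: str
    call: str
    status: str = "none"
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise InputError(f"unknown call {self.call!r}")
        if self.status not in STATUSES:
            raise InputError(f"unknown status {self.status!r}")
        if self.call in ("RR", "RS") and self.status != "sequence-confirmed":
            raise InputError(
                "a resistant call requires sequencing confirmation "
                f"({self.specimen_id}: {self.call}/{self.status})"
            )


@dataclass(frozen=True)
class BatchControls:
    """Control wells of one extraction/PCR series.

    ``blank_bands`` holds the observed band set of each blank extraction
    (one blank per series of up to 24 extractions); ``negative_bands``
    those of the no-DNA PCR controls (at least two per series).  The batch
    passes only if every control well shows no amplicon at all.
    """

    batch_id: str
    blank_bands: tuple[frozenset[int], ...]
    negative_bands: tuple[frozenset[int], ...]

    @property
    def passed(self) -> bool:
        return all(not b for b in (*self.blank_bands, *self.negative_bands))


@dataclass(frozen=True)
class Batch:
    controls: BatchControls
    #: specimen id -> initial lane pattern label
    lanes: Mapping[str, str] = field(default_factory=dict)


def run_batch(lanes: Mapping[str, str], controls: BatchControls,
              max_per_blank: int = 24, min_negatives: int = 2,
              ) -> tuple[list[GenotypeCall], list[tuple[str, str]]]:
    """Apply the control gate and triage one batch of lane observations.

    Returns final calls (SS / fail / invalid) plus the list of
    ``(specimen_id, pattern)`` candidates whose lanes contain undigested
    product and therefore enter the confirmation workflow.
    """
    if len(lanes) > max_per_blank * max(len(controls.blank_bands), 0):
        raise WorkflowConfigError(
            f"batch {controls.batch_id}: {len(lanes)} extractions but only "
            f"{len(controls.blank_bands)} blank(s); one blank is required "
            f"per {max_per_blank} extractions"
        )
    if len(controls.negative_bands) < min_negatives:
        raise WorkflowConfigError(
            f"batch {controls.batch_id}: at least {min_negatives} negative "
            "PCR controls are required"
        )
    calls: list[GenotypeCall] = []
    candidates: list[tuple[str, str]] = []
    if not controls.passed:
        log.warning("batch %s: control contamination, invalidating %d specimens",
                    controls.batch_id, len(lanes))
        for sid, pattern in lanes.items():
            calls.append(GenotypeCall(sid, "invalid",
                                      evidence=(f"dcaps:{pattern}",)))
        return calls, candidates
    for sid, pattern in lanes.items():
        if pattern == LANE_SS:
            calls.append(GenotypeCall(sid, "SS", evidence=(f"dcaps:{pattern}",)))
        elif pattern == LANE_FAIL:
            calls.append(GenotypeCall(sid, "fail",
                                      evidence=(f"dcaps:{pattern}",)))
        else:
            # RS / RR / ambiguous lanes all potentially contain a mutant
            # allele and must be confirmed
            log.info("batch %s: specimen %s is a candidate (%s)",
                     controls.batch_id, sid, pattern)
            candidates.append((sid, pattern))
    return calls, candidates


def sanger_call(allele_bases: tuple[str, str], wild: str = "A") -> str:
    """Direct-sequencing call at the diagnostic base of a diploid.

    Homozygotes yield a single base; heterozygotes a dual-peak call
    ``"X/Y"`` with the wild-type base listed first when present.
    """
    a, b = (x.upper() for x in allele_bases)
    if a == b:
        return a
    if wild in (a, b):
        other = b if a == wild else a
        return f"{wild}/{other}"
    return "/".join(sorted((a, b)))


def interpret_sanger(call: str, wild: str = "A") -> str:
    """Map a sequencing call at the diagnostic base to a genotype class."""
    bases = call.split("/")
    if len(bases) == 1:
        return "SS" if bases[0] == wild else "RR"
    return "RS" if wild in bases else "RR"


def confirm_workflow(specimen_id: str, initial_pattern: str,
                     oracle: Callable[[str], str],
                     repeats_same_extract: int = 1,
                     repeats_reextraction: int = 1,
                     wild_base: str = "A") -> GenotypeCall:
    """Run a candidate through the repeat-and-sequence decision tree.

    *oracle* produces observations on demand: requests ``"dcaps"`` (repeat
    on the same DNA extract) and ``"dcaps-reextract"`` (full repeat from a
    fresh leaf fragment) return a lane pattern label; ``"sequence"``
    returns the sequencing call at the diagnostic base of the long
    confirmation amplicon.  Any tier at which the resistant-looking
    pattern is not clearly reproduced ends the candidacy as a wild-type
    call.  A resistant genotype is only ever issued from the sequencing
    tier.  If the oracle is exhausted (no tissue left), the specimen is
    reported as a failure at whatever stage was reached.
    """
    evidence = [f"dcaps:{initial_pattern}"]
    status = "none"
    tiers = (
        ("dcaps", repeats_same_extract, "dcaps-repeated"),
        ("dcaps-reextract", repeats_reextraction, "re-extracted"),
    )
    try:
        for request, reps, reached in tiers:
            for _ in range(reps):
                obs = oracle(request)
                evidence.append(f"{request}:{obs}")
                if obs not in MUTANT_PATTERNS:
                    log.info("%s: pattern not reproduced at %s, calling SS",
                             specimen_id, request)
                    return GenotypeCall(specimen_id, "SS", "not-reproduced",
                                        tuple(evidence))
            status = reached
        seq = oracle("sequence")
    except OracleExhausted:
        log.info("%s: observation oracle exhausted at status %s",
                 specimen_id, status)
        return GenotypeCall(specimen_id, "fail", status, tuple(evidence))
    evidence.append(f"sequence:{seq}")
    genotype = interpret_sanger(seq, wild_base)
    log.info("%s: sequencing call %s -> %s", specimen_id, seq, genotype)
    return GenotypeCall(specimen_id, genotype, "sequence-confirmed",
                        tuple(evidence))


def genotype_batches(batches: Sequence[Batch],
                     oracle_factory: Callable[[str], Callable[[str], str]],
                     ) -> list[GenotypeCall]:
    """Call every specimen in a series of batches, confirming candidates."""
    calls: list[GenotypeCall] = []
    for batch in batches:
        finals, candidates = run_batch(batch.lanes, batch.controls)
        calls.extend(finals)
        for sid, pattern in candidates:
            calls.append(confirm_workflow(sid, pattern, oracle_factory(sid)))
    return calls


# ---------------------------------------------------------------------------
# File formats

LANE_CSV_COLUMNS = ("specimen", "observation_index", "pattern")
CALLS_CSV_COLUMNS = ("specimen", "call", "status", "evidence")


def write_lane_observations(rows: Iterable[tuple[str, int, str]],
                            path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LANE_CSV_COLUMNS)
        writer.writerows(rows)


def read_lane_observations(path: str | Path) -> list[tuple[str, int, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != LANE_CSV_COLUMNS:
            raise InputError(
                f"lane CSV must have columns {LANE_CSV_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        return [
            (row["specimen"], int(row["observation_index"]), row["pattern"])
            for row in reader
        ]


def write_calls(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CALLS_CSV_COLUMNS)
        for c in calls:
            writer.writerow([c.specimen_id, c.call, c.status,
                             ";".join(c.evidence)])


def read_calls(path: str | Path) -> list[GenotypeCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CALLS_CSV_COLUMNS:
            raise InputError(
                f"calls CSV must have columns {CALLS_CSV_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        return [
            GenotypeCall(row["specimen"], row["call"], row["status"],
                         tuple(e for e in row["evidence"].split(";") if e))
            for row in reader
        ]


def scripted_oracle(observations: Sequence[str]) -> Callable[[str], str]:
    """An oracle replaying a fixed observation list (for file-driven runs).

    Each request pops the next observation regardless of its kind; an
    empty script raises ``OracleExhausted``.
    """
    queue = list(observations)

    def oracle(request: str) -> str:
        if not queue:
            raise OracleExhausted(request)
        return queue.pop(0)

    return oracle
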