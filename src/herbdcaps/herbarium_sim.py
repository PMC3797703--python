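"""Synthetic herbarium cohort generator.

Emulates the observational process of a historical-specimen genotyping
study: diploid genotypes at Hardy-Weinberg proportions for a rare
resistance allele, amplification success declining weakly with specimen
age (logistic in collection year, calibrated to the study's overall and
pre-1851 success rates), post-mortem deamination miscalls (C->T and G->A
only) applied at the base-call layer, occasional transient "mixed-looking"
lanes on wild-type specimens, and optional contamination events that light
up blank-extraction controls.

All randomness flows from one seed through spawned generator streams, so a
cohort, its lane observations, and the confirmation-workflow observations
are jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from . import popstats, workflow
from .pcr_digest import LANE_FAIL, LANE_RS, LANE_SS, PrimingError, build_amplicon, classify_pattern, digest
from .reference import ReferenceFixture, build_reference_fixture
from .seqcore import InputError
from .workflow import Batch, BatchControls, GenotypeCall

_HERBARIA = ("Geneva", "Montpellier", "Dijon")
_HERBARIUM_P = (343 / 734, 304 / 734, 87 / 734)
_COUNTRIES = ("France", None, "Germany", "Switzerland", "Italy", "Spain", "UK")
# France and unknown-origin shares follow the published cohort; the
# remainder splits evenly over a few neighbouring countries.
_COUNTRY_P = (380 / 734, 96 / 734) + ((1.0 - 380 / 734 - 96 / 734) / 5,) * 5


@dataclass(frozen=True, kw_only=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults reproduce the published cohort: 734 specimens collected
    1788-1975 (eras weighted so ~14.7% predate 1851 and ~58.3% predate
    1900, with 7.6% undated), resistance allele frequency q = 7.3e-4 under
    Hardy-Weinberg, mean amplification success 93.3% (88.5% before 1851),
    deamination miscall rate 3e-4 per base call, and a transient
    mixed-lane artifact rate of 3/681 (so roughly four candidate lanes
    arise per ~685 successful specimens, of which the artifacts die on
    repetition).  Contamination is 0 by default: the study's controls were
    all clean; a positive rate exists for testing the control gate.
    """

    seed: int
    n: int = 734
    year_eras: tuple[tuple[int, int, float], ...] = (
        (1788, 1850, 0.159), (1851, 1899, 0.472), (1900, 1975, 0.369),
    )
    undated_share: float = 0.076
    q: float = 7.3e-4
    mutant_codon_split: tuple[tuple[str, float], ...] = (("CTA", 1.0),)
    overall_success: float = 0.933
    pre1851_success: float = 0.885
    miscall_rate: float = 3e-4
    ambiguous_rate: float = 3 / 681
    contamination_rate: float = 0.0
    batch_size: int = 24

    def __post_init__(self) -> None:
        rates = {
            "undated_share": self.undated_share, "q": self.q,
            "overall_success": self.overall_success,
            "pre1851_success": self.pre1851_success,
            "miscall_rate": self.miscall_rate,
            "ambiguous_rate": self.ambiguous_rate,
            "contamination_rate": self.contamination_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {value}")
        if self.n < 1:
            raise InputError("cohort size must be positive")
        if self.batch_size < 1:
            raise InputError("batch size must be positive")
        if abs(sum(w for _, w in self.mutant_codon_split) - 1.0) > 1e-9:
            raise InputError("mutant codon split must sum to 1")
        if abs(sum(w for _, _, w in self.year_eras) - 1.0) > 1e-9:
            raise InputError("year era weights must sum to 1")


def _year_pmf(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    years, probs = [], []
    for a, b, w in cfg.year_eras:
        span = np.arange(a, b + 1)
        years.append(span)
        probs.append(np.full(len(span), w / len(span)))
    return np.concatenate(years), np.concatenate(probs)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_success_model(cfg: CohortConfig) -> tuple[float, float]:
    """Logistic success-vs-year coefficients (a, b).

    Success probability is ``sigmoid(a + b * (year - 1900) / 100)``; the
    two coefficients are solved so that the expected success rate over the
    cohort's year distribution equals ``overall_success`` and the expected
    rate over pre-1851 years equals ``pre1851_success``.  A gentle slope
    rather than a step keeps the age trend weak, as observed.
    """
    years, probs = _year_pmf(cfg)
    z = (years - 1900.0) / 100.0
    pre = years < 1851
    if not pre.any() or pre.all():
        # degenerate era layout: match the overall rate only
        a = float(np.log(cfg.overall_success / (1 - cfg.overall_success)))
        return a, 0.0

    def equations(ab: np.ndarray) -> list[float]:
        p = _sigmoid(ab[0] + ab[1] * z)
        overall = float(np.dot(probs, p) / probs.sum())
        pre_mean = float(np.dot(probs[pre], p[pre]) / probs[pre].sum())
        return [overall - cfg.overall_success,
                pre_mean - cfg.pre1851_success]

    sol = optimize.root(equations, x0=np.array([2.6, 0.8]))
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"success-model calibration failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def simulate_degradation(base_calls: str, e: float,
                         rng: np.random.Generator | int) -> str:
    """Apply deamination-type miscalls to a string of base calls.

    Each C flips to T and each G to A independently with probability *e*;
    no other substitution ever occurs (in particular A and T are immune,
    so damage can never fabricate an A->C transversion).
    """
    if not 0.0 <= e <= 1.0:
        raise InputError(f"miscall rate must lie in [0, 1], got {e}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if e == 0.0 or not base_calls:
        return base_calls
    arr = np.frombuffer(base_calls.upper().encode("ascii"), dtype="S1").copy()
    hit = rng.random(len(arr)) < e
    arr[hit & (arr == b"C")] = b"T"
    arr[hit & (arr == b"G")] = b"A"
    return arr.tobytes().decode("ascii")


@dataclass
class SimulatedCohort:
    """A simulated specimen table plus its lane-observation process."""

    config: CohortConfig
    fixture: ReferenceFixture
    specimens: pd.DataFrame
    batches: list[Batch]
    success_coefficients: tuple[float, float]
    _genotypes: Mapping[str, tuple[str, str]] = field(repr=False, default_factory=dict)
    _lane_rng: np.random.Generator = field(repr=False, default=None)

    def draw_lane(self, specimen_id: str, artifact: bool = False) -> str:
        """Simulate one dCAPS lane for a specimen (fresh damage draw)."""
        genotype = self._genotypes[specimen_id]
        design = self.fixture.design
        fwd, rev = design.primer_pair
        frags = []
        for codon in genotype:
            template = self.fixture.templates[codon]
            degraded = simulate_degradation(
                template, self.config.miscall_rate, self._lane_rng
            )
            if degraded == template:
                frags.append(design.expected_patterns()[
                    "SS" if codon == design.snp.wild_codon else "RR"
                ])
                continue
            try:
                amp = build_amplicon(degraded, fwd, rev)
            except PrimingError:
                amp = None
            frags.append(
                None if amp is None
                else digest(amp, design.enzyme).fragments_for(
                    design.dcaps.orientation
                )
            )
        label = classify_pattern(
            frags,
            wild_fragments=design.wild_fragments,
            uncut_length=design.amplicon_length,
        ).label
        if artifact and label == LANE_SS and (
            self._lane_rng.random() < self.config.ambiguous_rate
        ):
            # transient mixed-looking lane on a wild-type specimen
            return LANE_RS
        return label

    def oracle(self, specimen_id: str) -> Callable[[str], str]:
        """Observation oracle for the confirmation workflow."""
        def produce(request: str) -> str:
            if request in ("dcaps", "dcaps-reextract"):
                return self.draw_lane(specimen_id, artifact=True)
            if request == "sequence":
                bases = []
                offset = self.fixture.snp.diagnostic_offset
                for codon in self._genotypes[specimen_id]:
                    read = simulate_degradation(
                        codon, self.config.miscall_rate, self._lane_rng
                    )
                    bases.append(read[offset])
                return workflow.sanger_call(
                    (bases[0], bases[1]),
                    wild=self.fixture.snp.wild_codon[offset],
                )
            raise InputError(f"unknown oracle request {request!r}")
        return produce


def simulate_cohort(cfg: CohortConfig,
                    fixture: ReferenceFixture | None = None) -> SimulatedCohort:
    """Draw a full cohort: specimens, genotypes, batches, and lanes."""
    if fixture is None:
        fixture = build_reference_fixture()
    cohort_ss, lane_ss, contam_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng = np.random.default_rng(cohort_ss)
    lane_rng = np.random.default_rng(lane_ss)
    contam_rng = np.random.default_rng(contam_ss)

    a, b = calibrate_success_model(cfg)
    years_support, years_p = _year_pmf(cfg)
    wild = fixture.snp.wild_codon
    mut_codons = [c for c, _ in cfg.mutant_codon_split]
    mut_p = np.array([w for _, w in cfg.mutant_codon_split])

    n = cfg.n
    ids = [f"S{i + 1:04d}" for i in range(n)]
    herbaria = rng.choice(_HERBARIA, size=n, p=_HERBARIUM_P)
    countries = rng.choice(np.array(_COUNTRIES, dtype=object), size=n,
                           p=_COUNTRY_P)
    latent_years = rng.choice(years_support, size=n, p=years_p / years_p.sum())
    undated = rng.random(n) < cfg.undated_share
    success_p = _sigmoid(a + b * (latent_years - 1900.0) / 100.0)
    amplifiable = rng.random(n) < success_p

    genotypes: dict[str, tuple[str, str]] = {}
    for sid in ids:
        alleles = []
        for _ in range(2):
            if rng.random() < cfg.q:
                alleles.append(mut_codons[int(rng.choice(len(mut_codons),
                                                         p=mut_p))])
            else:
                alleles.append(wild)
        # wild allele listed first for readability
        genotypes[sid] = tuple(sorted(alleles, key=lambda c: c != wild))

    specimens = pd.DataFrame({
        "id": ids,
        "herbarium": herbaria,
        "country": countries,
        "year": np.where(undated, np.nan, latent_years.astype(float)),
        "genotype": ["/".join(genotypes[sid]) for sid in ids],
        "amplifiable": amplifiable,
        "batch": [f"B{i // cfg.batch_size + 1:03d}" for i in range(n)],
    })

    cohort = SimulatedCohort(
        config=cfg, fixture=fixture, specimens=specimens, batches=[],
        success_coefficients=(a, b), _genotypes=genotypes, _lane_rng=lane_rng,
    )

    amplicon_len = fixture.design.amplicon_length
    for batch_id, group in specimens.groupby("batch", sort=True):
        contaminated = contam_rng.random() < cfg.contamination_rate
        controls = BatchControls(
            batch_id=str(batch_id),
            blank_bands=(
                frozenset([amplicon_len]) if contaminated else frozenset(),
            ),
            negative_bands=(frozenset(), frozenset()),
        )
        lanes: dict[str, str] = {}
        for sid, ok in zip(group["id"], group["amplifiable"]):
            lanes[sid] = (
                cohort.draw_lane(sid, artifact=True) if ok else LANE_FAIL
            )
        cohort.batches.append(Batch(controls=controls, lanes=lanes))
    return cohort


@dataclass
class StudyResult:
    cohort: SimulatedCohort
    calls: list[GenotypeCall]
    calls_frame: pd.DataFrame
    summary: dict


def run_study(cfg: CohortConfig,
              fixture: ReferenceFixture | None = None) -> StudyResult:
    """Simulate -> genotype (with confirmation) -> summarize, end to end."""
    cohort = simulate_cohort(cfg, fixture)
    calls = workflow.genotype_batches(cohort.batches, cohort.oracle)
    calls_frame = pd.DataFrame(
        [(c.specimen_id, c.call, c.status, ";".join(c.evidence))
         for c in calls],
        columns=["id", "call", "status", "evidence"],
    ).sort_values("id", ignore_index=True)
    metadata = cohort.specimens[["id", "herbarium", "country", "year"]]
    summary = popstats.summarize_cohort(metadata, calls_frame)
    try:
        table = popstats.success_by_age_table(metadata, calls_frame)
        if len(table) >= 2:
            chi = popstats.chisq_independence(table.to_numpy().T)
            summary["age_chisq"] = {
                "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value,
            }
    except popstats.DomainError:
        pass
    return StudyResult(cohort, calls, calls_frame, summary)
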