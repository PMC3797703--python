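# Methods

## The genotyping problem

`herbdcaps` models, end to end, the detection of a target-site
herbicide-resistance allele of acetyl-CoA carboxylase (ACCase), a
nuclear-encoded enzyme, in historical plant material. The resistance mutation is an
isoleucine-to-leucine substitution at ACCase codon 1781: the wild-type
codon is ATA, the resistant leucine codons are CTA or TTA, and the first
codon position is diagnostic (A in the wild type, C or T in the mutants).
Because the polymorphism does not itself create or destroy a restriction
site, genotyping uses the dCAPS (derived Cleaved Amplified Polymorphic
Sequence) trick: a PCR primer carrying one deliberate mismatch writes a
heterologous base into the amplicon so that an NspI recognition site
(RCATGY; R = A/G, Y = C/T) is completed only when the wild-type base is
present. Digestion then cleaves wild-type amplicons while resistant ones
stay intact, and a diploid genotype is read from the band pattern of a
gel lane:

| genotype | lane bands (nt) |
|---|---|
| wild homozygote (SS) | 85 + 42 |
| heterozygote (RS) | 127 + 85 + 42 |
| resistant homozygote (RR) | 127 |

## Assay geometry

The packaged assay uses three primers, written 5'→3' with the
non-homologous tail of the dCAPS primer in lowercase:

- `ACVII27` (forward, fully homologous): `CACAAGATGCAGCTAGATAGTGGCG`
- `ACVII-NspIR` (reverse dCAPS, 40 nt = 10-nt tail + 30-nt core):
  `gccctagaatAGGCACTGGCAATAGCAGCACTTCCATGCA`
- `ACVII34R` (reverse, for sequencing confirmation):
  `TTCCAACAGTTCGTCCAGTAACGAATG`

On the 127-nt dCAPS amplicon (top-strand coordinates, 1-based), the
forward primer occupies positions 1–25, the dCAPS core pairs with
positions 88–117 with its 3' terminus at 88, and the tail complement
fills 118–127. Codon 1781 sits at positions 87–89. The primer's
penultimate base (position 39 of 40) enforces a G at amplicon position
89; together with template bases G(85) and C(86) this completes
G·C·A·T·G·C = RCATGY across positions 85–90 — but only when position 87
carries the wild-type A. Either leucine codon breaks the site at its
first base. This layout is the unique geometry simultaneously consistent
with the printed primer lengths, the "penultimate mismatch", the 127-nt
product, the 85 + 42 digestion fragments, and discrimination of both
mutant codons, and the package's design search re-derives it from the
template alone (`design_dcaps` returns the printed 40-nt primer as its
top-ranked candidate).

Two geometry conventions needed a decision:

- **Fragment sizes are quoted on the dCAPS-primer strand.** NspI cuts
  RCATG^Y on the top strand and R^CATGY on the bottom, leaving a 4-nt 3'
  overhang (cut offsets 5 and 1 in REBASE style). The bottom-strand
  (primer-strand) cut at the 85/86 boundary yields 85 + 42; the
  top-strand boundary would give 89 + 38. Only the primer-strand
  convention matches the published pair, so `DigestResult` carries both
  and classification uses the primer strand.
- **Reading-frame offset.** Mapping codon c to nucleotides
  [3c − 2 + u, 3c + u], the assay geometry implies u = 2 relative to the
  amplicon start while a straight codon-1753-starts-at-position-1
  bookkeeping implies u = 0. The two differ by a 2-nt frame shift that
  cannot be resolved from the printed numbers alone; the fixture adopts
  the geometry that reproduces the product sizes and exposes `u` as a
  parameter (`CodingCoordinateMap.offset`) rather than hard-coding
  either choice.

## The synthetic reference template

No reference sequence ships with the package; `build_reference_fixture`
constructs a synthetic 175-nt template per allele in which every
constrained segment (primer footprints, the GC dinucleotide completing
the recognition site, the codon) is placed per the geometry above and
the remaining 90 filler positions are drawn from a seeded generator,
rejection-sampled until no allele's template or amplicon carries a
spurious NspI site and all product sizes verify through the PCR/digestion
engine itself (a fixed low-complexity filler is the deterministic
fallback if sampling ever exhausted its cap; in practice the first draw
almost always verifies). Identical seeds give byte-identical FASTA
output; the assay contract (127 nt, 85 + 42, 175 nt, mutants uncut) is
seed-independent.

## In-silico PCR

Annealing uses a deliberately simple mismatch-count model, not
thermodynamics: a primer core may carry at most `max_mismatches` (default
1) mismatches against its footprint, its 3'-terminal base must pair
(default `min_three_prime_match` = 1), and the best footprint must be
unique — two equally good placements raise a non-specific-priming error
rather than multiplying products, because the modelled assay is
single-product. Mismatched primer bases are substituted into the product
and tracked as `primer-enforced` provenance; 5' tails are appended
verbatim (forward) or reverse-complemented (reverse). Amplification
failure (either primer rejected) returns `None`, not an exception,
because it is a routine observation in degraded material.

A gel-resolution model exists (`GelModel`: bands closer than 10 nt
co-migrate, fragments under 20 nt run off) but is disabled by default
since lane patterns are read qualitatively.

## The confirmation workflow

Degraded-material genotyping treats any resistant-looking lane as a
claim requiring escalating evidence. `confirm_workflow` implements the
decision tree: (1) repeat dCAPS on the same extract; (2) if reproduced,
repeat the entire procedure from a fresh leaf fragment; (3) if still
reproduced, amplify the 175-nt product (ACVII27/ACVII34R) and sequence
the diagnostic codon, which alone determines the final call (a wild
sequencing read overrides any number of mixed lanes). Each tier defaults
to one repetition (configurable); any tier at which the pattern is not
clearly reproduced — including an ambiguous lane — ends the candidacy as
wild-type with status `not-reproduced`. The `GenotypeCall` type enforces
structurally that an RS or RR call can only exist with
`sequence-confirmed` status, and batch controls (one blank extraction
per 24 extractions, at least two no-DNA PCR controls) invalidate every
specimen in a batch on any control amplicon. Sequencing is abstracted to
the diagnostic codon; chromatogram simulation is out of scope.

## Statistics

With one resistant allele among n = 2 × 685 = 1370 alleles of the
genotyped diploids, the point estimate is x/n = 7.3 × 10⁻⁴. Interval
estimates use the Jeffreys Beta(½, ½) prior: the posterior after x
successes in n trials is Beta(x + ½, n − x + ½) and the reported
interval is equal-tailed (central), i.e. the posterior quantiles at
(1 − level)/2 and 1 − (1 − level)/2, with lower := 0 when x = 0 and
upper := 1 when x = n. Central rather than highest-density intervals are
used because the study's printed 99% bounds ([2.62 × 10⁻⁵, 4.67 × 10⁻³])
and 95% upper bound (3.40 × 10⁻³) match the central quantiles; the
method tag `jeffreys-central` travels with every interval.

Two published numbers are deliberately documented rather than
reproduced:

- The printed **95% lower bound, 3.65 × 10⁻⁴**, matches neither the
  central quantile (≈ 7.9 × 10⁻⁵) nor a highest-density bound; it
  numerically equals the posterior mode (x − ½)/(n − 1) = 0.5/1369 (and
  half the point estimate). A test pins this identity; the bound itself
  is not asserted as an interval endpoint.
- The **χ² statistic 14.07 (df = 8, p = 0.08)** for amplification
  success versus age depends on a 9-class year binning that is not
  published. The package verifies p = 0.08 from the printed statistic,
  implements the Pearson test on any 2 × k table, and defaults to
  25-year bins over 1776–1975 with undated specimens excluded — binning
  is a parameter precisely because the original classes are unknown.

**Interval conservatism.** At p ≈ 7 × 10⁻⁴ and n = 1370 the equal-tailed
Jeffreys interval markedly over-covers: the binomial outcome is
effectively Poisson with mean ≈ 0.96, the intervals for x = 0, 1, 2, 3
(together 98.3% of the probability mass) all contain p, and only x ≥ 4
misses, so true coverage is ≈ 98.3%, not 95%. This is discreteness, not
an implementation artifact; the coverage property test documents the
exact computation, and the practically important direction — no
undercoverage — holds with a wide margin.

## The cohort simulator

`simulate_cohort` emulates the observational process of the study, with
defaults fixed at the published study conditions:

| parameter | default | meaning |
|---|---|---|
| `n` | 734 | specimens sampled |
| `year_eras` | 1788–1850 (15.9%), 1851–1899 (47.2%), 1900–1975 (36.9%) | collection-year mixture (piecewise uniform) |
| `undated_share` | 0.076 | specimens with no usable collection date |
| `q` | 7.3 × 10⁻⁴ | resistance allele frequency (Hardy–Weinberg genotypes) |
| `mutant_codon_split` | CTA = 1.0 | leucine codon mix among mutant alleles (CTA was the codon observed) |
| `overall_success` / `pre1851_success` | 0.933 / 0.885 | amplification-success anchors |
| `miscall_rate` | 3 × 10⁻⁴ | per-base-call deamination miscall probability |
| `ambiguous_rate` | 3/681 ≈ 0.44% | transient mixed-looking lanes on wild-type specimens |
| `contamination_rate` | 0 | per-batch control contamination (testing only; the study's controls were all clean) |
| `batch_size` | 24 | extractions per blank control |

Design choices worth recording:

- **Amplification success is logistic in collection year**,
  p(year) = σ(a + b·(year − 1900)/100), with (a, b) solved numerically at
  configuration time so the expectation over the year mixture hits both
  anchors. A smooth weak trend was chosen over a step function so the
  age-versus-success χ² test exercises a trend too weak to reject
  independence, as observed.
- **Damage acts on base calls, not genotypes.** Each allele's template
  is passed through `simulate_degradation` (C→T and G→A each with
  probability `miscall_rate`; no other substitution exists in the model)
  before PCR and digestion. A structural consequence, asserted over 10⁶
  simulated codons: damage can never convert wild ATA into mutant CTA,
  because A→C is not a deamination product — the code-level counterpart
  of the argument that an observed A-to-C transversion cannot be a
  degradation artifact.
- **Ambiguous candidacies are injected, not emergent.** Transient mixed
  lanes are drawn only for wild-type specimens at `ambiguous_rate`,
  reproducing the few-candidates-then-one-confirmed narrative without
  pretending to model heteroduplexes or partial digestion. (Damage can
  additionally produce genuinely odd lanes; both routes funnel into the
  same confirmation tree.)
- **One seed, spawned streams.** Cohort composition, lane/damage draws,
  and contamination each use a child of a single `SeedSequence`, so the
  whole study — including the confirmation workflow's repeat
  observations — is reproducible from `CohortConfig.seed`.

What the simulator does **not** model: DNA fragment-length
distributions (age enters only through success probability), PCR
efficiency or band intensities, spatial population structure, partial
digestion chemistry, and real sequence variation outside the SNP codon.
Passing tests therefore demonstrate the correctness of the genotyping
logic and statistics under the stated observation model, not robustness
to every failure mode of real herbarium DNA.

## Problem sizes and numerical choices in the test suite

Expensive checks are scaled to remain quick while staying statistically
meaningful: interval coverage uses 2000 binomial draws (interval reuse
by outcome value makes this instant); the damage non-fabrication
property uses ~10⁶ codons; end-to-end parameter recovery runs 60 cohorts
of 300 specimens at q = 5 × 10⁻³ and checks that the median estimate
falls inside the central 95% band of the sampling distribution and that
interval coverage is at least 90%. The brute-force design oracle runs on
a 40-nt toy template where exhaustive enumeration over every (window,
orientation, 3'-end, mismatch-set) combination is feasible. The Jeffreys
quadrature oracle integrates the Beta(5.5, 5.5) density with adaptive
quadrature (`epsabs` 10⁻¹³) and root-finds the quantiles to 10⁻¹²,
independent of any library quantile routine.

## Known limitations

- The annealing model counts mismatches; it has no melting-temperature
  or secondary-structure scoring, so `design_dcaps` candidates should be
  re-checked thermodynamically before wet-lab use.
- The synthetic template satisfies every printed constraint but is not
  the real ACCase sequence; coordinates relative to the true reference
  should be re-verified against the accession if available.
- Multi-product PCR is out of scope by construction (unique-footprint
  semantics); templates with repeated primer sites raise errors.
- `summarize_cohort` replicates the study's denominators exactly (full
  cohort for date shares, genotyped specimens for genotype shares);
  other conventions require recomputation from the returned counts.
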