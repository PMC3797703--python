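"""Cohort statistics: allele frequencies, credible intervals, and summaries.

The frequency of a rare resistance allele among ``2N`` alleles of ``N``
genotyped diploid specimens is estimated as ``x / 2N`` with equal-tailed
Bayesian credible intervals under the Jeffreys Beta(1/2, 1/2) prior, whose
posterior after x successes in n trials is Beta(x + 1/2, n - x + 1/2).
Amplification success versus specimen age is tested with a Pearson
chi-square test of independence on a 2 x k age-class table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import DomainError, InputError


@dataclass(frozen=True)
class FrequencyEstimate:
    """Allele count, point estimate, and credible intervals."""

    x: int
    n: int
    point: float
    #: (level, lower, upper, method tag)
    intervals: tuple[tuple[float, float, float, str], ...]

    def interval(self, level: float) -> tuple[float, float]:
        for lv, lo, hi, _ in self.intervals:
            if abs(lv - level) < 1e-12:
                return (lo, hi)
        raise KeyError(f"no interval at level {level}")


def jeffreys_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed Jeffreys credible interval for a binomial proportion.

    Quantiles of the Beta(x + 1/2, n - x + 1/2) posterior at
    (1 - level)/2 and 1 - (1 - level)/2, with the standard boundary
    conventions lower = 0 when x = 0 and upper = 1 when x = n.
    """
    if not 0 < level < 1:
        raise DomainError(f"interval level must be in (0, 1), got {level}")
    if not 0 <= x <= n:
        raise DomainError(f"need 0 <= x <= n, got x={x}, n={n}")
    posterior = stats.beta(x + 0.5, n - x + 0.5)
    alpha = (1.0 - level) / 2.0
    lower = 0.0 if x == 0 else float(posterior.ppf(alpha))
    upper = 1.0 if x == n else float(posterior.ppf(1.0 - alpha))
    return (lower, upper)


def jeffreys_posterior_mode(x: int, n: int) -> float:
    """Mode of the Jeffreys posterior, (x - 1/2) / (n - 1) for 0 < x < n."""
    if not 0 < x < n:
        raise DomainError("posterior mode defined here only for 0 < x < n")
    return (x - 0.5) / (n - 1.0)


def estimate_frequency(x: int, genotyped: int,
                       levels: Sequence[float] = (0.95, 0.99),
                       ) -> FrequencyEstimate:
    """Allele frequency among the 2N alleles of N genotyped diploids."""
    if genotyped <= 0:
        raise DomainError("need at least one genotyped specimen")
    n = 2 * genotyped
    if not 0 <= x <= n:
        raise DomainError(f"mutant allele count {x} outside [0, {n}]")
    intervals = tuple(
        (lv, *jeffreys_interval(x, n, lv), "jeffreys-central")
        for lv in levels
    )
    return FrequencyEstimate(x, n, x / n, intervals)


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p_value: float
    table: tuple[tuple[int, ...], ...]


def chisq_independence(table: Sequence[Sequence[int]] | np.ndarray) -> ChiSqResult:
    """Pearson chi-square test of independence on a 2 x k count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise DomainError("contingency table must be two-dimensional")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DomainError(
            "contingency table has a zero marginal; drop empty classes"
        )
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return ChiSqResult(float(stat), int(df), float(p),
                       tuple(tuple(int(v) for v in row) for row in arr))


def read_contingency_csv(path) -> np.ndarray:
    """Read a headerless CSV of counts into a contingency table."""
    table = pd.read_csv(path, header=None).to_numpy()
    if not np.issubdtype(table.dtype, np.number):
        raise InputError("contingency CSV must contain only counts")
    return table


def chisq_pvalue(statistic: float, df: int) -> float:
    """Upper-tail p-value for a chi-square statistic."""
    if statistic < 0 or df < 1:
        raise DomainError("need statistic >= 0 and df >= 1")
    return float(stats.chi2.sf(statistic, df))


def success_by_age_table(metadata: pd.DataFrame, calls: pd.DataFrame,
                         bin_edges: Sequence[int] | None = None,
                         ) -> pd.DataFrame:
    """2 x k table of genotyping success/failure counts per age class.

    Default binning: 25-year classes spanning 1776-1975.  Undated
    specimens are excluded (their age class is unknown); empty classes are
    dropped.
    """
    if bin_edges is None:
        bin_edges = list(range(1776, 2001, 25))
    df = _join_cohort(metadata, calls)
    dated = df[df["year"].notna()].copy()
    dated["age_class"] = pd.cut(dated["year"], bins=bin_edges, right=False)
    dated["success"] = dated["call"].isin(["SS", "RS", "RR"])
    table = (
        dated.groupby("age_class", observed=True)["success"]
        .agg(successes="sum", total="count")
    )
    table["failures"] = table["total"] - table["successes"]
    return table[["successes", "failures"]]


def _join_cohort(metadata: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    for name, df in (("metadata", metadata), ("calls", calls)):
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise InputError(f"duplicate specimen ids in {name}: {dups[:5]}")
    return metadata.merge(calls[["id", "call"]], on="id", how="left")


def summarize_cohort(metadata: pd.DataFrame, calls: pd.DataFrame,
                     levels: Sequence[float] = (0.95, 0.99)) -> dict:
    """Cohort-level summary mirroring the study's reported quantities.

    Collection-date shares use the full cohort as denominator (undated
    specimens stay in the denominator but cannot enter any dated-share
    numerator); genotype shares use the genotyped specimens only.
    Resistant allele count: one allele per RS call, two per RR call.
    """
    df = _join_cohort(metadata, calls)
    total = len(df)
    genotyped_mask = df["call"].isin(["SS", "RS", "RR"])
    genotyped = int(genotyped_mask.sum())
    failed = int((df["call"] == "fail").sum())
    invalid = int((df["call"] == "invalid").sum())

    years = df["year"]
    dated = years.notna()
    pre1900 = int((years < 1900).sum())
    pre1850 = int((years < 1850).sum())
    undated = int((~dated).sum())

    pre1851_mask = dated & (years < 1851)
    pre1851_total = int(pre1851_mask.sum())
    pre1851_success = int((pre1851_mask & genotyped_mask).sum())

    carriers = int(df["call"].isin(["RS", "RR"]).sum())
    mutant_alleles = int((df["call"] == "RS").sum() + 2 * (df["call"] == "RR").sum())

    summary: dict = {
        "n_specimens": total,
        "n_genotyped": genotyped,
        "n_failed": failed,
        "n_invalid": invalid,
        "success_rate": genotyped / total if total else float("nan"),
        "pre1900_count": pre1900,
        "pre1900_share": pre1900 / total if total else float("nan"),
        "pre1850_count": pre1850,
        "pre1850_share": pre1850 / total if total else float("nan"),
        "undated_count": undated,
        "undated_share": undated / total if total else float("nan"),
        "pre1851_success_rate": (
            pre1851_success / pre1851_total if pre1851_total else float("nan")
        ),
        "n_carriers": carriers,
        "carrier_share": carriers / genotyped if genotyped else float("nan"),
        "mutant_alleles": mutant_alleles,
    }
    if genotyped:
        est = estimate_frequency(mutant_alleles, genotyped, levels)
        summary["allele_frequency"] = est.point
        summary["allele_n"] = est.n
        summary["intervals"] = [
            {"level": lv, "lower": lo, "upper": hi, "method": tag}
            for lv, lo, hi, tag in est.intervals
        ]
    return summary


def format_summary(summary: Mapping) -> str:
    """Human-readable rendering with study-style rounding (raw values stay
    in the machine summary)."""
    lines = [
        f"specimens: {summary['n_specimens']}",
        f"genotyped: {summary['n_genotyped']} "
        f"({summary['success_rate'] * 100:.1f}%)",
        f"failed: {summary['n_failed']}, invalid: {summary['n_invalid']}",
        f"collected before 1900: {summary['pre1900_count']} "
        f"({summary['pre1900_share'] * 100:.1f}%)",
        f"collected before 1850: {summary['pre1850_count']} "
        f"({summary['pre1850_share'] * 100:.1f}%)",
        f"undated: {summary['undated_count']} "
        f"({summary['undated_share'] * 100:.1f}%)",
        f"resistant-allele carriers: {summary['n_carriers']} "
        f"({summary['carrier_share'] * 100:.2f}% of genotyped)",
    ]
    if "allele_frequency" in summary:
        lines.append(
            f"resistant allele frequency: {summary['mutant_alleles']}/"
            f"{summary['allele_n']} = {summary['allele_frequency']:.2e}"
        )
        for iv in summary["intervals"]:
            lines.append(
                f"  {iv['level'] * 100:.0f}% credible interval "
                f"[{iv['lower']:.3g}, {iv['upper']:.3g}] ({iv['method']})"
            )
    return "\n".join(lines)
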