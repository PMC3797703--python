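"""Frequency estimation, Jeffreys intervals, chi-square, cohort summary."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import betaln

from herbdcaps.popstats import (
    DomainError,
    chisq_independence,
    chisq_pvalue,
    estimate_frequency,
    jeffreys_interval,
    jeffreys_posterior_mode,
    success_by_age_table,
    summarize_cohort,
)
from herbdcaps.reference import build_demo_cohort
from herbdcaps.seqcore import InputError


class TestJeffreysInterval:
    def test_published_99_interval(self):
        lo, hi = jeffreys_interval(1, 1370, 0.99)
        assert lo == pytest.approx(2.62e-5, rel=5e-3)
        assert hi == pytest.approx(4.67e-3, rel=5e-3)

    def test_published_95_upper_bound(self):
        _, hi = jeffreys_interval(1, 1370, 0.95)
        assert hi == pytest.approx(3.40e-3, rel=5e-3)

    def test_matches_quadrature_oracle(self):
        """(x=5, n=10): numerical integration of the Beta(5.5, 5.5) density,
        independent of any quantile routine."""
        norm = math.exp(betaln(5.5, 5.5))

        def cdf(x):
            return quad(lambda t: t**4.5 * (1 - t)**4.5 / norm, 0, x,
                        epsabs=1e-13)[0]

        lo_oracle = brentq(lambda x: cdf(x) - 0.025, 1e-9, 1 - 1e-9, xtol=1e-12)
        hi_oracle = brentq(lambda x: cdf(x) - 0.975, 1e-9, 1 - 1e-9, xtol=1e-12)
        lo, hi = jeffreys_interval(5, 10, 0.95)
        assert lo == pytest.approx(lo_oracle, abs=1e-6)
        assert hi == pytest.approx(hi_oracle, abs=1e-6)

    def test_boundary_conventions(self):
        assert jeffreys_interval(0, 100, 0.95)[0] == 0.0
        assert jeffreys_interval(100, 100, 0.95)[1] == 1.0

    def test_invalid_level_raises(self):
        with pytest.raises(DomainError):
            jeffreys_interval(1, 10, 1.5)

    def test_intervals_nest_and_narrow(self):
        lo95, hi95 = jeffreys_interval(3, 500, 0.95)
        lo99, hi99 = jeffreys_interval(3, 500, 0.99)
        assert lo99 < lo95 < hi95 < hi99
        # width decreases with n at fixed x/n
        w1 = np.diff(jeffreys_interval(3, 500, 0.95))[0]
        w2 = np.diff(jeffreys_interval(30, 5000, 0.95))[0]
        assert w2 < w1

    def test_no_undercoverage_at_study_conditions(self):
        """At p = 7e-4, n = 1370 the equal-tailed interval is conservative:
        every x in 0..3 (98.3% of the mass) yields an interval containing
        p, so empirical coverage sits above the nominal 95%."""
        p, n = 7e-4, 1370
        rng = np.random.default_rng(42)
        xs = rng.binomial(n, p, size=2000)
        cache = {}
        covered = 0
        for x in xs:
            x = int(x)
            if x not in cache:
                lo, hi = jeffreys_interval(x, n, 0.95)
                cache[x] = lo <= p <= hi
            covered += cache[x]
        assert covered / len(xs) >= 0.93

    def test_printed_lower_bound_equals_posterior_mode(self):
        """The study's printed 95% lower bound (3.65e-4) is not the central
        2.5% quantile (~7.9e-5) but numerically equals the Jeffreys
        posterior mode (x - 1/2)/(n - 1)."""
        lo, _ = jeffreys_interval(1, 1370, 0.95)
        assert lo == pytest.approx(7.9e-5, rel=0.01)
        assert jeffreys_posterior_mode(1, 1370) == pytest.approx(3.65e-4,
                                                                 rel=5e-3)


class TestEstimateFrequency:
    def test_study_point_estimate(self):
        est = estimate_frequency(1, 685)
        assert est.n == 1370
        assert est.point == pytest.approx(7.3e-4, rel=5e-3)
        assert est.interval(0.99)[0] == pytest.approx(2.62e-5, rel=5e-3)

    @pytest.mark.parametrize("x, genotyped, point",
                             [(0, 100, 0.0), (1370, 685, 1.0)])
    def test_boundaries(self, x, genotyped, point):
        assert estimate_frequency(x, genotyped).point == point

    def test_zero_genotyped_raises(self):
        with pytest.raises(DomainError):
            estimate_frequency(0, 0)


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        res = chisq_independence([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # expected counts all 10 -> sum (O-E)^2/E = 4 * 25/10 = 10
        res = chisq_independence([[5, 15], [15, 5]])
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 1

    def test_published_p_value(self):
        assert chisq_pvalue(14.07, 8) == pytest.approx(0.08, abs=5e-3)

    def test_invariant_under_permutation_and_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, 5))
            res = chisq_independence(table)
            # brute force Pearson statistic
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            brute = ((table - exp) ** 2 / exp).sum()
            assert res.statistic == pytest.approx(brute)
            assert res.df == 4
            perm = table[::-1][:, rng.permutation(5)]
            assert chisq_independence(perm).statistic == pytest.approx(brute)

    def test_zero_marginal_raises(self):
        with pytest.raises(DomainError, match="marginal"):
            chisq_independence([[0, 10], [0, 5]])

    def test_contingency_csv_input(self, tmp_path):
        from herbdcaps.popstats import read_contingency_csv

        path = tmp_path / "table.csv"
        path.write_text("5,15\n15,5\n")
        table = read_contingency_csv(path)
        assert chisq_independence(table).statistic == pytest.approx(10.0)


@pytest.fixture(scope="module")
def demo():
    return build_demo_cohort()


class TestCohortSummary:
    def test_study_margins(self, demo):
        summary = summarize_cohort(*demo)
        assert summary["n_specimens"] == 734
        assert summary["n_genotyped"] == 685
        assert summary["success_rate"] == pytest.approx(0.933, abs=5e-4)
        assert summary["pre1900_count"] == 428
        assert summary["pre1900_share"] == pytest.approx(0.583, abs=5e-4)
        assert summary["pre1850_count"] == 108
        assert summary["undated_count"] == 56
        assert summary["undated_share"] == pytest.approx(0.076, abs=5e-4)
        assert summary["n_carriers"] == 1
        assert summary["carrier_share"] == pytest.approx(0.0015, abs=5e-5)
        assert summary["mutant_alleles"] == 1
        assert summary["allele_frequency"] == pytest.approx(7.3e-4, rel=5e-3)
        assert summary["pre1851_success_rate"] == pytest.approx(0.885, abs=5e-3)

    def test_age_table_excludes_undated(self, demo):
        metadata, calls = demo
        table = success_by_age_table(metadata, calls)
        assert table.to_numpy().sum() == 678  # 734 - 56 undated
        assert (table.sum(axis=1) > 0).all()

    def test_duplicate_ids_raise(self, demo):
        metadata, calls = demo
        bad = metadata.copy()
        bad.loc[1, "id"] = bad.loc[0, "id"]
        with pytest.raises(InputError, match="duplicate"):
            summarize_cohort(bad, calls)
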