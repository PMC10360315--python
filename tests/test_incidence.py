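"""Severity-class pooling, incidence expectations, variances, and CIs."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mldmatrix import (
    IncidenceEstimate,
    Phenotype,
    SeverityClass,
    SyntheticConfig,
    Variant,
    analytic_ci,
    bootstrap_ci,
    generate_variant_pool,
    genotype_incidence,
    one_in,
    phenotype_incidence,
    severity_class_frequencies,
)

S, M, m, B, U = (
    SeverityClass.SEVERE,
    SeverityClass.MODERATE,
    SeverityClass.MILD,
    SeverityClass.BENIGN,
    SeverityClass.UNKNOWN,
)


def make_pool(class_freqs: dict[SeverityClass, list[float]], an: int = 100_000):
    pool = []
    i = 0
    for cls, freqs in class_freqs.items():
        for f in freqs:
            i += 1
            pool.append(
                Variant(
                    id=f"c.{i}A>G",
                    freq_by_population={"all": f},
                    allele_number_by_population={"all": an},
                    finalized_severity=cls,
                )
            )
    return pool


def freqs_of(class_freqs, an=100_000):
    return severity_class_frequencies(make_pool(class_freqs, an), "finalized", "all")


class TestClassFrequencies:
    def test_class_frequency_is_sum_of_member_frequencies(self):
        out = freqs_of({S: [0.001, 0.002]})
        assert out[S].p_hat == pytest.approx(0.003)
        assert out[M].p_hat == 0.0 and out[M].var == 0.0

    def test_variance_is_binomial_sampling_variance(self):
        out = freqs_of({S: [0.5]}, an=1000)
        assert out[S].var == pytest.approx(0.5 * 0.5 / 1000)  # p(1-p)/AN

    def test_missing_population_frequency_warns_and_contributes_zero(self):
        pool = make_pool({S: [0.001]})
        with pytest.warns(UserWarning, match="no frequency"):
            out = severity_class_frequencies(pool, "finalized", "nfe")
        assert out[S].p_hat == 0.0


class TestExpectations:
    def test_infantile_is_squared_severe_frequency(self):
        inc = phenotype_incidence(freqs_of({S: [0.001]}))
        assert inc[Phenotype.INFANTILE].expected == pytest.approx(1e-6)

    def test_juvenile_is_twice_severe_times_moderate(self):
        inc = phenotype_incidence(freqs_of({S: [0.001], M: [0.001]}))
        assert inc[Phenotype.JUVENILE].expected == pytest.approx(2e-6)

    def test_adult_combines_moderate_homozygotes_and_severe_mild(self):
        inc = phenotype_incidence(freqs_of({S: [0.002], M: [0.003], m: [0.001]}))
        assert inc[Phenotype.ADULT].expected == pytest.approx(0.003**2 + 2 * 0.002 * 0.001)

    def test_overall_is_sum_of_symptomatic_phenotypes(self):
        inc = phenotype_incidence(freqs_of({S: [1e-3], M: [5e-4], m: [2e-4]}))
        total = sum(
            inc[p].expected for p in (Phenotype.INFANTILE, Phenotype.JUVENILE, Phenotype.ADULT)
        )
        assert inc["overall"].expected == pytest.approx(total, rel=0, abs=0)

    def test_gus_covers_vus_pairings_except_benign(self):
        inc = phenotype_incidence(freqs_of({S: [1e-3], M: [1e-3], m: [1e-3], B: [0.01], U: [2e-3]}))
        pU, path = 2e-3, 3e-3
        assert inc[Phenotype.UNKNOWN].expected == pytest.approx(2 * pU * path + pU**2)

    def test_hardy_weinberg_conservation_over_all_class_pairs(self):
        """Summing the 15 unordered class-pair genotype frequencies returns
        the square of the total allele frequency."""
        out = freqs_of({S: [1e-3, 2e-3], M: [5e-4], m: [1e-4], B: [0.01], U: [3e-3]})
        classes = list(out)
        total = 0.0
        for a, b in itertools.combinations_with_replacement(classes, 2):
            pa, pb = out[a].p_hat, out[b].p_hat
            total += genotype_incidence(pa, pb, homozygous=a is b)
        assert total == pytest.approx(sum(v.p_hat for v in out.values()) ** 2)

    def test_scaling_frequencies_by_c_scales_expectations_by_c_squared(self):
        base = {S: [1e-3], M: [4e-4], m: [1e-4], B: [0.01], U: [1e-3]}
        c = 3.0
        scaled = {cls: [c * f for f in fs] for cls, fs in base.items()}
        inc0 = phenotype_incidence(freqs_of(base))
        inc1 = phenotype_incidence(freqs_of(scaled))
        for phen in inc0:
            assert inc1[phen].expected == pytest.approx(c**2 * inc0[phen].expected)


class TestVariancePropagation:
    def test_zero_variant_variance_zeroes_every_variance_formula(self):
        """With Var[v] = 0 for all variants every propagated phenotype
        variance vanishes (the expectations are then exact)."""
        out = freqs_of({S: [1e-3], M: [5e-4], m: [2e-4]})
        for entry in out.values():
            entry.var = 0.0
        for symmetric in (False, True):
            inc = phenotype_incidence(out, symmetric_juvenile_variance=symmetric)
            for phen in (Phenotype.INFANTILE, Phenotype.JUVENILE, Phenotype.ADULT, "overall"):
                assert inc[phen].variance == 0.0

    def test_variances_match_monte_carlo_propagation(self):
        """Independent oracle: redraw class frequencies from normals with the
        pooled variances and compare the empirical variance of each phenotype
        incidence with the analytic propagation."""
        out = freqs_of({S: [4e-3], M: [2e-3], m: [1e-3]}, an=50_000)
        inc = phenotype_incidence(out, symmetric_juvenile_variance=True)
        rng = np.random.default_rng(0)
        n = 400_000
        pS = rng.normal(out[S].p_hat, math.sqrt(out[S].var), n)
        pM = rng.normal(out[M].p_hat, math.sqrt(out[M].var), n)
        pm = rng.normal(out[m].p_hat, math.sqrt(out[m].var), n)
        samples = {
            Phenotype.INFANTILE: pS**2,
            Phenotype.JUVENILE: 2 * pS * pM,
            Phenotype.ADULT: pM**2 + 2 * pS * pm,
        }
        samples["overall"] = sum(samples.values())
        for phen, sample in samples.items():
            assert inc[phen].variance == pytest.approx(sample.var(), rel=0.05), phen


class TestAnalyticCI:
    def test_interval_shrinks_to_the_point_estimate_as_variance_vanishes(self):
        est = IncidenceEstimate("all", Phenotype.INFANTILE, expected=1e-4, variance=1e-16)
        ci = analytic_ci(est)
        assert ci.ci_low == pytest.approx(1e-4, rel=1e-3)
        assert ci.ci_high == pytest.approx(1e-4, rel=1e-3)
        assert ci.ci_low <= est.expected <= ci.ci_high

    def test_uniform_moments_recover_uniform_quantiles(self):
        # mean 1/2, variance 1/12 are the moments of Beta(1,1) = U(0,1)
        est = IncidenceEstimate("all", Phenotype.INFANTILE, expected=0.5, variance=1 / 12)
        ci = analytic_ci(est)
        assert ci.ci_low == pytest.approx(0.025)
        assert ci.ci_high == pytest.approx(0.975)

    def test_impossible_moments_rejected(self):
        est = IncidenceEstimate("all", Phenotype.INFANTILE, expected=0.5, variance=0.3)
        with pytest.raises(ValueError):
            analytic_ci(est)


class TestBootstrap:
    def test_bootstrap_is_seeded_and_reproducible(self):
        pool = make_pool({S: [1e-3], M: [5e-4]})
        a = bootstrap_ci(pool, "finalized", "all", n_iter=500, seed=42)
        b = bootstrap_ci(pool, "finalized", "all", n_iter=500, seed=42)
        assert a["overall"].ci_low == b["overall"].ci_low

    def test_huge_allele_numbers_collapse_the_interval(self):
        pool = make_pool({S: [1e-3]}, an=10**12)
        out = bootstrap_ci(pool, "finalized", "all", n_iter=500, seed=1)
        est = out[Phenotype.INFANTILE]
        assert est.ci_low == pytest.approx(est.expected, rel=1e-3)
        assert est.ci_high == pytest.approx(est.expected, rel=1e-3)

    def test_bootstrap_matches_analytic_interval_for_infantile(self):
        pool = make_pool({S: [2e-3, 1e-3]}, an=50_000)
        freqs = severity_class_frequencies(pool, "finalized", "all")
        analytic = analytic_ci(phenotype_incidence(freqs)[Phenotype.INFANTILE])
        boot = bootstrap_ci(pool, "finalized", "all", n_iter=20_000, seed=7)[Phenotype.INFANTILE]
        assert boot.ci_low == pytest.approx(analytic.ci_low, rel=0.1)
        assert boot.ci_high == pytest.approx(analytic.ci_high, rel=0.1)

    def test_tiny_iteration_count_warns(self):
        pool = make_pool({S: [1e-3]})
        with pytest.warns(UserWarning, match="too small"):
            bootstrap_ci(pool, "finalized", "all", n_iter=50, seed=0)


class TestGenotypeIncidence:
    def test_heterozygote_carries_factor_two(self):
        assert genotype_incidence(0.5, 0.5) == pytest.approx(0.5)
        assert genotype_incidence(1.21e-3, 1.21e-3, homozygous=True) == pytest.approx(
            1.4641e-6
        )

    def test_published_nfe_homozygote_rate_from_rounded_frequency(self):
        # c.465+1G>A at the printed 3-s.f. NFE frequency; the printed rate
        # 1 in 683,188 used unrounded frequencies, so match at the rounding level
        rate = genotype_incidence(1.21e-3, 1.21e-3, homozygous=True)
        assert one_in(rate) == pytest.approx(683_188, rel=5e-3)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            genotype_incidence(-0.1, 0.5)
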