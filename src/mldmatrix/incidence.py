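"""Population disease-burden estimation under Hardy-Weinberg proportions.

Each severity class pools its member variants (assumed never to co-occur in
cis), so the class allele frequency is the sum of member frequencies and the
class variance is the sum of per-variant binomial sampling variances
p(1-p)/AN, with AN the number of chromosomes sampled in the population.

Under random mating, phenotype birth incidences follow from the phenotype
matrix:

    E[Infantile] = p_S^2
    E[Juvenile]  = 2 p_S p_M
    E[Adult]     = p_M^2 + 2 p_S p_m
    E[Overall]   = E[Infantile] + E[Juvenile] + E[Adult]

(p_S, p_M, p_m, p_B, p_U = pooled severe, moderate, mild, benign, unknown
frequencies). Variances propagate through these quadratic forms with the
normal-theory expressions for products and squares of estimated frequencies;
the Overall variance needs covariance terms because the severe class enters
every symptomatic phenotype. The asymptomatic expectation includes carrier
pairings (benign x pathogenic), and the genotype-of-unknown-significance (GUS)
expectation covers every VUS pairing except VUS x benign.

95% CIs come either from a method-of-moments beta approximation (analytic) or
from re-drawing each variant's allele count binomially and recomputing the
incidences (bootstrap). Asymptomatic and GUS variances are not derived
analytically; use the bootstrap for those.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import Phenotype, SeverityClass, Variant

__all__ = [
    "SeverityClassFrequency",
    "IncidenceEstimate",
    "SEVERITY_FIELDS",
    "severity_class_frequencies",
    "phenotype_incidence",
    "analytic_ci",
    "bootstrap_ci",
    "genotype_incidence",
    "one_in",
]

#: Selector aliases for the severity field used to pool variants.
SEVERITY_FIELDS = {
    "patient": "patient_based_severity",
    "activity": "activity_based_severity_cds",
    "activity_genomic": "activity_based_severity_genomic",
    "finalized": "finalized_severity",
}

_CLASSES = (
    SeverityClass.SEVERE,
    SeverityClass.MODERATE,
    SeverityClass.MILD,
    SeverityClass.BENIGN,
    SeverityClass.UNKNOWN,
)


def one_in(rate: float) -> float:
    """Reciprocal "1 in N" representation of an incidence (inf at zero)."""
    if rate < 0:
        raise ValueError(f"negative incidence: {rate}")
    return math.inf if rate == 0 else 1.0 / rate


@dataclass
class SeverityClassFrequency:
    """Pooled allele frequency and variance for one severity class."""

    population: str
    severity_class: SeverityClass
    p_hat: float
    var: float
    variant_ids: list[str]


@dataclass
class IncidenceEstimate:
    """Expected birth incidence of one phenotype, with optional 95% CI."""

    population: str
    phenotype: "Phenotype | str"  # a Phenotype, or the "overall" aggregate
    expected: float
    variance: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: Optional[str] = None  # "analytic" | "bootstrap"

    @property
    def one_in(self) -> float:
        return one_in(self.expected)


def _resolve_field(severity_field: str) -> str:
    return SEVERITY_FIELDS.get(severity_field, severity_field)


def severity_class_frequencies(
    variants: Iterable[Variant],
    severity_field: str = "finalized",
    population: str = "all",
    default_allele_number: int = 100_000,
) -> dict[SeverityClass, SeverityClassFrequency]:
    """Pool variants into severity classes for one population.

    ``severity_field`` selects which assignment partitions the variants
    ("patient", "activity", "finalized", or a Variant attribute name). A
    variant with no frequency for the population contributes 0 with a warning;
    per-variant variance is p(1-p)/AN with AN the population allele number
    (falling back to ``default_allele_number``).
    """
    attr = _resolve_field(severity_field)
    out = {
        cls: SeverityClassFrequency(
            population=population, severity_class=cls, p_hat=0.0, var=0.0, variant_ids=[]
        )
        for cls in _CLASSES
    }
    for v in variants:
        cls = getattr(v, attr)
        p = v.frequency(population)
        if p < 0:
            raise ValueError(f"{v.id}: negative frequency {p}")
        an = v.allele_number_by_population.get(population, default_allele_number)
        entry = out[cls]
        entry.p_hat += p
        entry.var += p * (1.0 - p) / an
        entry.variant_ids.append(v.id)
    return out


def _phenotype_expectations(
    pS: float, pM: float, pm: float, pB: float, pU: float
) -> dict[Phenotype, float]:
    e_inf = pS**2
    e_juv = 2.0 * pS * pM
    e_adu = pM**2 + 2.0 * pS * pm
    e_asym = (
        pm**2
        + 2.0 * pm * (pM + pB)
        + 2.0 * pB * (pS + pM)
        + pB**2
        + 2.0 * pU * pB
    )
    e_gus = 2.0 * pU * (pS + pM + pm) + pU**2
    return {
        Phenotype.INFANTILE: e_inf,
        Phenotype.JUVENILE: e_juv,
        Phenotype.ADULT: e_adu,
        Phenotype.ASYMPTOMATIC: e_asym,
        Phenotype.UNKNOWN: e_gus,
    }


def _var_square(p: float, v: float) -> float:
    """Var[X^2] for X with mean p, variance v (normal theory).

    2((v+p^2)^2 - p^4), expanded to 2v(v + 2p^2) so it vanishes exactly at
    v = 0 instead of cancelling in floating point.
    """
    return 2.0 * v * (v + 2.0 * p**2)


def _var_cross(pa: float, va: float, pb: float, vb: float) -> float:
    """Var[2 X Y] for independent X, Y with means pa, pb and variances va, vb.

    4((va+pa^2)(vb+pb^2) - pa^2 pb^2), expanded for exact cancellation.
    """
    return 4.0 * (va * vb + va * pb**2 + vb * pa**2)


def phenotype_incidence(
    freqs: Mapping[SeverityClass, SeverityClassFrequency],
    symmetric_juvenile_variance: bool = False,
) -> dict[Phenotype, IncidenceEstimate]:
    """Expected incidence and variance of each phenotype (no CIs yet).

    The juvenile variance by default neglects the severe-class sampling
    variance (it conditions on the severe frequency); set
    ``symmetric_juvenile_variance=True`` for the symmetric product-variance
    form, as a sensitivity analysis. Asymptomatic and GUS variances are not
    computed analytically (``variance=None``); use :func:`bootstrap_ci`.
    """
    pS, vS = freqs[SeverityClass.SEVERE].p_hat, freqs[SeverityClass.SEVERE].var
    pM, vM = freqs[SeverityClass.MODERATE].p_hat, freqs[SeverityClass.MODERATE].var
    pm, vm = freqs[SeverityClass.MILD].p_hat, freqs[SeverityClass.MILD].var
    pB = freqs[SeverityClass.BENIGN].p_hat
    pU = freqs[SeverityClass.UNKNOWN].p_hat
    population = freqs[SeverityClass.SEVERE].population

    e = _phenotype_expectations(pS, pM, pm, pB, pU)

    var_inf = _var_square(pS, vS)
    if symmetric_juvenile_variance:
        var_juv = _var_cross(pS, vS, pM, vM)
    else:
        var_juv = 4.0 * pS**2 * vM  # severe frequency treated as fixed
    var_mm = _var_square(pM, vM)
    var_sm = _var_cross(pS, vS, pm, vm)
    var_adu = var_mm + var_sm

    # Overall variance: the severe class feeds every symptomatic phenotype, so
    # the homozygote and compound-het terms covary and must be expanded. The
    # pooled compound-het variance Var[2 pS (pM + pm)] is the two cross
    # variances plus the covariance 2 Cov(2 pS pM, 2 pS pm) = 8 pM pm Var[S].
    var_s_moderate = _var_cross(pS, vS, pM, vM)
    var_smm = var_sm + var_s_moderate + 8.0 * pM * pm * vS
    cov_smm_inf = 2.0 * pS * vS * 2.0 * (pm + pM)
    cov_smm_mm = 2.0 * pM * vM * 2.0 * pS
    var_overall = var_smm + var_inf + var_mm + 2.0 * cov_smm_inf + 2.0 * cov_smm_mm

    out = {
        phen: IncidenceEstimate(population=population, phenotype=phen, expected=e[phen])
        for phen in e
    }
    out[Phenotype.INFANTILE].variance = var_inf
    out[Phenotype.JUVENILE].variance = var_juv
    out[Phenotype.ADULT].variance = var_adu
    out["overall"] = IncidenceEstimate(  # type: ignore[index]
        population=population,
        phenotype="overall",  # type: ignore[arg-type]
        expected=e[Phenotype.INFANTILE] + e[Phenotype.JUVENILE] + e[Phenotype.ADULT],
        variance=var_overall,
    )
    return out


def analytic_ci(estimate: IncidenceEstimate, level: float = 0.95) -> IncidenceEstimate:
    """95% CI from a method-of-moments beta matched to (expected, variance).

    Requires ``expected`` in (0,1) and ``0 < variance < expected(1-expected)``
    (otherwise no beta has those moments).
    """
    m, v = estimate.expected, estimate.variance
    if v is None:
        raise ValueError("estimate has no analytic variance; use bootstrap_ci")
    if not (0.0 < m < 1.0):
        raise ValueError(f"expected incidence must lie in (0, 1), got {m}")
    if not (0.0 < v < m * (1.0 - m)):
        raise ValueError(
            f"variance {v} incompatible with a beta of mean {m}"
        )
    nu = m * (1.0 - m) / v - 1.0
    a, b = m * nu, (1.0 - m) * nu
    lo, hi = stats.beta.ppf([(1 - level) / 2, (1 + level) / 2], a, b)
    return replace(estimate, ci_low=float(lo), ci_high=float(hi), method="analytic")


def bootstrap_ci(
    variants: Sequence[Variant],
    severity_field: str = "finalized",
    population: str = "all",
    n_iter: int = 100_000,
    seed: Optional[int] = None,
    default_allele_number: int = 100_000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> dict[Phenotype, IncidenceEstimate]:
    """Bootstrap 95% CIs for every phenotype incidence (plus ``"overall"``).

    Per iteration, each variant's allele count is redrawn from
    Binomial(AN, p)/AN and every phenotype incidence is recomputed; the CI is
    the empirical 2.5/97.5 percentile band. Reported expectations are the
    point estimates from the observed frequencies. Seeded and reproducible.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is too small for stable 95% CIs", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    attr = _resolve_field(severity_field)

    class_draws = {cls: np.zeros(n_iter) for cls in _CLASSES}
    for v in variants:
        p = v.frequency(population)
        an = v.allele_number_by_population.get(population, default_allele_number)
        draws = rng.binomial(an, p, size=n_iter) / an
        class_draws[getattr(v, attr)] += draws

    e = _phenotype_expectations(
        *(class_draws[c] for c in _CLASSES)
    )
    e["overall"] = (
        e[Phenotype.INFANTILE] + e[Phenotype.JUVENILE] + e[Phenotype.ADULT]
    )

    point = phenotype_incidence(
        severity_class_frequencies(
            variants, severity_field, population, default_allele_number
        )
    )
    alpha = (1 - level) / 2
    out: dict[Phenotype, IncidenceEstimate] = {}
    for phen, sample in e.items():
        lo, hi = np.quantile(sample, [alpha, 1 - alpha])
        out[phen] = replace(
            point[phen], ci_low=float(lo), ci_high=float(hi), method="bootstrap"
        )
    return out


def genotype_incidence(pA: float, pB: float, homozygous: bool = False) -> float:
    """Hardy-Weinberg birth incidence of one biallelic genotype.

    ``pA**2`` for a homozygote, ``2 pA pB`` for a compound heterozygote.
    """
    for p in (pA, pB):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"allele frequency outside [0, 1]: {p}")
    if homozygous:
        return pA * pA
    return 2.0 * pA * pB
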