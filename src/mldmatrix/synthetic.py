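"""Synthetic variant pools, patient cohorts, and activity tables.

Every pipeline stage can be exercised without any external download: the
generator draws a variant pool with known ("true") severity classes and
log-uniform allele frequencies, samples a diploid symptomatic patient cohort
from Hardy-Weinberg genotype proportions conditioned on a symptomatic
phenotype-matrix prediction, and emits replicate ion-ratio activity wells
whose percent-of-wild-type activities sit at class-typical values plus
Gaussian noise. Ground truth severities are stored on each generated
``Variant`` (all four severity fields carry the generating class) so recovery
by the severity ruleset and the activity brackets can be checked directly.

The defaults emulate the curated study conditions: a cohort of 489 literature
cases, pathogenic allele frequencies spanning 1e-6..1e-3, a pool skewed toward
severe alleles, gnomAD-scale allele numbers, a small (5%) phenotype
misclassification rate, and sub-percent replicate noise in the activity assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .activity import ActivityMeasurement, Construct
from .datamodel import (
    Consequence,
    PatientRecord,
    Phenotype,
    SeverityClass,
    Variant,
    INFANTILE_ONSET_MAX_YEARS,
    JUVENILE_ONSET_MAX_YEARS,
)
from .incidence import genotype_incidence
from .matrix import PhenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "WILDTYPE_ID",
    "CLASS_ACTIVITY_MEANS",
    "generate_variant_pool",
    "generate_cohort",
    "generate_activity_table",
    "true_severities",
]

#: Reserved id for the wild-type reference wells in generated activity tables.
WILDTYPE_ID = "WT"

#: Percent-of-wild-type activity at which each class's variants are centered:
#: mid-bracket for the pathogenic classes (brackets <2 / 2-<4 / 4-13), well
#: clear of the 13% threshold for benign.
CLASS_ACTIVITY_MEANS: Mapping[SeverityClass, float] = {
    SeverityClass.SEVERE: 0.5,
    SeverityClass.MODERATE: 3.0,
    SeverityClass.MILD: 8.0,
    SeverityClass.BENIGN: 60.0,
    SeverityClass.UNKNOWN: 8.0,  # a VUS behaves like an uncharacterized mild allele
}

_SYMPTOMATIC = (Phenotype.INFANTILE, Phenotype.JUVENILE, Phenotype.ADULT)

#: Onset-age windows (years) per symptomatic presentation.
_ONSET_WINDOWS = {
    Phenotype.INFANTILE: (0.0, INFANTILE_ONSET_MAX_YEARS),
    Phenotype.JUVENILE: (INFANTILE_ONSET_MAX_YEARS, JUVENILE_ONSET_MAX_YEARS),
    Phenotype.ADULT: (JUVENILE_ONSET_MAX_YEARS, 40.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator."""

    n_variants_per_class: Mapping[SeverityClass, int] = field(
        default_factory=lambda: {
            SeverityClass.SEVERE: 8,
            SeverityClass.MODERATE: 4,
            SeverityClass.MILD: 3,
            SeverityClass.BENIGN: 2,
        }
    )
    frequency_log10_range: tuple[float, float] = (-6.0, -3.0)
    populations: Sequence[str] = ("all",)
    n_patients: int = 489
    phenotype_misclassification_rate: float = 0.05
    activity_noise_sd: float = 0.5  # percent-of-wild-type units
    allele_number: int = 100_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.phenotype_misclassification_rate <= 1.0):
            raise ValueError("misclassification rate must lie in [0, 1]")
        lo, hi = self.frequency_log10_range
        if lo > hi:
            raise ValueError("frequency_log10_range must be ordered")
        if self.activity_noise_sd < 0:
            raise ValueError("activity noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_variant_pool(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[Variant]:
    """Draw a variant pool with known severity classes and frequencies.

    Frequencies are log-uniform within ``frequency_log10_range``, drawn
    independently per population. Severe alleles alternate between missense
    and stop-gained consequences (so the LoF rule has something to fire on);
    all other classes are missense. The generating class is recorded in every
    severity field of the returned variants.
    """
    if rng is None:
        rng = config.rng()
    lo, hi = config.frequency_log10_range
    pool: list[Variant] = []
    position = 100
    for cls, n in config.n_variants_per_class.items():
        for i in range(n):
            is_stop = cls is SeverityClass.SEVERE and i % 2 == 1
            vid = f"c.{position}G>{'A' if is_stop else 'T'}"
            position += 7
            freqs = {
                pop: float(10.0 ** rng.uniform(lo, hi)) for pop in config.populations
            }
            pool.append(
                Variant(
                    id=vid,
                    consequence=Consequence.STOP_GAINED if is_stop else Consequence.MISSENSE,
                    freq_by_population=freqs,
                    allele_number_by_population={
                        pop: config.allele_number for pop in config.populations
                    },
                    patient_based_severity=cls,
                    activity_based_severity_cds=cls,
                    activity_based_severity_genomic=cls,
                    finalized_severity=cls,
                )
            )
    return pool


def true_severities(pool: Sequence[Variant]) -> dict[str, SeverityClass]:
    """Ground-truth severity map of a generated pool."""
    return {v.id: v.finalized_severity for v in pool}


def generate_cohort(
    pool: Sequence[Variant],
    config: SyntheticConfig,
    matrix: Optional[PhenotypeMatrix] = None,
    population: str = "all",
    rng: Optional[np.random.Generator] = None,
) -> list[PatientRecord]:
    """Sample a symptomatic patient cohort under Hardy-Weinberg proportions.

    Genotypes are drawn proportionally to their Hardy-Weinberg incidence
    (p^2 homozygote, 2pq heterozygote) among the unordered allele pairs whose
    matrix prediction is symptomatic -- conditioning on being a patient, which
    keeps cohorts desk-scale at realistic 1e-6 incidences. The recorded
    phenotype is the matrix prediction, flipped to a random other symptomatic
    phenotype with probability ``phenotype_misclassification_rate``; onset
    ages are uniform within the recorded phenotype's window.
    """
    if rng is None:
        rng = config.rng()
    if matrix is None:
        matrix = PhenotypeMatrix.default()
    truth = true_severities(pool)

    pairs: list[tuple[str, str, Phenotype]] = []
    weights: list[float] = []
    for i, a in enumerate(pool):
        for b in pool[i:]:
            predicted = matrix.predict(truth[a.id], truth[b.id])
            if predicted not in _SYMPTOMATIC:
                continue
            pairs.append((a.id, b.id, predicted))
            weights.append(
                genotype_incidence(
                    a.frequency(population),
                    b.frequency(population),
                    homozygous=a.id == b.id,
                )
            )
    if not pairs or sum(weights) == 0:
        raise ValueError("pool admits no symptomatic genotype")

    w = np.asarray(weights)
    w /= w.sum()
    choices = rng.choice(len(pairs), size=config.n_patients, p=w)
    records: list[PatientRecord] = []
    for j, idx in enumerate(choices, start=1):
        a, b, predicted = pairs[idx]
        phenotype = predicted
        if rng.random() < config.phenotype_misclassification_rate:
            others = [p for p in _SYMPTOMATIC if p is not predicted]
            phenotype = others[rng.integers(len(others))]
        lo, hi = _ONSET_WINDOWS[phenotype]
        records.append(
            PatientRecord(
                patient_id=f"SYN{j:04d}",
                allele1=a,
                allele2=b,
                phenotype=phenotype,
                age_of_onset_years=float(rng.uniform(lo, hi)),
                source_ref="synthetic",
            )
        )
    return records


def generate_activity_table(
    pool: Sequence[Variant],
    config: SyntheticConfig,
    construct: Construct = Construct.CDS,
    variants_per_plate: int = 90,
    rng: Optional[np.random.Generator] = None,
) -> list[ActivityMeasurement]:
    """Emit replicate ion-ratio wells for every pool variant plus wild-type.

    Each variant gets three replicates whose percent-of-wild-type activities
    are the class-typical mean (:data:`CLASS_ACTIVITY_MEANS`) plus Gaussian
    noise of sd ``activity_noise_sd``. Wells are back-converted to
    (ARSA ratio, BLA ratio) pairs against per-plate wild-type wells of
    normalized activity exactly 1, so re-normalizing with
    :func:`mldmatrix.activity.percent_wt_activity` reproduces the injected
    percents exactly.
    """
    if rng is None:
        rng = config.rng()
    truth = true_severities(pool)
    measurements: list[ActivityMeasurement] = []
    for start in range(0, len(pool), variants_per_plate):
        plate = f"plate{start // variants_per_plate + 1}"
        measurements.append(
            ActivityMeasurement(
                variant_id=WILDTYPE_ID,
                construct=construct,
                replicate_ion_ratios=[(1.0, 1.0)] * 3,
                plate_id=plate,
            )
        )
        for v in pool[start : start + variants_per_plate]:
            mean = CLASS_ACTIVITY_MEANS[truth[v.id]]
            ratios = []
            for _ in range(3):
                percent = mean + rng.normal(0.0, config.activity_noise_sd)
                bla = 1.0
                ratios.append((percent / 100.0 * bla, bla))
            measurements.append(
                ActivityMeasurement(
                    variant_id=v.id,
                    construct=construct,
                    replicate_ion_ratios=ratios,
                    plate_id=plate,
                )
            )
    return measurements
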