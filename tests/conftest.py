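"""Shared fixtures: printed-cohort reconstruction and synthetic defaults."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from mldmatrix import PatientRecord, Phenotype, SeverityClass, SyntheticConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

_counter = itertools.count(1)


def make_records(
    allele1: str, allele2: str | None, phenotype_counts: dict[Phenotype, int]
) -> list[PatientRecord]:
    """Expand a genotype's phenotype tally into individual patient records."""
    records = []
    for phen, n in phenotype_counts.items():
        for _ in range(n):
            records.append(
                PatientRecord(
                    patient_id=f"T{next(_counter):04d}",
                    allele1=allele1,
                    allele2=allele2,
                    phenotype=phen,
                )
            )
    return records


#: The ten most common genotypes of the curated cohort with their published
#: phenotype breakdowns (used as a compact in-paper test cohort).
TOP_GENOTYPES: list[tuple[str, str, dict[Phenotype, int]]] = [
    ("c.465+1G>A", "c.465+1G>A", {Phenotype.INFANTILE: 32, Phenotype.UNKNOWN: 1}),
    ("c.465+1G>A", "p.P428L", {Phenotype.JUVENILE: 25, Phenotype.INFANTILE: 1}),
    ("p.P428L", "p.P428L", {Phenotype.JUVENILE: 15, Phenotype.ADULT: 9}),
    ("c.465+1G>A", "p.I181S", {Phenotype.ADULT: 4, Phenotype.JUVENILE: 4, Phenotype.INFANTILE: 1}),
    ("p.R313X", "p.R313X", {Phenotype.INFANTILE: 6, Phenotype.UNKNOWN: 1}),
    ("c.465+1G>A", "p.R290H", {Phenotype.ADULT: 3, Phenotype.JUVENILE: 2}),
    ("c.465+1G>A", "p.R86W", {Phenotype.JUVENILE: 5}),
    ("c.465+1G>A", "c.855-1G>A", {Phenotype.INFANTILE: 4}),
    ("c.465+1G>A", "p.R86Q", {Phenotype.INFANTILE: 2, Phenotype.JUVENILE: 2}),
    ("p.R86Q", "p.S98F", {Phenotype.ADULT: 2, Phenotype.JUVENILE: 2}),
]

#: Patient-based severity of the well-characterized alleles above.
TOP_SEVERITIES: dict[str, SeverityClass] = {
    "c.465+1G>A": SeverityClass.SEVERE,
    "p.P428L": SeverityClass.MODERATE,
    "p.I181S": SeverityClass.MILD,
    "p.R313X": SeverityClass.SEVERE,
    "p.R290H": SeverityClass.MILD,
    "p.R86W": SeverityClass.MODERATE,
    "c.855-1G>A": SeverityClass.SEVERE,
    "p.R86Q": SeverityClass.MODERATE,
    "p.S98F": SeverityClass.MODERATE,
}


@pytest.fixture
def top_genotype_cohort() -> list[PatientRecord]:
    records = []
    for a, b, tally in TOP_GENOTYPES:
        records.extend(make_records(a, b, tally))
    return records


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=20260921,
        phenotype_misclassification_rate=0.0,
        activity_noise_sd=0.0,
        n_patients=600,
    )
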