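"""The phenotype matrix: genotype -> phenotype prediction, entropy, accuracy.

The matrix is a symmetric look-up table mapping an unordered pair of allele
severity classes to the expected MLD presentation, built on the assumption
that the impact of the two ARSA alleles on residual enzyme activity is
additive: two severe alleles give the earliest-onset (infantile/late-infantile)
form, and each step up in residual activity gives a later-onset, milder
phenotype. A genotype containing an uncharacterized allele (VUS) has a
predictable phenotype only when the partner allele is benign -- every other
VUS pairing is a genotype of unknown significance (GUS).

Genotype-phenotype consistency is quantified by the Shannon entropy
``H[G] = -sum_i p_i ln p_i`` of the phenotype distribution observed for a
genotype: 0 means perfectly consistent, ln k is the maximum over k categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .datamodel import (
    GenotypeSummary,
    ObservationCount,
    PatientRecord,
    Phenotype,
    SeverityClass,
    count_variant_observations,
)

__all__ = [
    "PhenotypeMatrix",
    "predict_phenotype",
    "genotype_entropy",
    "evaluate_matrix_accuracy",
    "entropy_summary",
    "GenotypeAccuracy",
    "MatrixAccuracy",
    "EntropySummary",
]

_CLASSES = (
    SeverityClass.SEVERE,
    SeverityClass.MODERATE,
    SeverityClass.MILD,
    SeverityClass.BENIGN,
    SeverityClass.UNKNOWN,
)


def _pair(a: SeverityClass, b: SeverityClass) -> tuple[str, str]:
    x, y = sorted((a.value, b.value))
    return (x, y)


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Symmetric map from an unordered severity-class pair to a phenotype."""

    table: Mapping[tuple[str, str], Phenotype]

    def __post_init__(self) -> None:
        expected = {_pair(a, b) for a in _CLASSES for b in _CLASSES}
        got = set(self.table)
        if got != expected:
            raise ValueError(
                "phenotype matrix must cover all 15 unordered severity pairs;"
                f" missing {sorted(expected - got)}, extra {sorted(got - expected)}"
            )

    def predict(self, s1: SeverityClass, s2: SeverityClass) -> Phenotype:
        """Look up the expected phenotype for an unordered severity pair."""
        return self.table[_pair(s1, s2)]

    @classmethod
    def default(cls) -> "PhenotypeMatrix":
        """The default matrix shipped with the package."""
        with resources.as_file(
            resources.files("mldmatrix").joinpath("data/phenotype_matrix.tsv")
        ) as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMatrix":
        """Load a matrix from a 5x5 grid with severity labels as headers.

        The grid must be symmetric; asymmetry is an error, not silently
        resolved.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        table: dict[tuple[str, str], Phenotype] = {}
        for row_cls in df.index:
            for col_cls in df.columns:
                a = SeverityClass(row_cls.strip().lower())
                b = SeverityClass(col_cls.strip().lower())
                phen = Phenotype(str(df.loc[row_cls, col_cls]).strip().lower())
                key = _pair(a, b)
                if key in table and table[key] is not phen:
                    raise ValueError(f"asymmetric matrix at {key}")
                table[key] = phen
        return cls(table=table)

    def to_tsv(self, path) -> None:
        labels = [c.value for c in _CLASSES]
        grid = [
            [self.table[_pair(SeverityClass(r), SeverityClass(c))].value for c in labels]
            for r in labels
        ]
        pd.DataFrame(grid, index=labels, columns=labels).to_csv(
            path, sep="\t", index_label="severity"
        )


def predict_phenotype(
    s1: SeverityClass, s2: SeverityClass, matrix: Optional[PhenotypeMatrix] = None
) -> Phenotype:
    """Expected phenotype for a biallelic genotype with allele severities
    ``s1`` and ``s2`` (order irrelevant)."""
    if matrix is None:
        matrix = PhenotypeMatrix.default()
    return matrix.predict(s1, s2)


def genotype_entropy(phenotype_counts: Mapping[Phenotype, int | float]) -> float:
    """Shannon entropy (natural log) of a genotype's phenotype tally.

    Every category present with a positive count contributes, including
    ``unknown``; zero counts are ignored. Raises on an all-zero or negative
    tally.
    """
    total = 0.0
    for phen, n in phenotype_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {phen}: {n}")
        total += n
    if total <= 0:
        raise ValueError("entropy of an empty phenotype tally is undefined")
    h = 0.0
    for n in phenotype_counts.values():
        if n > 0:
            p = n / total
            h -= p * math.log(p)
    return h


@dataclass
class GenotypeAccuracy:
    """Per-genotype breakdown of matrix-prediction accuracy."""

    key: object  # GenotypeKey
    predicted: Phenotype
    n_matched: int
    n_evaluated: int

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_matched / self.n_evaluated


@dataclass
class MatrixAccuracy:
    """Cohort-level accuracy of matrix phenotype prediction."""

    overall_accuracy: float  # percent
    n_matched: int
    n_evaluated: int
    per_genotype: list[GenotypeAccuracy]


def evaluate_matrix_accuracy(
    records: Sequence[PatientRecord],
    severities: Mapping[str, SeverityClass],
    matrix: Optional[PhenotypeMatrix] = None,
    min_patients: int = 5,
    exclude: Optional[set[str]] = None,
) -> MatrixAccuracy:
    """Fraction of observed phenotypes matching the matrix prediction.

    The evaluation is restricted to complete records whose both alleles were
    observed in at least ``min_patients`` carriers in ``records`` and are not
    in ``exclude``. Records with an unknown observed phenotype are dropped
    from the denominator. Accuracy is reported as a percentage.
    """
    if matrix is None:
        matrix = PhenotypeMatrix.default()
    exclude = exclude or set()
    counts = count_variant_observations(records)

    per_key: dict[object, GenotypeAccuracy] = {}
    n_matched = 0
    n_evaluated = 0
    for r in records:
        key = r.genotype_key
        if key is None:
            continue
        a, b = key.allele1, key.allele2
        if a in exclude or b in exclude:
            continue
        if counts[a].patient_count < min_patients or counts[b].patient_count < min_patients:
            continue
        predicted = matrix.predict(
            severities.get(a, SeverityClass.UNKNOWN),
            severities.get(b, SeverityClass.UNKNOWN),
        )
        if key not in per_key:
            per_key[key] = GenotypeAccuracy(key=key, predicted=predicted, n_matched=0, n_evaluated=0)
        if r.phenotype is Phenotype.UNKNOWN:
            continue
        n_evaluated += 1
        per_key[key].n_evaluated += 1
        if r.phenotype is predicted:
            n_matched += 1
            per_key[key].n_matched += 1
    if n_evaluated == 0:
        raise ValueError("no records eligible for accuracy evaluation")
    per_genotype = [g for g in per_key.values() if g.n_evaluated > 0]
    return MatrixAccuracy(
        overall_accuracy=100.0 * n_matched / n_evaluated,
        n_matched=n_matched,
        n_evaluated=n_evaluated,
        per_genotype=per_genotype,
    )


@dataclass
class EntropySummary:
    mean: float
    sd: float  # population (n-denominator) standard deviation
    n_genotypes: int
    n_patients: int


def entropy_summary(
    summaries: Iterable[GenotypeSummary],
    observation_counts: Mapping[str, ObservationCount],
    min_patients_per_allele: int = 5,
) -> EntropySummary:
    """Mean and population SD of entropy over well-observed genotypes.

    Restricted to genotypes whose both alleles were each observed in at least
    ``min_patients_per_allele`` carriers.
    """
    entropies: list[float] = []
    n_patients = 0
    for s in summaries:
        a, b = s.key.allele1, s.key.allele2
        ca = observation_counts.get(a)
        cb = observation_counts.get(b)
        if ca is None or cb is None:
            continue
        if ca.patient_count < min_patients_per_allele or cb.patient_count < min_patients_per_allele:
            continue
        entropies.append(s.entropy)
        n_patients += s.n_patients
    if not entropies:
        raise ValueError("no genotypes meet the per-allele observation threshold")
    n = len(entropies)
    mean = sum(entropies) / n
    var = sum((h - mean) ** 2 for h in entropies) / n
    return EntropySummary(mean=mean, sd=math.sqrt(var), n_genotypes=n, n_patients=n_patients)
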