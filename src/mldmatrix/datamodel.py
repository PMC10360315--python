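"""Domain types and table I/O for the curated MLD patient/variant data.

The package works from three delimited-text tables: a curated patient table
(one row per literature case: two ARSA alleles, phenotype, optional age of
onset), a variant annotation table (consequence, ClinVar label, per-population
gnomAD allele frequencies/numbers, in-silico predictor scores), and an
enzyme-activity table (handled in :mod:`mldmatrix.activity`).

Alleles are identified by their HGVS string exactly as given (whitespace
stripped, ``c.``/``p.`` prefix case normalized); no transcript-coordinate
conversion is attempted.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "SeverityClass",
    "Phenotype",
    "Variant",
    "PatientRecord",
    "GenotypeKey",
    "GenotypeSummary",
    "ObservationCount",
    "POPULATIONS",
    "INFANTILE_ONSET_MAX_YEARS",
    "JUVENILE_ONSET_MAX_YEARS",
    "canonical_hgvs",
    "phenotype_from_onset",
    "most_severe",
    "severity_rank",
    "parse_patient_table",
    "write_patient_table",
    "parse_variant_table",
    "write_variant_table",
    "tabulate_genotypes",
    "count_variant_observations",
]

#: gnomAD subpopulation column suffixes recognized in variant tables.
POPULATIONS = ("all", "afr", "asj", "amr", "eas", "fin", "nfe", "sas", "oth")

#: Age-of-onset cutoffs (years) separating the three MLD presentations.
INFANTILE_ONSET_MAX_YEARS = 2.5
JUVENILE_ONSET_MAX_YEARS = 16.0


class SeverityClass(str, enum.Enum):
    """Functional severity of one ARSA allele.

    ``severe > moderate > mild > benign`` orders residual-activity impact;
    ``unknown`` marks an uncharacterized allele (VUS) and is incomparable.
    """

    SEVERE = "severe"
    MODERATE = "moderate"
    MILD = "mild"
    BENIGN = "benign"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ordinal position of each comparable class (0 = most severe).
_SEVERITY_RANK = {
    SeverityClass.SEVERE: 0,
    SeverityClass.MODERATE: 1,
    SeverityClass.MILD: 2,
    SeverityClass.BENIGN: 3,
}


def severity_rank(cls: SeverityClass) -> int:
    """Ordinal rank of a comparable severity class (0 = severe ... 3 = benign).

    Raises ``ValueError`` for ``unknown``, which has no place in the order.
    """
    try:
        return _SEVERITY_RANK[cls]
    except KeyError:
        raise ValueError("'unknown' severity has no ordinal rank") from None


def most_severe(classes: Iterable[SeverityClass]) -> SeverityClass:
    """The most severe class among ``classes``, ignoring ``unknown``.

    Returns ``unknown`` when no comparable class is present.
    """
    best = SeverityClass.UNKNOWN
    for c in classes:
        if c is SeverityClass.UNKNOWN:
            continue
        if best is SeverityClass.UNKNOWN or severity_rank(c) < severity_rank(best):
            best = c
    return best


class Phenotype(str, enum.Enum):
    """MLD presentation, ordered by age of onset (infantile = earliest)."""

    INFANTILE = "infantile"  # infantile / late-infantile, onset < 2.5 y
    JUVENILE = "juvenile"  # onset 2.5-16 y
    ADULT = "adult"  # onset > 16 y
    ASYMPTOMATIC = "asymptomatic"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Symptomatic presentations (the three the curated literature reports).
SYMPTOMATIC_PHENOTYPES = (Phenotype.INFANTILE, Phenotype.JUVENILE, Phenotype.ADULT)

_PHENOTYPE_ALIASES = {
    "infantile": Phenotype.INFANTILE,
    "late-infantile": Phenotype.INFANTILE,
    "late infantile": Phenotype.INFANTILE,
    "late_infantile": Phenotype.INFANTILE,
    "infantile/late-infantile": Phenotype.INFANTILE,
    "infantile/late_infantile": Phenotype.INFANTILE,
    "infantile_late_infantile": Phenotype.INFANTILE,
    "juvenile": Phenotype.JUVENILE,
    "early juvenile": Phenotype.JUVENILE,
    "late juvenile": Phenotype.JUVENILE,
    "adult": Phenotype.ADULT,
    "asymptomatic": Phenotype.ASYMPTOMATIC,
    "unknown": Phenotype.UNKNOWN,
    "": Phenotype.UNKNOWN,
}


def parse_phenotype(text: str) -> Phenotype:
    """Map a free-text phenotype label to the enum, case-insensitively."""
    key = text.strip().lower()
    try:
        return _PHENOTYPE_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized phenotype label: {text!r}") from None


def phenotype_from_onset(age_years: float) -> Phenotype:
    """Presentation implied by an age of onset, using the standard cutoffs."""
    if age_years < 0:
        raise ValueError("age of onset must be non-negative")
    if age_years < INFANTILE_ONSET_MAX_YEARS:
        return Phenotype.INFANTILE
    if age_years <= JUVENILE_ONSET_MAX_YEARS:
        return Phenotype.JUVENILE
    return Phenotype.ADULT


class Consequence(str, enum.Enum):
    """Molecular consequence class of a variant."""

    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_DELETION = "inframe_deletion"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def canonical_hgvs(text: str) -> str:
    """Canonicalize an HGVS identifier by exact-string normalization.

    Strips surrounding/internal whitespace and lower-cases a leading ``C.`` or
    ``P.`` prefix. No coordinate or transcript conversion is performed.
    """
    s = "".join(text.split())
    if s[:2] in ("C.", "P."):
        s = s[0].lower() + s[1:]
    return s


@dataclass
class Variant:
    """One ARSA allele with its annotations and severity assignments.

    ``id`` is the canonical HGVS c. string (or p. string for legacy tables that
    identify missense alleles that way); it is the join key across all tables.
    """

    id: str
    hgvs_p: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    clinvar_label: Optional[str] = None
    freq_by_population: dict[str, float] = field(default_factory=dict)
    allele_number_by_population: dict[str, int] = field(default_factory=dict)
    predictor_scores: dict[str, float] = field(default_factory=dict)
    patient_based_severity: SeverityClass = SeverityClass.UNKNOWN
    activity_based_severity_cds: SeverityClass = SeverityClass.UNKNOWN
    activity_based_severity_genomic: SeverityClass = SeverityClass.UNKNOWN
    finalized_severity: SeverityClass = SeverityClass.UNKNOWN

    def __post_init__(self) -> None:
        self.id = canonical_hgvs(self.id)
        if not self.id:
            raise ValueError("variant id must be non-empty")
        self.consequence = Consequence(self.consequence)
        for attr in (
            "patient_based_severity",
            "activity_based_severity_cds",
            "activity_based_severity_genomic",
            "finalized_severity",
        ):
            setattr(self, attr, SeverityClass(getattr(self, attr)))
        for pop, f in self.freq_by_population.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency for {pop!r} outside [0, 1]: {f}")

    def frequency(self, population: str, default: float | None = None) -> float:
        """Allele frequency in ``population``; warns and returns 0 if absent
        (unless ``default`` is given)."""
        if population in self.freq_by_population:
            return self.freq_by_population[population]
        if default is not None:
            return default
        warnings.warn(
            f"variant {self.id} has no frequency for population {population!r};"
            " using 0",
            stacklevel=2,
        )
        return 0.0


@dataclass(frozen=True, order=True)
class GenotypeKey:
    """Unordered pair of allele ids; homozygotes are keyed ``(a, a)``."""

    allele1: str
    allele2: str

    @classmethod
    def of(cls, a: str, b: str) -> "GenotypeKey":
        a, b = sorted((canonical_hgvs(a), canonical_hgvs(b)))
        return cls(a, b)

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.allele1}/{self.allele2}"


@dataclass
class PatientRecord:
    """One curated case: an unordered allele pair and its phenotype.

    ``allele2`` is ``None`` when the literature reported only one allele; such
    incomplete records are excluded from genotype tabulation but still
    contribute their known allele to per-variant tallies.
    """

    patient_id: str
    allele1: str
    allele2: Optional[str] = None
    phenotype: Phenotype = Phenotype.UNKNOWN
    age_of_onset_years: Optional[float] = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        self.allele1 = canonical_hgvs(self.allele1)
        if not self.allele1:
            raise ValueError(f"patient {self.patient_id}: allele1 is required")
        if self.allele2 is not None:
            a2 = canonical_hgvs(self.allele2)
            self.allele2 = a2 or None
        if self.age_of_onset_years is not None and self.age_of_onset_years < 0:
            raise ValueError(
                f"patient {self.patient_id}: negative age of onset"
            )

    @property
    def is_complete(self) -> bool:
        return self.allele2 is not None

    @property
    def genotype_key(self) -> Optional[GenotypeKey]:
        if not self.is_complete:
            return None
        return GenotypeKey.of(self.allele1, self.allele2)

    @property
    def alleles(self) -> tuple[str, ...]:
        """Known allele ids (one for incomplete records, two otherwise)."""
        if self.allele2 is None:
            return (self.allele1,)
        return (self.allele1, self.allele2)


@dataclass
class GenotypeSummary:
    """Phenotype tally for one genotype across the cohort."""

    key: GenotypeKey
    n_patients: int
    phenotype_counts: dict[Phenotype, int]
    entropy: float
    mean_onset_years: Optional[float] = None


@dataclass(frozen=True)
class ObservationCount:
    """How often a variant was seen in the cohort.

    ``patient_count`` counts carriers (a homozygote counts once);
    ``allele_count`` counts allele slots (a homozygote counts twice).
    """

    patient_count: int
    allele_count: int


# ---------------------------------------------------------------------------
# Patient table I/O
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = ("patient_id", "allele1", "allele2", "phenotype")


def _check_onset_consistency(record: PatientRecord, row_label: str, strict: bool) -> None:
    if record.age_of_onset_years is None or record.phenotype not in SYMPTOMATIC_PHENOTYPES:
        return
    implied = phenotype_from_onset(record.age_of_onset_years)
    if implied is not record.phenotype:
        msg = (
            f"{row_label}: age of onset {record.age_of_onset_years} y implies"
            f" {implied.value!r} but phenotype is {record.phenotype.value!r}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=3)


def parse_patient_table(path, *, strict: bool = False) -> list[PatientRecord]:
    """Read a tab-separated curated patient table.

    The file must have a header naming at least ``patient_id``, ``allele1``,
    ``allele2`` and ``phenotype``; ``age_of_onset_years`` and ``source_ref``
    are optional. Empty cells are missing values. A blank ``allele2`` yields an
    incomplete record. Phenotype/onset inconsistencies warn unless
    ``strict=True``, in which case they raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table is missing columns: {missing}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate patient_id values: {dupes}")

    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        label = f"row {i + 2} (patient {row['patient_id']!r})"
        try:
            phenotype = parse_phenotype(row["phenotype"])
        except ValueError as exc:
            raise ValueError(f"{label}: {exc}") from None
        onset_text = str(row.get("age_of_onset_years", "")).strip()
        onset = float(onset_text) if onset_text else None
        record = PatientRecord(
            patient_id=row["patient_id"],
            allele1=row["allele1"],
            allele2=row["allele2"] or None,
            phenotype=phenotype,
            age_of_onset_years=onset,
            source_ref=str(row.get("source_ref", "")),
        )
        _check_onset_consistency(record, label, strict)
        records.append(record)
    return records


def write_patient_table(records: Iterable[PatientRecord], path) -> None:
    """Write records as a tab-separated table that round-trips through
    :func:`parse_patient_table`."""
    rows = [
        {
            "patient_id": r.patient_id,
            "allele1": r.allele1,
            "allele2": r.allele2 or "",
            "phenotype": r.phenotype.value,
            "age_of_onset_years": "" if r.age_of_onset_years is None else r.age_of_onset_years,
            "source_ref": r.source_ref,
        }
        for r in records
    ]
    columns = ["patient_id", "allele1", "allele2", "phenotype", "age_of_onset_years", "source_ref"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

_SEVERITY_COLUMNS = (
    "patient_based_severity",
    "activity_based_severity_cds",
    "activity_based_severity_genomic",
    "finalized_severity",
)


def parse_variant_table(path) -> dict[str, Variant]:
    """Read a tab-separated variant annotation table keyed by variant id.

    Recognized columns: ``id``, ``hgvs_p``, ``consequence``, ``clinvar_label``,
    ``freq_<POP>`` / ``an_<POP>`` for each gnomAD population suffix, predictor
    score columns ``sift`` / ``polyphen`` / ``revel``, and the four severity
    columns. Only ``id`` is required.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("variant table must have an 'id' column")
    variants: dict[str, Variant] = {}
    for i, row in df.iterrows():
        freq = {}
        an = {}
        for pop in POPULATIONS:
            f = str(row.get(f"freq_{pop}", "")).strip()
            if f:
                freq[pop] = float(f)
            a = str(row.get(f"an_{pop}", "")).strip()
            if a:
                an[pop] = int(float(a))
        scores = {}
        for name, col in (("SIFT", "sift"), ("PolyPhen", "polyphen"), ("REVEL", "revel")):
            s = str(row.get(col, "")).strip()
            if s:
                scores[name] = float(s)
        severities = {}
        for col in _SEVERITY_COLUMNS:
            s = str(row.get(col, "")).strip().lower()
            severities[col] = SeverityClass(s) if s else SeverityClass.UNKNOWN
        consequence_text = str(row.get("consequence", "")).strip().lower()
        variant = Variant(
            id=row["id"],
            hgvs_p=str(row.get("hgvs_p", "")).strip() or None,
            consequence=Consequence(consequence_text) if consequence_text else Consequence.OTHER,
            clinvar_label=str(row.get("clinvar_label", "")).strip() or None,
            freq_by_population=freq,
            allele_number_by_population=an,
            predictor_scores=scores,
            **severities,
        )
        if variant.id in variants:
            raise ValueError(f"row {i + 2}: duplicate variant id {variant.id!r}")
        variants[variant.id] = variant
    return variants


def write_variant_table(variants: Iterable[Variant], path) -> None:
    """Write variants as a tab-separated table that round-trips through
    :func:`parse_variant_table`."""
    rows = []
    for v in variants:
        row: dict[str, object] = {
            "id": v.id,
            "hgvs_p": v.hgvs_p or "",
            "consequence": v.consequence.value,
            "clinvar_label": v.clinvar_label or "",
        }
        for pop in POPULATIONS:
            row[f"freq_{pop}"] = v.freq_by_population.get(pop, "")
            row[f"an_{pop}"] = v.allele_number_by_population.get(pop, "")
        row["sift"] = v.predictor_scores.get("SIFT", "")
        row["polyphen"] = v.predictor_scores.get("PolyPhen", "")
        row["revel"] = v.predictor_scores.get("REVEL", "")
        for col in _SEVERITY_COLUMNS:
            row[col] = getattr(v, col).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_genotypes(records: Iterable[PatientRecord]) -> dict[GenotypeKey, GenotypeSummary]:
    """Group complete records by unordered genotype and tally phenotypes.

    Incomplete records (one known allele) are excluded. Mean onset is computed
    over the records that report an age of onset. Entropy is the Shannon
    entropy (natural log) of the phenotype tally, with every observed category
    -- including ``unknown`` -- contributing.
    """
    from .matrix import genotype_entropy  # local import to avoid a cycle

    counts: dict[GenotypeKey, Counter] = {}
    onsets: dict[GenotypeKey, list[float]] = {}
    for r in records:
        key = r.genotype_key
        if key is None:
            continue
        counts.setdefault(key, Counter())[r.phenotype] += 1
        if r.age_of_onset_years is not None:
            onsets.setdefault(key, []).append(r.age_of_onset_years)

    out: dict[GenotypeKey, GenotypeSummary] = {}
    for key, tally in counts.items():
        ages = onsets.get(key, [])
        out[key] = GenotypeSummary(
            key=key,
            n_patients=sum(tally.values()),
            phenotype_counts=dict(tally),
            entropy=genotype_entropy(tally),
            mean_onset_years=(sum(ages) / len(ages)) if ages else None,
        )
    return out


def count_variant_observations(
    records: Iterable[PatientRecord],
) -> dict[str, ObservationCount]:
    """Per-variant carrier and allele tallies across the cohort.

    A homozygote contributes one to ``patient_count`` and two to
    ``allele_count``; incomplete records contribute their single known allele
    to both tallies.
    """
    patient: Counter = Counter()
    allele: Counter = Counter()
    for r in records:
        for v in set(r.alleles):
            patient[v] += 1
        for v in r.alleles:
            allele[v] += 1
    return {
        v: ObservationCount(patient_count=patient[v], allele_count=allele[v])
        for v in allele
    }
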