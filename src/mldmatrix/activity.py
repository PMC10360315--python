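"""Enzyme-activity normalization, severity brackets, and concordance metrics.

The assay expresses ARSA variants (in a CDS or intron-inclusive genomic
construct) in ARSA-knockout HEK293T cells and measures sulfatide catabolism by
LC-MS/MS, with co-expressed beta-lactamase (BLA) as a transfection control.
Each well yields a blank-subtracted product/internal-standard ion ratio for
ARSA and for BLA; the normalized activity of a well is ARSA ratio / BLA ratio,
and a variant's percent-of-wild-type activity is

    100 * (variant normalized activity) / (mean wild-type normalized activity)

against the wild-type wells of the same plate (per-plate referencing absorbs
assay drift between batches). Values can be slightly negative after blank
subtraction; negative values reflect null enzymatic activity.

Percent-of-wild-type activity maps to an activity-based severity class via
fixed brackets derived from the well-characterized patient alleles:
< 2% severe, 2 to < 4% moderate, 4 to 13% mild, > 13% benign. 13% is also the
pathogenic/benign screening threshold.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SeverityClass, severity_rank

__all__ = [
    "Construct",
    "ActivityMeasurement",
    "ActivityResult",
    "SeverityBrackets",
    "DiagnosticMetrics",
    "DEFAULT_FINALIZATION_OVERRIDES",
    "percent_wt_activity",
    "activity_based_severity",
    "finalize_severity",
    "diagnostic_metrics",
    "predictor_correlation",
    "parse_activity_table",
    "write_activity_results",
]


class Construct(str, enum.Enum):
    CDS = "cds"
    GENOMIC = "genomic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ActivityMeasurement:
    """Replicate ion-ratio pairs for one variant (or wild-type) on one plate.

    Each replicate is a ``(target_enzyme_ratio, control_enzyme_ratio)`` pair of
    blank-subtracted ion ratios (ARSA and BLA respectively). Ratios may be
    negative after blank subtraction.
    """

    variant_id: str
    construct: Construct
    replicate_ion_ratios: list[tuple[float, float]]
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        if not self.replicate_ion_ratios:
            raise ValueError(f"{self.variant_id}: at least one replicate required")
        for t, c in self.replicate_ion_ratios:
            if not (math.isfinite(t) and math.isfinite(c)):
                raise ValueError(f"{self.variant_id}: non-finite ion ratio")


@dataclass
class ActivityResult:
    """Percent-of-wild-type activity for one variant/construct."""

    variant_id: str
    construct: Construct
    mean_percent_wt: float
    sd_percent_wt: float
    activity_based_severity: SeverityClass = SeverityClass.UNKNOWN
    n_replicates: int = 0


@dataclass(frozen=True)
class SeverityBrackets:
    """Percent-of-wild-type activity limits for each severity class.

    ``severe_upper`` and ``moderate_upper`` are exclusive upper bounds;
    ``mild_upper`` is inclusive (a variant at exactly 13% is mild, and 13% is
    the pathogenic screening threshold). Negative activities are severe.
    """

    severe_upper: float = 2.0
    moderate_upper: float = 4.0
    mild_upper: float = 13.0

    def __post_init__(self) -> None:
        if not (0.0 < self.severe_upper < self.moderate_upper < self.mild_upper):
            raise ValueError("brackets must satisfy 0 < severe < moderate < mild")

    @property
    def pathogenic_threshold(self) -> float:
        return self.mild_upper


def percent_wt_activity(
    variant: ActivityMeasurement,
    wildtype: ActivityMeasurement,
    brackets: Optional[SeverityBrackets] = None,
) -> ActivityResult:
    """Normalize a variant's replicates to percent of wild-type activity.

    Per replicate, normalized activity = target ratio / control ratio; the
    percent of wild-type is 100 x normalized / mean wild-type normalized
    activity over the wild-type wells of the same plate. Replicates with a
    zero control ratio are dropped with a warning. The mean wild-type
    normalized activity must be strictly positive.

    When ``brackets`` is given the activity-based severity of the mean is
    filled in; otherwise it is left ``unknown``.
    """
    if variant.construct is not wildtype.construct:
        raise ValueError("variant and wild-type measurements use different constructs")
    if variant.plate_id != wildtype.plate_id:
        raise ValueError("variant and wild-type measurements come from different plates")

    def normalized(m: ActivityMeasurement) -> np.ndarray:
        vals = []
        for t, c in m.replicate_ion_ratios:
            if c == 0:
                warnings.warn(
                    f"{m.variant_id}: replicate with zero control ratio dropped",
                    stacklevel=3,
                )
                continue
            vals.append(t / c)
        return np.asarray(vals, dtype=float)

    wt = normalized(wildtype)
    if wt.size == 0:
        raise ValueError("wild-type measurement has no usable replicates")
    wt_mean = float(wt.mean())
    if wt_mean <= 0:
        raise ValueError(f"wild-type normalized activity must be positive, got {wt_mean}")
    var = normalized(variant)
    if var.size == 0:
        raise ValueError(f"{variant.variant_id}: no usable replicates")
    percents = 100.0 * var / wt_mean
    mean = float(percents.mean())
    sd = float(percents.std(ddof=1)) if percents.size > 1 else 0.0
    severity = (
        activity_based_severity(mean, brackets) if brackets is not None else SeverityClass.UNKNOWN
    )
    return ActivityResult(
        variant_id=variant.variant_id,
        construct=variant.construct,
        mean_percent_wt=mean,
        sd_percent_wt=sd,
        activity_based_severity=severity,
        n_replicates=int(percents.size),
    )


def activity_based_severity(
    percent_wt: float, brackets: Optional[SeverityBrackets] = None
) -> SeverityClass:
    """Bracket a percent-of-wild-type activity into a severity class.

    Negative values (null activity after blank subtraction) are severe; the
    mild bracket is closed at its upper limit (13.0 -> mild, 13.0+eps ->
    benign).
    """
    if brackets is None:
        brackets = SeverityBrackets()
    if not math.isfinite(percent_wt):
        raise ValueError(f"non-finite activity: {percent_wt}")
    if percent_wt < brackets.severe_upper:
        return SeverityClass.SEVERE
    if percent_wt < brackets.moderate_upper:
        return SeverityClass.MODERATE
    if percent_wt <= brackets.mild_upper:
        return SeverityClass.MILD
    return SeverityClass.BENIGN


#: p.P428L is pinned to its patient-based (moderate) class: it assays severe
#: (0.04% of wild-type) in HEK293T cells, likely through cathepsin-L proteolysis
#: absent in disease-relevant tissue, while 117 curated patients show moderate
#: disease.
DEFAULT_FINALIZATION_OVERRIDES: Mapping[str, SeverityClass] = {
    "p.P428L": SeverityClass.MODERATE,
}


def _closer_to(target: SeverityClass, a: SeverityClass, b: SeverityClass) -> SeverityClass:
    """Of two comparable classes, the one ordinally closer to ``target``;
    ties break toward the more severe call (conservative for screening)."""
    da = abs(severity_rank(a) - severity_rank(target))
    db = abs(severity_rank(b) - severity_rank(target))
    if da < db:
        return a
    if db < da:
        return b
    return a if severity_rank(a) < severity_rank(b) else b


def finalize_severity(
    patient_based: SeverityClass,
    cds: Optional[SeverityClass] = None,
    genomic: Optional[SeverityClass] = None,
    overrides: Optional[Mapping[str, SeverityClass]] = None,
    variant_id: Optional[str] = None,
) -> SeverityClass:
    """Reconcile patient-based and activity-based calls into one class.

    Explicit overrides win. Otherwise patient evidence wins whenever present;
    with no patient-based class the CDS and genomic activity calls are used
    (agreement or a single call is taken as-is; on disagreement the call
    ordinally closer to the patient-based class is taken, ties and the
    no-patient-evidence case resolving toward the more severe call). All
    inputs unknown yields ``unknown``, not an error.
    """
    if overrides is None:
        overrides = DEFAULT_FINALIZATION_OVERRIDES
    if variant_id is not None and variant_id in overrides:
        return overrides[variant_id]

    cds = cds or SeverityClass.UNKNOWN
    genomic = genomic or SeverityClass.UNKNOWN
    calls = [c for c in (cds, genomic) if c is not SeverityClass.UNKNOWN]

    if patient_based is SeverityClass.UNKNOWN:
        if not calls:
            return SeverityClass.UNKNOWN
        if len(calls) == 1 or calls[0] is calls[1]:
            return calls[0]
        # CDS vs genomic disagreement with no patient anchor: take the more
        # severe call (conservative for screening).
        return calls[0] if severity_rank(calls[0]) < severity_rank(calls[1]) else calls[1]

    if not calls or patient_based in calls:
        return patient_based
    if len(calls) == 2 and calls[0] is not calls[1]:
        return _closer_to(patient_based, calls[0], calls[1])
    # activity agrees with itself but contradicts patient evidence: concede to
    # the literature consensus.
    return patient_based


@dataclass
class DiagnosticMetrics:
    """2x2 performance of the pathogenic/benign activity call."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # percent
    specificity: float  # percent
    lr_plus: float  # may be inf
    dor: float  # may be inf


def diagnostic_metrics(
    truth: Mapping[str, str],
    percent_wt: Mapping[str, float],
    threshold: float = 13.0,
) -> DiagnosticMetrics:
    """Sensitivity/specificity/LR+/DOR of calling pathogenic at <= threshold.

    ``truth`` maps variant id to ``"pathogenic"`` or ``"benign"`` (derive it
    upstream from patient-based severity: severe/moderate/mild -> pathogenic).
    Ratios with zero denominators are reported as ``inf``, not errors.
    """
    ids = sorted(set(truth) & set(percent_wt))
    if not ids:
        raise ValueError("no variants shared between truth and activity maps")
    tp = fp = fn = tn = 0
    for vid in ids:
        label = truth[vid].strip().lower()
        if label not in ("pathogenic", "benign"):
            raise ValueError(f"{vid}: truth label must be 'pathogenic' or 'benign'")
        call_pathogenic = percent_wt[vid] <= threshold
        if label == "pathogenic":
            tp += call_pathogenic
            fn += not call_pathogenic
        else:
            fp += call_pathogenic
            tn += not call_pathogenic
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else math.inf
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else math.inf
    fpr = fp / (tn + fp) if (tn + fp) else math.nan
    lr_plus = (sens / 100.0) / fpr if fpr else math.inf
    dor = (tp * tn) / (fp * fn) if fp * fn else math.inf
    return DiagnosticMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, lr_plus=lr_plus, dor=dor,
    )


def predictor_correlation(
    percent_wt: Mapping[str, float], scores: Mapping[str, float]
) -> float:
    """Pearson correlation between activity and an in-silico predictor score.

    Computed on the id intersection; requires at least 3 paired observations
    and non-degenerate variance in both vectors. Exclude ClinVar-characterized
    variants upstream when reproducing predictor benchmarks, since ClinVar is
    in those predictors' training data.
    """
    ids = sorted(set(percent_wt) & set(scores))
    if len(ids) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(ids)}")
    x = np.asarray([percent_wt[i] for i in ids], dtype=float)
    y = np.asarray([scores[i] for i in ids], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def parse_activity_table(path) -> list[ActivityMeasurement]:
    """Read a tab-separated activity table into grouped measurements.

    Columns: ``id``, ``construct``, ``plate_id``, ``replicate``,
    ``arsa_ion_ratio``, ``bla_ion_ratio``. Rows are grouped by
    (id, construct, plate_id), replicates ordered by the ``replicate`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("id", "construct", "plate_id", "replicate", "arsa_ion_ratio", "bla_ion_ratio")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"activity table is missing columns: {missing}")
    out: dict[tuple[str, str, str], list[tuple[int, float, float]]] = {}
    for _, row in df.iterrows():
        key = (row["id"], row["construct"].strip().lower(), row["plate_id"])
        out.setdefault(key, []).append(
            (int(row["replicate"]), float(row["arsa_ion_ratio"]), float(row["bla_ion_ratio"]))
        )
    measurements = []
    for (vid, construct, plate), rows in out.items():
        rows.sort()
        measurements.append(
            ActivityMeasurement(
                variant_id=vid,
                construct=Construct(construct),
                replicate_ion_ratios=[(t, c) for _, t, c in rows],
                plate_id=plate,
            )
        )
    return measurements


def write_activity_results(results: Iterable[ActivityResult], path) -> None:
    """Write activity results as a tab-separated table."""
    rows = [
        {
            "id": r.variant_id,
            "construct": r.construct.value,
            "mean_percent_wt": r.mean_percent_wt,
            "sd_percent_wt": r.sd_percent_wt,
            "severity": r.activity_based_severity.value,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
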