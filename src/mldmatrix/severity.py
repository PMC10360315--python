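"""Patient-based severity classification of ARSA variants.

Variant severity is inferred from the curated cohort by iterating a small
ruleset to a fixpoint. The logic rests on the recessive additive model behind
the phenotype matrix: an infantile/late-infantile presentation implies two
severe alleles, juvenile implies severe+moderate, adult implies
moderate+moderate or severe+mild, and an asymptomatic carrier of a pathogenic
allele implies the partner is benign.

Rules (fired in staged order, repeated until nothing changes):

R1  loss-of-function consequence (stop-gained, frameshift)     -> severe
R2  seen in any infantile/late-infantile patient               -> severe
R3  in a juvenile patient, partner of a severe allele          -> moderate
R4  homozygous in an adult patient                             -> moderate
R5  in a symptomatic patient, uncategorized partner of a
    moderate allele                                            -> moderate
R6  in an adult patient, partner of a severe allele            -> mild
R7  in an asymptomatic individual, partner of a pathogenic
    (severe/moderate/mild) allele                              -> benign

Conflicting rule firings resolve to the most severe class; the full trace of
fired rules is kept for audit. Variants seen in fewer than ``min_patients``
carriers are reported as ``unknown`` regardless of rules (their working class
still propagates to partners during iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .datamodel import (
    Consequence,
    PatientRecord,
    Phenotype,
    SeverityClass,
    Variant,
    count_variant_observations,
    severity_rank,
)

__all__ = [
    "SeverityAssignment",
    "DEFAULT_BENIGN_OVERRIDES",
    "is_lof",
    "assign_patient_based_severity",
]

#: High-frequency / ClinVar-benign alleles treated as benign by default.
#: p.T393S is the classic ARSA pseudo-deficiency allele (ClinVar benign,
#: overall gnomAD frequency ~0.48); p.P220L and c.466-7G>C are too frequent in
#: gnomAD subpopulations to be pathogenic. The curated literature contains no
#: asymptomatic individuals, so rule R7 cannot derive these from patient data.
DEFAULT_BENIGN_OVERRIDES: Mapping[str, SeverityClass] = {
    "p.T393S": SeverityClass.BENIGN,
    "p.P220L": SeverityClass.BENIGN,
    "c.466-7G>C": SeverityClass.BENIGN,
}

_PATHOGENIC = (SeverityClass.SEVERE, SeverityClass.MODERATE, SeverityClass.MILD)
_SYMPTOMATIC = (Phenotype.INFANTILE, Phenotype.JUVENILE, Phenotype.ADULT)


@dataclass
class SeverityAssignment:
    """Outcome of the ruleset for one variant."""

    variant_id: str
    severity: SeverityClass
    rule_trace: list[str] = field(default_factory=list)
    eligible: bool = False


def is_lof(variant: Variant) -> bool:
    """True for loss-of-function consequences: stop-gained and frameshift.

    In-frame deletions, splice and missense changes are not called LoF here;
    they are classified from patient or activity evidence instead.
    """
    return variant.consequence in (Consequence.STOP_GAINED, Consequence.FRAMESHIFT)


class _Working:
    """Mutable rule-application state for one run of the ruleset."""

    def __init__(self, overrides: Mapping[str, SeverityClass]):
        self.cls: dict[str, SeverityClass] = {}
        self.trace: dict[str, list[str]] = {}
        self.overrides = dict(overrides)
        self.changed = False
        for vid, sev in self.overrides.items():
            self.cls[vid] = sev

    def get(self, vid: str) -> SeverityClass:
        return self.cls.get(vid, SeverityClass.UNKNOWN)

    def fire(self, vid: str, rule: str, severity: SeverityClass) -> None:
        tag = f"{rule}:{severity.value}"
        tr = self.trace.setdefault(vid, [])
        if tag not in tr:
            tr.append(tag)
        if vid in self.overrides:
            return  # overridden classes are pinned
        current = self.get(vid)
        if current is SeverityClass.UNKNOWN or severity_rank(severity) < severity_rank(current):
            self.cls[vid] = severity
            self.changed = True


def _stage_lof_infantile(state: _Working, records, variants) -> None:
    if variants:
        for vid, v in variants.items():
            if is_lof(v):
                state.fire(vid, "R1", SeverityClass.SEVERE)
    for r in records:
        if r.phenotype is Phenotype.INFANTILE:
            for vid in r.alleles:
                state.fire(vid, "R2", SeverityClass.SEVERE)


def _stage_moderate(state: _Working, records) -> None:
    while True:
        state.changed = False
        for r in records:
            if not r.is_complete:
                continue
            a, b = r.allele1, r.allele2
            if r.phenotype is Phenotype.JUVENILE:
                if state.get(a) is SeverityClass.SEVERE:
                    state.fire(b, "R3", SeverityClass.MODERATE)
                if state.get(b) is SeverityClass.SEVERE:
                    state.fire(a, "R3", SeverityClass.MODERATE)
            if r.phenotype is Phenotype.ADULT and a == b:
                state.fire(a, "R4", SeverityClass.MODERATE)
            if r.phenotype in _SYMPTOMATIC:
                if state.get(a) is SeverityClass.MODERATE and state.get(b) is SeverityClass.UNKNOWN:
                    state.fire(b, "R5", SeverityClass.MODERATE)
                if state.get(b) is SeverityClass.MODERATE and state.get(a) is SeverityClass.UNKNOWN:
                    state.fire(a, "R5", SeverityClass.MODERATE)
        if not state.changed:
            break


def _stage_mild(state: _Working, records) -> None:
    for r in records:
        if not r.is_complete or r.phenotype is not Phenotype.ADULT:
            continue
        a, b = r.allele1, r.allele2
        if state.get(a) is SeverityClass.SEVERE:
            state.fire(b, "R6", SeverityClass.MILD)
        if state.get(b) is SeverityClass.SEVERE:
            state.fire(a, "R6", SeverityClass.MILD)


def _stage_benign(state: _Working, records) -> None:
    for r in records:
        if not r.is_complete or r.phenotype is not Phenotype.ASYMPTOMATIC:
            continue
        a, b = r.allele1, r.allele2
        if state.get(a) in _PATHOGENIC:
            state.fire(b, "R7", SeverityClass.BENIGN)
        if state.get(b) in _PATHOGENIC:
            state.fire(a, "R7", SeverityClass.BENIGN)


def assign_patient_based_severity(
    records: Sequence[PatientRecord],
    variants: Optional[Mapping[str, Variant]] = None,
    min_patients: int = 5,
    overrides: Optional[Mapping[str, SeverityClass]] = None,
    max_cycles: int = 100,
) -> dict[str, SeverityAssignment]:
    """Run the severity ruleset over the cohort to a fixpoint.

    ``variants`` supplies consequence annotations for rule R1 (LoF); without
    it only the patient-derived rules fire. ``overrides`` pins variants to a
    fixed class (defaults to :data:`DEFAULT_BENIGN_OVERRIDES`); overridden
    classes propagate to partners but never change.

    Returns an assignment for every variant observed in ``records`` (plus any
    annotated or overridden variant). Variants seen in fewer than
    ``min_patients`` carriers are reported ``unknown`` (``eligible=False``)
    even when rules fired for them; overrides are reported regardless of
    eligibility. Patients with an unknown phenotype never fire rules;
    contradictory evidence lands in ``rule_trace``, never raises.
    """
    if overrides is None:
        overrides = DEFAULT_BENIGN_OVERRIDES
    counts = count_variant_observations(records)
    state = _Working(overrides)

    for _ in range(max_cycles):
        before = dict(state.cls)
        _stage_lof_infantile(state, records, variants)
        _stage_moderate(state, records)
        _stage_mild(state, records)
        _stage_benign(state, records)
        if state.cls == before:
            break

    ids = set(counts) | set(state.cls) | (set(variants) if variants else set())
    out: dict[str, SeverityAssignment] = {}
    for vid in sorted(ids):
        eligible = counts.get(vid) is not None and counts[vid].patient_count >= min_patients
        trace = list(state.trace.get(vid, []))
        if vid in overrides:
            severity = overrides[vid]
            trace.append(f"override:{severity.value}")
        elif eligible:
            severity = state.get(vid)
        else:
            severity = SeverityClass.UNKNOWN
        out[vid] = SeverityAssignment(
            variant_id=vid, severity=severity, rule_trace=trace, eligible=eligible
        )
    return out
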