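"""Classify ARSA variant severity from a curated patient cohort.

Builds a miniature curated cohort from the published phenotype breakdowns of
the ten most common genotypes, runs the patient-based severity ruleset to its
fixpoint, and prints the class and rule trace for each well-observed allele.
"""

from mldmatrix import PatientRecord, Phenotype, assign_patient_based_severity

# (allele1, allele2, {phenotype: patient count}) for the ten most common
# genotypes of the curated literature cohort.
TOP_GENOTYPES = [
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


def main() -> None:
    records = []
    i = 0
    for a, b, tally in TOP_GENOTYPES:
        for phenotype, n in tally.items():
            for _ in range(n):
                i += 1
                records.append(
                    PatientRecord(
                        patient_id=f"P{i:03d}", allele1=a, allele2=b, phenotype=phenotype
                    )
                )

    assignments = assign_patient_based_severity(records, min_patients=5)
    print(f"cohort: {len(records)} patients, {len(assignments)} distinct alleles\n")
    print(f"{'allele':<14} {'severity':<10} {'eligible':<9} rules fired")
    for vid, a in assignments.items():
        print(f"{vid:<14} {a.severity.value:<10} {str(a.eligible):<9} {', '.join(a.rule_trace)}")
    print(
        "\nSeverity is inferred from phenotypes alone: infantile carriers are"
        "\nsevere, partners of severe alleles in juvenile patients are moderate,"
        "\npartners of severe alleles in adult patients are mild. Alleles seen"
        "\nin fewer than 5 patients stay 'unknown' (not robustly classifiable)."
        "\nConflicts resolve to the most severe fired class, so a single"
        "\ninfantile report (as for p.P428L and p.I181S here) pulls an allele"
        "\nto severe; the trace keeps every firing for audit, and curators can"
        "\npin exceptions via the overrides map."
    )


if __name__ == "__main__":
    main()
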