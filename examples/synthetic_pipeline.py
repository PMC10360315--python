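"""End-to-end ground-truth recovery on synthetic data.

Generates a variant pool with known severities, samples a symptomatic cohort
under Hardy-Weinberg proportions, re-derives severities with the patient-based
ruleset, brackets noisy activity measurements, and scores the phenotype matrix
against the (partly misclassified) recorded phenotypes.
"""

from mldmatrix import (
    SeverityBrackets,
    SeverityClass,
    SyntheticConfig,
    assign_patient_based_severity,
    evaluate_matrix_accuracy,
    generate_activity_table,
    generate_cohort,
    generate_variant_pool,
    percent_wt_activity,
    true_severities,
)
from mldmatrix.synthetic import WILDTYPE_ID


def main() -> None:
    config = SyntheticConfig(seed=42)  # defaults: 489 patients, 5% phenotype noise
    pool = generate_variant_pool(config)
    cohort = generate_cohort(pool, config)
    truth = true_severities(pool)

    assigned = assign_patient_based_severity(
        cohort, variants={v.id: v for v in pool}, overrides={}
    )
    eligible = {vid: a for vid, a in assigned.items() if a.eligible}
    correct = sum(1 for vid, a in eligible.items() if a.severity is truth[vid])
    print(f"cohort: {len(cohort)} patients over {len(pool)} alleles")
    print(f"severity ruleset: {correct}/{len(eligible)} eligible alleles match truth")

    measurements = generate_activity_table(pool, config)
    wildtype = {m.plate_id: m for m in measurements if m.variant_id == WILDTYPE_ID}
    brackets = SeverityBrackets()
    hits = sum(
        percent_wt_activity(m, wildtype[m.plate_id], brackets).activity_based_severity
        is truth[m.variant_id]
        for m in measurements
        if m.variant_id != WILDTYPE_ID
    )
    print(f"activity brackets: {hits}/{len(pool)} alleles recover their class")

    accuracy = evaluate_matrix_accuracy(cohort, truth)
    print(
        f"phenotype matrix: {accuracy.overall_accuracy:.1f}% of {accuracy.n_evaluated}"
        " phenotypes match the prediction"
    )
    print(
        "\nWith 5% injected phenotype noise the matrix accuracy sits near 95%;"
        "\nat zero noise all three recovery rates are exact. This bounds what"
        "\nthe pipeline can claim on real data, where phenotype reporting and"
        "\nassay noise are both larger."
    )


if __name__ == "__main__":
    main()
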