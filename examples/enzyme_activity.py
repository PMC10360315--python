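"""From raw ion ratios to activity-based severity and assay diagnostics.

Builds a small plate of replicate ion-ratio wells (ARSA product ratio, BLA
control ratio), normalizes each variant to percent of the wild-type wells,
brackets the means into severity classes, and computes the diagnostic
performance of the 13% pathogenic threshold against patient-based truth.
"""

import math

from mldmatrix import (
    ActivityMeasurement,
    Construct,
    SeverityBrackets,
    diagnostic_metrics,
    percent_wt_activity,
)

# Published mean CDS activities (% of wild type) for five classified alleles.
KNOWN = {
    "p.P428L": (0.037, "pathogenic"),
    "p.R86Q": (2.13, "pathogenic"),
    "p.I181S": (4.32, "pathogenic"),
    "p.R86W": (7.86, "pathogenic"),
    "p.T393S": (14.69, "benign"),
}


def wells(vid: str, percent: float) -> ActivityMeasurement:
    # back-construct ion ratios: BLA control ratio 1.0, ARSA ratio percent/100
    return ActivityMeasurement(
        variant_id=vid,
        construct=Construct.CDS,
        replicate_ion_ratios=[(percent / 100.0, 1.0)] * 3,
        plate_id="demo",
    )


def main() -> None:
    wildtype = wells("WT", 100.0)
    brackets = SeverityBrackets()
    print(f"{'allele':<10} {'%WT':>7}  severity")
    percents, truth = {}, {}
    for vid, (percent, label) in KNOWN.items():
        result = percent_wt_activity(wells(vid, percent), wildtype, brackets)
        percents[vid] = result.mean_percent_wt
        truth[vid] = label
        print(f"{vid:<10} {result.mean_percent_wt:>7.2f}  {result.activity_based_severity.value}")

    out = diagnostic_metrics(truth, percents, threshold=brackets.pathogenic_threshold)
    dor = "infinite" if math.isinf(out.dor) else f"{out.dor:.1f}"
    print(
        f"\n13% threshold vs patient-based truth: sensitivity {out.sensitivity:.0f}%,"
        f" specificity {out.specificity:.0f}%, DOR {dor}"
    )
    print(
        "Brackets: <2% severe, 2-<4% moderate, 4-13% mild, >13% benign."
        "\nZero false positives make the diagnostic odds ratio infinite: every"
        "\nallele called pathogenic by the assay is pathogenic in patients."
    )


if __name__ == "__main__":
    main()
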