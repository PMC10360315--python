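# mldmatrix

Genotype–phenotype analysis for metachromatic leukodystrophy (MLD), a
recessive lysosomal storage disorder caused by biallelic loss of arylsulfatase
A (*ARSA*) activity. The package is written for rare-disease geneticists and
newborn-screening (NBS) analysts who need to go from curated patient tables,
population allele frequencies, and enzyme-activity screens to variant severity
calls, phenotype predictions, and population disease-burden estimates.

## What it computes

- **Patient-based severity** — an auditable ruleset iterated to a fixpoint
  over a curated cohort assigns each *ARSA* allele a class in
  {severe, moderate, mild, benign, unknown}: infantile/late-infantile carriers
  and loss-of-function alleles are severe, partners of severe alleles in
  juvenile patients are moderate, partners of severe alleles in adult patients
  are mild, and so on.
- **Phenotype matrix** — a symmetric look-up table from the unordered severity
  pair (s₁, s₂) of a genotype to the expected phenotype: (severe, severe) →
  infantile/late-infantile, (severe, moderate) → juvenile, (severe, mild) and
  (moderate, moderate) → adult, milder pairings → asymptomatic, VUS pairings →
  unknown unless the partner is benign.
- **Entropy** — genotype–phenotype consistency as H[G] = −Σ p̂ᵢ ln p̂ᵢ over the
  phenotype distribution observed for a genotype (0 = perfectly consistent).
- **Activity-based severity** — percent-of-wild-type enzyme activity from
  replicate LC–MS/MS ion ratios, bracketed as < 2 % severe, 2–< 4 % moderate,
  4–13 % mild, > 13 % benign, with reconciliation into a finalized class and
  diagnostic metrics (sensitivity, specificity, LR+, DOR) for the 13 %
  pathogenic threshold.
- **Disease burden** — under Hardy–Weinberg proportions, E[Infantile] = p̂ₛ²,
  E[Juvenile] = 2 p̂ₛ p̂ₘₒ, E[Adult] = p̂ₘₒ² + 2 p̂ₛ p̂ₘᵢ, with variance
  propagation and 95 % CIs both analytic (beta method-of-moments) and
  bootstrap, plus per-genotype incidences and the incidence of genotypes of
  unknown significance (GUS).
- **Discovery simulation** — a frequency-weighted coupon-collector model of
  how fast molecular screening encounters distinct pathogenic alleles, with
  monotone piecewise-cubic extrapolation to not-yet-catalogued alleles and
  conversion to births per novel allele.
- **Synthetic data** — generators for all three input tables with known ground
  truth, so every stage is testable end to end.

## Worked example

```python
from mldmatrix import (
    PatientRecord, Phenotype, SeverityClass,
    evaluate_matrix_accuracy, genotype_entropy, predict_phenotype,
)

# the nine reported patients compound-heterozygous for the common
# splice-null (severe) and a mild missense allele
records = [
    PatientRecord(patient_id=f"P{i}", allele1="c.465+1G>A", allele2="p.I181S",
                  phenotype=phen)
    for i, phen in enumerate(
        [Phenotype.INFANTILE] + [Phenotype.JUVENILE] * 4 + [Phenotype.ADULT] * 4
    )
]
severities = {"c.465+1G>A": SeverityClass.SEVERE, "p.I181S": SeverityClass.MILD}

print(predict_phenotype(*severities.values()))
print(round(genotype_entropy({Phenotype.INFANTILE: 1, Phenotype.JUVENILE: 4,
                              Phenotype.ADULT: 4}), 2))
print(round(evaluate_matrix_accuracy(records, severities).overall_accuracy, 1))
```

prints

```
adult
0.96
44.4
```

The matrix predicts adult-onset disease for a severe+mild genotype; the
observed phenotype spread gives this genotype the highest entropy in the
cohort (0.96 of a possible ln 3 ≈ 1.10), and only 4 of its 9 reported
phenotypes match the prediction (44.4 % accuracy).

The `examples/` directory holds one narrative script per capability
(severity classification, phenotype prediction and entropy, enzyme activity,
disease burden with CIs, discovery simulation, and end-to-end synthetic
recovery); each prints the numbers it computes and what they mean, e.g.

```sh
python examples/disease_burden.py
```

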