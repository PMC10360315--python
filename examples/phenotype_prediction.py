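"""Predict MLD phenotype from a genotype and measure its consistency.

Looks up phenotype-matrix predictions for a few genotypes, then computes the
entropy of the published phenotype breakdowns of the most common genotypes:
0 means every patient with that genotype had the same presentation, ln 3
(about 1.099) is the maximum over the three symptomatic categories.
"""

from mldmatrix import Phenotype, PhenotypeMatrix, SeverityClass, genotype_entropy

S, M, m, B, U = (
    SeverityClass.SEVERE,
    SeverityClass.MODERATE,
    SeverityClass.MILD,
    SeverityClass.BENIGN,
    SeverityClass.UNKNOWN,
)


def main() -> None:
    matrix = PhenotypeMatrix.default()
    print("matrix predictions (unordered severity pair -> phenotype):")
    for a, b in [(S, S), (S, M), (S, m), (M, M), (m, M), (U, S), (U, B)]:
        print(f"  ({a.value}, {b.value}) -> {matrix.predict(a, b).value}")

    print("\nentropy of the published phenotype breakdowns:")
    breakdowns = {
        "c.465+1G>A/c.465+1G>A": {Phenotype.INFANTILE: 32, Phenotype.UNKNOWN: 1},
        "c.465+1G>A/p.P428L": {Phenotype.JUVENILE: 25, Phenotype.INFANTILE: 1},
        "p.P428L/p.P428L": {Phenotype.JUVENILE: 15, Phenotype.ADULT: 9},
        "c.465+1G>A/p.I181S": {Phenotype.ADULT: 4, Phenotype.JUVENILE: 4, Phenotype.INFANTILE: 1},
    }
    for genotype, counts in breakdowns.items():
        print(f"  {genotype:<24} H = {genotype_entropy(counts):.2f}")
    print(
        "\nLow entropy (0.14, 0.16) marks highly consistent genotypes; the"
        "\nsevere/mild compound heterozygote is the least consistent (0.96),"
        "\nspreading over all three onset categories."
    )


if __name__ == "__main__":
    main()
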