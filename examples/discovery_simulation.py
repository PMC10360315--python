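"""Simulate how fast newborn screening discovers distinct pathogenic alleles.

Draws simulated MLD patients (two pathogenic alleles, frequency-weighted, with
replacement) until every allele in the pool has been seen, averages the
first-appearance patient index per rank, extrapolates the discovery curve one
rank past the pool (alleles not yet catalogued), and converts the final
discovery gap into births per novel allele.
"""

import numpy as np

from mldmatrix import (
    SyntheticConfig,
    births_per_novel_allele,
    extrapolate_discovery,
    generate_variant_pool,
    one_in,
    phenotype_incidence,
    severity_class_frequencies,
    simulate_discovery,
    true_severities,
    SeverityClass,
)

PATHOGENIC = (SeverityClass.SEVERE, SeverityClass.MODERATE, SeverityClass.MILD)


def main() -> None:
    config = SyntheticConfig(seed=11)
    pool = generate_variant_pool(config)
    truth = true_severities(pool)
    freqs = {v.id: v.frequency("all") for v in pool if truth[v.id] in PATHOGENIC}

    curve = simulate_discovery(freqs, n_sims=5_000, seed=11)
    print(f"discovery curve over {curve.n_variants} pathogenic alleles "
          f"({curve.n_sims:,} simulations):")
    for rank, mean in enumerate(curve.mean_patients_to_rank, start=1):
        print(f"  rank {rank:>2}: first seen at patient {mean:,.2f}")

    (next_rank,) = extrapolate_discovery(curve, extra_ranks=1)
    gap = next_rank - curve.mean_patients_to_rank[-1]
    print(f"\nextrapolated rank {curve.n_variants + 1}: patient {next_rank:,.0f} "
          f"(gap of {gap:,.0f} patients)")

    incidence = phenotype_incidence(
        severity_class_frequencies(pool, "finalized", "all")
    )["overall"]
    births = births_per_novel_allele(gap, one_in(incidence.expected))
    print(f"overall incidence {1/one_in(incidence.expected):.2e} "
          f"-> a never-before-seen allele every 1 in {births:,.0f} births")
    print(
        "\nThe first allele always appears with the first patient; rare alleles"
        "\nstretch the tail. Dividing the patient gap by the disease incidence"
        "\nconverts screened patients into population births."
    )


if __name__ == "__main__":
    main()
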