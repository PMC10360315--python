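# Methods

## Scope and model

`mldmatrix` implements a genotype–phenotype analysis for metachromatic
leukodystrophy (MLD), an autosomal-recessive lysosomal storage disorder caused
by loss of arylsulfatase A (ARSA) activity. The model treats the impact of the
two *ARSA* alleles of a genotype as additive on residual enzyme activity, and
disease severity as a decreasing function of residual activity. Alleles carry
one of five severity classes — severe, moderate, mild, benign, unknown — and a
symmetric 5×5 look-up table (the phenotype matrix) maps the unordered class
pair of a genotype to an expected presentation: two severe alleles →
infantile/late-infantile onset (< 2.5 y), severe+moderate → juvenile
(2.5–16 y), severe+mild or moderate+moderate → adult (> 16 y), any
mild/moderate pairing below that → asymptomatic. A genotype containing an
uncharacterized allele (VUS) is predictable only when the partner is benign;
everything else is a genotype of unknown significance (GUS).

## Patient-based severity ruleset

Severity classes are inferred from a curated cohort of literature cases by
iterating seven rules to a fixpoint (module `severity`): loss-of-function
consequences and alleles seen in infantile patients are severe; partners of
severe alleles in juvenile patients, adult homozygotes, and symptomatic
partners of moderate alleles are moderate; partners of severe alleles in adult
patients are mild; partners of pathogenic alleles in asymptomatic individuals
are benign. The stages run in that order (severe first, then moderate, mild,
benign) and the whole cycle repeats until nothing changes, since later classes
are defined relative to earlier ones. Conflicting firings resolve to the most
severe class — deliberately mechanical and auditable, with every firing kept
in a rule trace. Classes are only *reported* for alleles observed in at least
`min_patients = 5` carriers (a carrier threshold: homozygotes count once);
below-threshold alleles still propagate their working class to partners during
iteration but are emitted as `unknown`.

Three high-frequency alleles (the classic pseudo-deficiency allele p.T393S,
plus p.P220L and c.466-7G>C) ship as a default benign override list: the
curated literature contains no asymptomatic individuals, so the benign rule
alone can never fire on real curated data, yet population frequencies close to
0.5 are incompatible with pathogenicity. Overrides are pinned: they propagate
but never change.

The mechanical max-severity resolution means a single infantile report drags
an allele to severe even when dozens of later-onset reports point elsewhere
(single anomalous infantile cases exist in the literature for otherwise
moderate/mild alleles). That is a property of the ruleset, not a bug; curators
who accept the literature consensus for such an allele express it through the
overrides map.

## Entropy and matrix accuracy

Genotype–phenotype consistency is the Shannon entropy H = −Σ pᵢ ln pᵢ of the
phenotype tally of a genotype (natural log; 0 = perfectly consistent; ln k
maximum over k categories). Every observed category contributes, *including*
"unknown" phenotypes — the published per-genotype entropies are reproducible
only under that convention. Matrix accuracy is the percentage of observed
phenotypes matching the matrix prediction, restricted to complete genotypes
whose both alleles meet the 5-carrier threshold; records with unknown
*observed* phenotype leave the denominator (the same convention that keeps an
all-but-one-consistent homozygous splice-null genotype from being penalized
for one unphenotyped case). The cohort-level entropy summary uses the
population (n-denominator) standard deviation.

## Enzyme activity

A variant's activity is measured as blank-subtracted LC–MS/MS ion ratios
(ARSA product/internal standard over a beta-lactamase transfection control) in
replicate transfected wells; percent-of-wild-type is
100 × normalized(variant) / mean normalized(wild-type) against the wild-type
wells of the *same plate* (per-plate referencing absorbs assay drift; whether
the published per-variant values used per-plate or global wild-type means is
not stated, and per-plate is the choice here). Negative percentages arise from
blank subtraction near zero activity and are kept as-is, bracketing as severe.
Replicate dispersion is the sample (n−1) standard deviation. Brackets: < 2 %
severe, 2–< 4 % moderate, 4–13 % mild (closed at 13, which is also the
pathogenic screening threshold), > 13 % benign.

Finalized severity reconciles patient-based and activity-based calls: explicit
overrides win (the default pins p.P428L to its patient-based moderate class —
it assays near-null, plausibly via cathepsin-L proteolysis absent in
disease-relevant tissue); otherwise patient evidence wins whenever present;
with no patient anchor, agreeing or single activity calls are taken as-is and
CDS/genomic disagreements resolve toward the class ordinally closer to the
patient class, ties and anchor-free disagreements breaking toward the more
severe call (conservative for screening).

Diagnostic performance of the 13 % threshold is summarized by sensitivity,
specificity, LR+ and the diagnostic odds ratio on a pathogenic/benign truth
split; zero-denominator ratios are reported as infinite, never raised.

## Incidence and confidence intervals

Variants are assumed not to co-occur in cis, so a severity class's allele
frequency is the sum of member frequencies and its variance the sum of
per-variant binomial sampling variances p(1−p)/AN (AN = chromosomes sampled;
default 100 000 when a population-specific allele number is absent). Under
Hardy–Weinberg proportions:

    E[Infantile] = p_S²        E[Juvenile] = 2 p_S p_M
    E[Adult]     = p_M² + 2 p_S p_m
    E[Overall]   = E[Infantile] + E[Juvenile] + E[Adult]

Variances propagate with the normal-theory forms Var[X²] = 2V(V + 2p²) and
Var[2XY] = 4(V_x V_y + V_x p_y² + V_y p_x²), written in expanded form so they
vanish exactly (not merely to rounding) when every per-variant variance is
zero. The juvenile variance conditions on the severe frequency
(Var = 4 p_S² V_M) by default; `symmetric_juvenile_variance=True` switches to
the full product form for sensitivity analysis. The overall variance adds the
covariance terms that arise because the severe class feeds every symptomatic
phenotype: Var[2p_S(p_M+p_m)] = Var[2p_S p_m] + Var[2p_S p_M] + 8 p_M p_m V_S,
plus 2·Cov terms 4 p_S V_S (p_M+p_m) and 4 p_S p_M V_M against the homozygote
terms. All four propagated variances are validated against an independent
Monte-Carlo propagation oracle in the test suite.

The asymptomatic expectation includes carrier pairings (benign × anything,
mild × mild/moderate), which is why it sits near 1 in 2 for populations with a
common benign allele; GUS covers every VUS pairing except VUS × benign.
Analytic 95 % CIs come from a method-of-moments beta matched to (mean,
variance) — valid only when variance < mean(1−mean), enforced — evaluated at
the 2.5/97.5 % quantiles. The bootstrap redraws each variant's allele count
from Binomial(AN, p̂)/AN, recomputes every phenotype incidence per iteration,
and takes empirical percentiles; asymptomatic and GUS intervals are
bootstrap-only, since their analytic variances are not derived.

## Discovery simulation

Simulated patients draw two alleles with replacement from the pathogenic pool,
weighted by frequency normalized over the pool (hence invariant to uniform
rescaling). Per run, the first-appearance patient index of each rank is
recorded until every allele is seen; the curve is the per-rank mean over runs
(default 10⁵; the always-runnable tests use 10⁴–2×10⁴, which bounds
Monte-Carlo error on small pools below the asserted tolerances). Runs
exceeding a patient cap (default 10⁷) abort with a warning rather than hang on
vanishing-frequency tails. The curve is validated against a closed form for
two equal alleles (mean patients to rank 2 = 5/3) and a dynamic-programming
oracle for k ≤ 5 equal alleles. Extrapolation fits a monotone-preserving
piecewise cubic (PCHIP) to (rank, mean patients) — an unconstrained cubic can
oscillate — and evaluates it past the last rank; births per novel allele is
the product of the patients-per-novel-allele gap and births per patient (the
reciprocal incidence). The curve stores mean first-appearance *indices*;
`rank_gaps()` gives the between-discovery differences.

## Synthetic data

The generator (module `synthetic`) emulates the three input tables with known
ground truth. Defaults are fixed study conditions: 489 patients (the curated
cohort size), pathogenic allele frequencies log-uniform in 10⁻⁶–10⁻³
(spanning the observed range from the most common splice null down to
singleton-scale alleles), a class pool of 8/4/3/2
severe/moderate/mild/benign alleles (mirroring the strong severe skew of the
real 28/5/2/2 tally at desk scale), allele number 100 000, a 5 % phenotype
misclassification rate (the curated cohort's mean per-genotype entropy of
~0.1 nat is consistent with a small single-digit labeling noise), and
0.5 %-of-wild-type Gaussian replicate noise (the published replicate SDs of
low-activity variants are sub-percent). Cohorts are sampled *conditionally on
being symptomatic* — genotype probabilities proportional to Hardy–Weinberg
incidence among matrix-symptomatic pairs — which keeps cohorts desk-scale at
realistic 10⁻⁶ incidences; activity wells are back-constructed from injected
percent-of-wild-type values against unit wild-type wells so re-normalization
recovers the injected value exactly at zero noise; class activity means sit
mid-bracket (0.5/3/8/60 %) to make boundary stress tests explicit.

What the generator does **not** emulate — and hence what passing tests cannot
show about real data: duplicated patients across publications, cis
combinations and pseudo-deficiency modifiers (e.g. c.*96A>G), splice effects
visible only in genomic constructs, plate drift and batch effects,
ascertainment bias in gnomAD subpopulations, and non-random mating.

## Numerical choices and degenerate inputs

Natural logarithms throughout; zero-count entropy categories contribute
nothing; an all-zero tally is an error. Bracket boundaries: 2.0 → moderate,
4.0 → mild, 13.0 → mild, above 13 → benign; non-finite activities are errors;
zero-control replicates drop with a warning; non-positive wild-type references
are errors. HGVS identifiers are canonicalized by string normalization only
(whitespace, prefix case) — no transcript conversion. Genotype keys sort
allele ids lexicographically; homozygotes are keyed (a, a). "1 in N" values
are exact reciprocals, infinite at zero incidence. All randomness flows
through seeded `numpy.random.Generator` instances.

## Limitations

Severity classes are ordinal, not quantitative; the matrix cannot express
within-class heterogeneity (the near-cutoff mean onset of the moderate
homozygote genotype is an example). Incidence estimates inherit gnomAD's
sampling and ascertainment properties and assume class-level independence of
allele draws. The accuracy of the matrix evaluated on the same cohort that
defined the severity classes is optimistic by construction; an unbiased
estimate requires held-out cohorts, which is out of scope here.
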