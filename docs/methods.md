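# Methods

## Model and assumptions

The package models one autosomal locus with two alleles in an effectively
infinite, randomly mating population with discrete generations and no
mutation, migration or drift. Genotypes are *ordered* pairs (maternal
allele, paternal allele) everywhere; no unordered genotype type exists, so
reciprocal heterozygotes can never be merged silently. On the trait scale
the A1A1 homozygote is anchored at 0 and A2A2 at 2a (no re-centering); the
heterozygotes sit at a(1 + k1) (A2 maternal) and a(1 + k2) (A2 paternal)
with k1, k2 ∈ [−1, 1]. Useful special cases: k1 = k2 = k is ordinary
Mendelian dominance; k1 = −k2 is imprinting without dominance (the
heterozygote *mean* is midway between the homozygotes); |k| = 1 is complete
silencing of one parental copy. Environmental variance, multiple loci,
multiple alleles and maternal genetic effects are out of scope.

## Parameters

| parameter | meaning | units | domain | default |
|---|---|---|---|---|
| a | half the homozygote difference | trait units | finite | — |
| k1, k2 | heterozygote coefficients by parental origin of A2 | dimensionless | [−1, 1] | — |
| p1 | frequency of A1 (p2 = 1 − p1) | probability | [0, 1] | — |
| f | inbreeding coefficient (excess homozygosity) | probability | [0, 1] | 0 |
| t | slope of the linear fitness φ = 1 + G t | 1/trait units | all φ > 0 | — |

Validation happens at construction: out-of-range k or p raises rather than
clips. p1 ∈ {0, 1} is admitted with a warning (all variances are then 0),
because fixation is a legitimate boundary of sweeps. A selection
coefficient is rejected exactly when some genotype's absolute fitness would
be ≤ 0, the weakest condition under which relative fitnesses make sense.

## The five partitions

All five approaches share the same total variance and differ only in how
they split it. A1 defines breeding values through mean offspring (doubled
deviation from the mean), A2b through sex-specific sums of parent-of-origin
average effects; these two are identical and are the only partitions that
produce the additive-by-dominance covariances σ_AD_f, σ_AD_m. A2a sums a
maternal-origin and a paternal-origin effect across an individual's own two
alleles; A3a and A3b are frequency-weighted least-squares regressions on
A2-allele count and on separate maternal/paternal A2 indicators. The
regression pair is also implemented literally as weighted `lstsq` fits
(`regression_breeding_values`), a reconstruction validated against the
closed-form tables; A2a and A3b share identical components, as do their
breeding values.

One typographic issue in the source material deserves a note: its summary
table of covariances between relatives prints, for the pooled approaches,
the full-sib and half-sib expressions in each other's columns (and garbles
a leading 1/8 coefficient in the A3a row). The package uses the assignment
consistent with the kinship identities — parent–offspring = σ²_A/2,
half-sib = σ²_A/4, full-sib = σ²_A/2 + σ²_D/4, each with the approach's own
components — which is exactly what the source's numerical examples follow,
and what the A1/2b sex-split row already satisfies.

## Inbreeding

The inbred population is represented exactly as the stated two-group
mixture — Hardy-Weinberg proportions with weight 1 − f plus a fully
homozygous group with weight f — not via identity-by-descent sampling, and
f is held fixed across generations. Only the A2b construction is extended
to f > 0 (the others are not defined there): the f-corrected average
effects inflate toward the homozygous substitution scale 2a, the two
alleles of an individual are correlated f, and the dominance variances
become sex-specific. Covariances between relatives under inbreeding are
not provided (the mixture is a marginal genotype model, not a mating
system), and the Monte Carlo sampler draws genotypes from the mixture
frequencies directly.

## Selection

Fitness is linear in the genotypic value, so mean fitness is 1 + tμ and all
post-selection quantities are exact rational expressions in (a, k1, k2, p1,
t). The response composite ψ = a p1 p2 (k1 + k2) is a *standard-deviation
scale* quantity — its square equals σ²_D + σ_AD_f + σ_AD_m — which is what
makes the closed-form response agree with the exact mating-table recursion
to machine precision; reading ψ as the component sum itself would introduce
an O(t²(k1+k2)) error. The breeder's-equation comparison uses
h² = σ²_A(1)/σ²_G with the A1/2b pooled additive variance. The sign of
(prediction − truth) under pure dominance equals the sign of the *signed*
dominance scale 2 a k p1 p2; the familiar "breeder's equation
overestimates" statement is therefore asserted only on the a k > 0 grid it
describes, and no global inequality is asserted when dominance and
imprinting are both present. Multi-generation iteration
(`iterate_selection`) simply re-applies the one-generation closed form with
the updated allele frequency; this is an extrapolation beyond the
single-step analysis and is off by default. The alternative published
prediction Δμ = S(h² + σ²_p/2) is a documented `NotImplementedError` stub:
its σ²_p has no computable definition.

## The enumeration oracle and simulator

The oracle never consults the closed forms. It enumerates the 4×4×4
(mother, father, offspring) mating table from the genotype frequencies and
Mendelian ½:½ segregation, keeps maternal gametes in the maternal slot, and
derives moments, offspring-mean breeding values, parent–offspring, full-sib
and half-sib covariances (shared parent, other parents i.i.d.), and the
fitness-weighted one-generation selection recursion. The Monte Carlo
sampler draws ordered allele pairs from the mixture distribution with a
seeded `numpy` generator (same seed ⇒ identical population) and
`empirical_components` plugs the *sample* allele frequency into an
approach's construction before taking weighted sample moments — applied to
the exact distribution instead of a sample, the same code reproduces the
closed forms to ~1e−15, which is itself a test. Monte Carlo checks use
n = 10⁶ with 20 seed replicates and a 4-standard-error band on the
replicate mean; identity checks use a 1000-point random grid at tolerance
1e−12. These sizes keep the full suite under a few seconds on one core
while leaving the sampling-error bands far tighter than any effect of
interest.

## Numerical conventions

Everything is double precision. Golden-value comparisons round half *away
from zero* to the printed precision (4 decimals for the scenario tables,
2 for the selfing examples): the source tables demonstrably use that
convention (an exact tie 0.03125 is printed 0.0313, which half-even
rounding would miss). Raw doubles are always available through the JSON
output paths. Degenerate inputs: fixation (p1 ∈ {0, 1}) warns and yields
zero variances; monomorphic Monte Carlo samples raise, since plug-in
effects are undefined there.

## What the simulator does and does not emulate

The sampler reproduces genotype-frequency sampling noise in an idealized
population that exactly matches the model (no pedigree structure, no
linked loci, no environmental noise, no measurement error). Passing Monte
Carlo tests therefore demonstrates correctness of the estimators and
closed forms under the model's own assumptions — not robustness of
variance-component estimation in real pedigree data, where sampling
variances of relative covariances are far larger and maternal effects can
masquerade as imprinting.

## Known limitations

Single locus, two alleles; selection results assume an outbred base
population; no covariances between relatives under inbreeding; no standard
errors or estimation machinery for observed data; the multi-generation
selection trajectory re-derives components each generation, which the
single-generation theory does not strictly license.
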