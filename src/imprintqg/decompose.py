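"""Breeding values, variance components and covariances between relatives.

Five classical ways of partitioning the genotypic value of an imprinted
locus are implemented, labelled as in the comparative analysis they come
from:

* ``A1``  -- breeding values from mating tables, i.e. twice the deviation of
  a parent's mean offspring from the population mean, kept separate by
  parental sex.
* ``A2a`` -- sum of parent-of-origin average effects (eps_i. maternal,
  eps_.j paternal) applied to an individual's own alleles.
* ``A2b`` -- the sex-specific "rescue" of A2a: a female decomposition using
  maternal-origin effects for both alleles, and a male decomposition using
  paternal-origin effects, each with its own dominance deviation.  A1 and
  A2b give identical results.
* ``A3a`` -- least-squares regression of genotypic value on A2-allele count
  (one slope; reciprocal heterozygotes forced equal).
* ``A3b`` -- least-squares regression on separate maternal-origin and
  paternal-origin A2 indicators.  Shares variance components with A2a.

Under Mendelian expression (k1 = k2) all five agree; imprinting breaks the
equivalence and creates a covariance between additive and dominance terms
that only A1/A2b can recover.  All functions here require an outbred
population (f = 0); the inbreeding module extends A2b to f > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, NamedTuple, Optional

import numpy as np

from .core import (
    GENOTYPES,
    G11,
    G12,
    G21,
    G22,
    Genotype,
    ImprintingLocus,
    PopulationState,
    alphas,
    genotype_frequencies,
    genotypic_values,
    population_mean,
    require_outbred,
    total_genetic_variance,
)


class Approach(str, Enum):
    """Label of a variance-partitioning approach."""

    A1 = "A1"
    A2a = "A2a"
    A2b = "A2b"
    A3a = "A3a"
    A3b = "A3b"

    @classmethod
    def parse(cls, label: "Approach | str") -> "Approach":
        if isinstance(label, cls):
            return label
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown approach {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: Approaches whose additive variance is a single pooled quantity.
POOLED_APPROACHES = (Approach.A2a, Approach.A3a, Approach.A3b)


class AdditiveEffects2a(NamedTuple):
    """Parent-of-origin average effects: eps_i. (maternal), eps_.j (paternal)."""

    eps_1_maternal: float
    eps_2_maternal: float
    eps_1_paternal: float
    eps_2_paternal: float


@dataclass(frozen=True)
class BreedingValueTable:
    """Per-genotype breeding values for one approach.

    ``values`` is the genotype's breeding value; for A1/A2b it is the mean of
    the sex-specific ``female`` and ``male`` values (which are also exposed).
    ``het_mean`` is the mean of the two reciprocal heterozygotes' values,
    equal to (p1 - p2)(alpha_f + alpha_m)/2 for every approach.
    """

    approach: Approach
    values: Dict[Genotype, float]
    female: Optional[Dict[Genotype, float]]
    male: Optional[Dict[Genotype, float]]
    het_mean: float


@dataclass(frozen=True)
class DominanceDeviation:
    """Per-genotype dominance deviations.

    A2a has a single deviation per genotype (``values``); A2b has separate
    female and male deviations.  Each set has frequency-weighted mean zero.
    """

    approach: Approach
    values: Optional[Dict[Genotype, float]]
    female: Optional[Dict[Genotype, float]]
    male: Optional[Dict[Genotype, float]]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive/dominance variance partition for one approach.

    ``sigma2_A`` is the pooled additive variance; for A1/A2b it equals
    ``(sigma2_A_f + sigma2_A_m)/2`` (the quantity the breeder's-equation
    heritability uses), for the other approaches it is the approach's own
    single additive variance and the sex-specific slots repeat it.  The
    components of every approach sum to the same total ``sigma2_G``:
    ``sigma2_A + sigma2_D + sigma_AD_f + sigma_AD_m = sigma2_G``.
    """

    approach: Approach
    sigma2_A_f: float
    sigma2_A_m: float
    sigma2_A: float
    sigma2_D: float
    sigma_AD_f: float
    sigma_AD_m: float
    sigma2_G: float


@dataclass(frozen=True)
class RelativeCovariances:
    """Covariances between relatives implied by one approach's components.

    Maternal half sibs share only their mother (fathers drawn independently);
    full sibs share both parents.  For the pooled approaches the two
    parent-offspring (and the two half-sib) entries coincide.
    """

    approach: Approach
    cov_mother_offspring: float
    cov_father_offspring: float
    cov_fullsib: float
    cov_halfsib_maternal: float
    cov_halfsib_paternal: float


def additive_effects_2a(
    locus: ImprintingLocus, pop: PopulationState
) -> AdditiveEffects2a:
    """Average effects of inheriting each allele from each parent (f = 0).

    eps_1. = -p2 alpha_f, eps_2. = p1 alpha_f (maternal origin);
    eps_.1 = -p2 alpha_m, eps_.2 = p1 alpha_m (paternal origin).
    Each origin's effects are deviations: p1 eps_1 + p2 eps_2 = 0.
    """
    require_outbred(pop, "additive_effects_2a")
    af, am = alphas(locus, pop)
    p1, p2 = pop.p1, pop.p2
    return AdditiveEffects2a(
        eps_1_maternal=-p2 * af,
        eps_2_maternal=p1 * af,
        eps_1_paternal=-p2 * am,
        eps_2_paternal=p1 * am,
    )


def breeding_values(
    locus: ImprintingLocus, pop: PopulationState, approach: "Approach | str"
) -> BreedingValueTable:
    """Per-genotype breeding values under the chosen approach (f = 0)."""
    approach = Approach.parse(approach)
    require_outbred(pop, "breeding_values")
    af, am = alphas(locus, pop)
    p1, p2 = pop.p1, pop.p2
    a, k1, k2 = locus.a, locus.k1, locus.k2
    het_mean = 0.5 * (p1 - p2) * (af + am)

    female = male = None
    if approach in (Approach.A1, Approach.A2b):
        female = {
            G11: -2.0 * p2 * af,
            G21: (p1 - p2) * af,
            G12: (p1 - p2) * af,
            G22: 2.0 * p1 * af,
        }
        male = {
            G11: -2.0 * p2 * am,
            G21: (p1 - p2) * am,
            G12: (p1 - p2) * am,
            G22: 2.0 * p1 * am,
        }
        values = {g: 0.5 * (female[g] + male[g]) for g in GENOTYPES}
    elif approach == Approach.A2a:
        values = {
            G11: -p2 * (af + am),
            G21: p1 * af - p2 * am,
            G12: -p2 * af + p1 * am,
            G22: p1 * (af + am),
        }
    elif approach == Approach.A3a:
        values = {
            G11: -p2 * (af + am),
            G21: het_mean,
            G12: het_mean,
            G22: p1 * (af + am),
        }
    else:  # A3b
        values = {
            G11: -p2 * (af + am),
            G21: a * (p1 - p2 + k1 - 2.0 * p1 * p2 * (k1 + k2)),
            G12: a * (p1 - p2 + k2 - 2.0 * p1 * p2 * (k1 + k2)),
            G22: p1 * (af + am),
        }
    return BreedingValueTable(approach, values, female, male, het_mean)


def dominance_deviations(
    locus: ImprintingLocus, pop: PopulationState, approach: "Approach | str"
) -> DominanceDeviation:
    """Per-genotype dominance deviations; defined only for A2a and A2b.

    A2b: lambda_ij^f = G_ij - mu - eps_i. - eps_j. (maternal-origin effects
    for both alleles) and lambda_ij^m with paternal-origin effects; A2a:
    lambda_ij = G_ij - mu - eps_i. - eps_.j.  The other approaches define
    dominance only at the variance level.
    """
    approach = Approach.parse(approach)
    if approach not in (Approach.A2a, Approach.A2b):
        raise ValueError(
            f"per-genotype dominance deviations exist only for A2a/A2b, not {approach.value}"
        )
    require_outbred(pop, "dominance_deviations")
    G = genotypic_values(locus)
    mu = population_mean(locus, pop)
    eps = additive_effects_2a(locus, pop)
    e_mat = {1: eps.eps_1_maternal, 2: eps.eps_2_maternal}
    e_pat = {1: eps.eps_1_paternal, 2: eps.eps_2_paternal}
    if approach == Approach.A2a:
        values = {
            g: G[g] - mu - e_mat[g.maternal] - e_pat[g.paternal] for g in GENOTYPES
        }
        return DominanceDeviation(approach, values, None, None)
    female = {g: G[g] - mu - e_mat[g.maternal] - e_mat[g.paternal] for g in GENOTYPES}
    male = {g: G[g] - mu - e_pat[g.maternal] - e_pat[g.paternal] for g in GENOTYPES}
    return DominanceDeviation(approach, None, female, male)


def variance_components(
    locus: ImprintingLocus, pop: PopulationState, approach: "Approach | str"
) -> VarianceComponents:
    """Variance components of the chosen approach (f = 0)."""
    approach = Approach.parse(approach)
    require_outbred(pop, "variance_components")
    af, am = alphas(locus, pop)
    p1, p2 = pop.p1, pop.p2
    a, k1, k2 = locus.a, locus.k1, locus.k2
    pq = p1 * p2
    sigma2_G = total_genetic_variance(locus, pop)

    if approach in (Approach.A1, Approach.A2b):
        s_af = 2.0 * pq * af * af
        s_am = 2.0 * pq * am * am
        s_d = a * a * pq * ((k1 - k2) ** 2 + pq * (k1 + k2) ** 2)
        c_f = a * pq * af * (k2 - k1)
        c_m = a * pq * am * (k1 - k2)
        return VarianceComponents(
            approach, s_af, s_am, 0.5 * (s_af + s_am), s_d, c_f, c_m, sigma2_G
        )
    if approach in (Approach.A2a, Approach.A3b):
        s_a = pq * (af * af + am * am)
        s_d = (a * pq * (k1 + k2)) ** 2
    else:  # A3a
        s_a = 0.5 * pq * (af + am) ** 2
        s_d = 0.5 * a * a * pq * ((k1 - k2) ** 2 + 2.0 * pq * (k1 + k2) ** 2)
    return VarianceComponents(approach, s_a, s_a, s_a, s_d, 0.0, 0.0, sigma2_G)


def relative_covariances(
    locus: ImprintingLocus, pop: PopulationState, approach: "Approach | str"
) -> RelativeCovariances:
    """Covariances between relatives implied by the approach (f = 0).

    For A1/A2b the sex-split closed forms are used directly.  For the pooled
    approaches the standard identities apply to that approach's own
    components: parent-offspring = sigma2_A/2, half-sib = sigma2_A/4,
    full-sib = sigma2_A/2 + sigma2_D/4.  (The source table prints the pooled
    approaches' full-sib and half-sib expressions in each other's columns;
    the identity-consistent assignment used here is the one its numerical
    examples follow.)
    """
    approach = Approach.parse(approach)
    require_outbred(pop, "relative_covariances")
    af, am = alphas(locus, pop)
    p1, p2 = pop.p1, pop.p2
    a, k1, k2 = locus.a, locus.k1, locus.k2
    pq = p1 * p2

    if approach in (Approach.A1, Approach.A2b):
        return RelativeCovariances(
            approach,
            cov_mother_offspring=0.5 * pq * af * (af + am),
            cov_father_offspring=0.5 * pq * am * (af + am),
            cov_fullsib=0.25
            * pq
            * (2.0 * (af * af + am * am) + a * a * pq * (k1 + k2) ** 2),
            cov_halfsib_maternal=0.5 * pq * af * af,
            cov_halfsib_paternal=0.5 * pq * am * am,
        )
    comps = variance_components(locus, pop, approach)
    po = 0.5 * comps.sigma2_A
    hs = 0.25 * comps.sigma2_A
    fs = 0.5 * comps.sigma2_A + 0.25 * comps.sigma2_D
    return RelativeCovariances(approach, po, po, fs, hs, hs)


def regression_breeding_values(
    locus: ImprintingLocus, pop: PopulationState, approach: "Approach | str"
) -> Dict[Genotype, float]:
    """A3a/A3b breeding values realised as explicit weighted least squares.

    A3a regresses the genotypic value on A2-allele count (one slope); A3b on
    separate maternal-origin and paternal-origin A2 indicators.  Regressions
    are frequency-weighted over the outbred genotype distribution, and the
    centred fitted values are returned.  They reproduce the closed-form
    breeding value tables.
    """
    approach = Approach.parse(approach)
    if approach not in (Approach.A3a, Approach.A3b):
        raise ValueError(f"regression construction applies to A3a/A3b, not {approach.value}")
    require_outbred(pop, "regression_breeding_values")
    G = genotypic_values(locus)
    freqs = genotype_frequencies(pop)
    y = np.array([G[g] for g in GENOTYPES])
    w = np.array([freqs[g] for g in GENOTYPES])
    if approach == Approach.A3a:
        X = np.column_stack(
            [np.ones(4), [float((g.maternal == 2) + (g.paternal == 2)) for g in GENOTYPES]]
        )
    else:
        X = np.column_stack(
            [
                np.ones(4),
                [float(g.maternal == 2) for g in GENOTYPES],
                [float(g.paternal == 2) for g in GENOTYPES],
            ]
        )
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    fitted = X @ beta
    mu = float(w @ fitted)  # equals the weighted mean of y
    return {g: float(fitted[i] - mu) for i, g in enumerate(GENOTYPES)}
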