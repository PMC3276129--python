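"""One generation of selection on an imprinted trait.

Selection acts through the linear fitness function phi_ij = 1 + G_ij * t on
an outbred population, giving mean fitness phibar = 1 + t*mu.  The exact
single-generation response of the mean is

    delta_mu = t * gamma * (phibar - t*psi/2) / phibar^2

with the composites (built from the A1/A2b components)

    gamma = (sigma2_A_f + sigma_AD_f + sigma2_A_m + sigma_AD_m) / 2
          = p1 p2 (alpha_f + alpha_m)^2 / 2
    psi   = a p1 p2 (k1 + k2),    psi^2 = sigma2_D + sigma_AD_f + sigma_AD_m.

The response is identical whether tallied through mothers or fathers, even
though the post-selection offspring means of the two parental sexes differ
whenever k1 != k2.  The breeder's equation delta_mu = h^2 S, with
h^2 = sigma2_A(1)/sigma2_G built on the A1/A2b additive variance, matches
the true response only when dominance variance and both AD covariances
vanish (k1 = k2 = 0); under pure imprinting (k1 = -k2) it overestimates the
response by exactly the factor 1 + k1^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from .core import (
    GENOTYPES,
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
from .decompose import Approach, variance_components


@dataclass(frozen=True)
class SelectionModel:
    """Linear fitness model phi_ij = 1 + G_ij * t with selection coefficient t."""

    t: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError(f"t must be finite, got {self.t!r}")


@dataclass(frozen=True)
class SelectionOutcome:
    """Everything one generation of selection produces.

    ``delta_mu_f``/``delta_mu_m`` are the exact responses tallied through
    female and male parents (equal by construction); ``delta_mu_breeder`` is
    the breeder's-equation prediction h^2 * S.  ``delta_mu_mendelian`` and
    ``delta_mu_imprinting_only`` carry the specialised closed forms when the
    parameters satisfy k1 = k2 or k1 = -k2 respectively, else None.
    """

    mean_fitness: float
    S: float
    p1_prime: float
    p2_prime: float
    delta_mu_f: float
    delta_mu_m: float
    delta_mu_breeder: float
    offspring_mean_diff: float
    psi: float
    gamma: float
    h2: float
    delta_mu_mendelian: Optional[float] = None
    delta_mu_imprinting_only: Optional[float] = None


def _validate(locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel) -> None:
    require_outbred(pop, "selection")
    G = genotypic_values(locus)
    for g, v in G.items():
        if 1.0 + v * sel.t <= 0.0:
            raise ValueError(
                f"t = {sel.t} gives non-positive fitness {1.0 + v * sel.t} "
                f"for genotype {g}; all phi_ij = 1 + G_ij t must be > 0"
            )


def mean_fitness(locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel) -> float:
    """phibar = 1 + t * mu."""
    _validate(locus, pop, sel)
    return 1.0 + sel.t * population_mean(locus, pop)


def fitness_table(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> pd.DataFrame:
    """Per-genotype values, fitnesses and frequencies before/after selection."""
    _validate(locus, pop, sel)
    G = genotypic_values(locus)
    freqs = genotype_frequencies(pop)
    phibar = 1.0 + sel.t * population_mean(locus, pop)
    rows = []
    for g in GENOTYPES:
        phi = 1.0 + G[g] * sel.t
        rows.append(
            {
                "genotype": str(g),
                "genotypic_value": G[g],
                "freq_before": freqs[g],
                "fitness_absolute": phi,
                "fitness_relative": phi / phibar,
                "freq_after": freqs[g] * phi / phibar,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def allele_freqs_after_selection(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> Tuple[float, float]:
    """(p1', p2') among selected parents (equivalently among their gametes)."""
    _validate(locus, pop, sel)
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2, t = pop.p1, pop.p2, sel.t
    denom = 2.0 * (1.0 + a * p2 * t * (2.0 + p1 * (k1 + k2)))
    p1p = p1 * (2.0 + a * p2 * t * (2.0 + k1 + k2)) / denom
    return p1p, 1.0 - p1p


def offspring_means(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> pd.DataFrame:
    """Mean offspring value of each parent genotype, by parental sex.

    ``maternal_before`` is the mean offspring of a mother of that genotype
    mated at random in the unselected population; ``maternal_after`` mates
    her with the selected population (partner allele frequencies p');
    ``paternal_*`` are the same through fathers.  The frequency-weighted
    mean of either *_before column equals the population mean.
    """
    _validate(locus, pop, sel)
    G = genotypic_values(locus)
    p = {1: pop.p1, 2: pop.p2}
    p1p, p2p = allele_freqs_after_selection(locus, pop, sel)
    q = {1: p1p, 2: p2p}

    def mat(g: Genotype, partner: dict) -> float:
        return 0.5 * sum(
            partner[l] * (G[Genotype(g.maternal, l)] + G[Genotype(g.paternal, l)])
            for l in (1, 2)
        )

    def pat(g: Genotype, partner: dict) -> float:
        return 0.5 * sum(
            partner[l] * (G[Genotype(l, g.maternal)] + G[Genotype(l, g.paternal)])
            for l in (1, 2)
        )

    rows = []
    for g in GENOTYPES:
        rows.append(
            {
                "genotype": str(g),
                "maternal_before": mat(g, p),
                "paternal_before": pat(g, p),
                "maternal_after": mat(g, q),
                "paternal_after": pat(g, q),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def offspring_mean_sex_difference(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> float:
    """Post-selection offspring-mean difference between the parental sexes.

    Gbar_f' - Gbar_m' = a p1 p2 t (k2 - k1)(alpha_f + alpha_m) / (2 phibar);
    zero iff k1 = k2 (no parent-of-origin effect) or the case is degenerate.
    """
    _validate(locus, pop, sel)
    af, am = alphas(locus, pop)
    phibar = 1.0 + sel.t * population_mean(locus, pop)
    return (
        0.5 * locus.a * pop.p1 * pop.p2 * sel.t * (locus.k2 - locus.k1) * (af + am) / phibar
    )


def breeders_prediction(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> float:
    """Breeder's-equation response h^2 * S = t * sigma2_A(1) / phibar.

    The heritability uses the A1/A2b pooled additive variance
    sigma2_A(1) = (sigma2_A_f + sigma2_A_m)/2.
    """
    _validate(locus, pop, sel)
    comps = variance_components(locus, pop, Approach.A1)
    phibar = 1.0 + sel.t * population_mean(locus, pop)
    return sel.t * comps.sigma2_A / phibar


def response_to_selection(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> SelectionOutcome:
    """Exact one-generation response and its breeder's-equation comparison."""
    _validate(locus, pop, sel)
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2, t = pop.p1, pop.p2, sel.t
    pq = p1 * p2
    mu = population_mean(locus, pop)
    phibar = 1.0 + t * mu
    sigma2_G = total_genetic_variance(locus, pop)
    comps = variance_components(locus, pop, Approach.A1)

    gamma = 0.5 * (
        comps.sigma2_A_f + comps.sigma_AD_f + comps.sigma2_A_m + comps.sigma_AD_m
    )
    psi = a * pq * (k1 + k2)  # psi**2 == sigma2_D + sigma_AD_f + sigma_AD_m
    delta_mu = t * gamma * (phibar - 0.5 * t * psi) / (phibar * phibar)
    p1p, p2p = allele_freqs_after_selection(locus, pop, sel)
    S = t * sigma2_G / phibar
    h2 = comps.sigma2_A / sigma2_G if sigma2_G > 0.0 else float("nan")

    mendelian = imprinting_only = None
    if k1 == k2:
        # no imprinting: delta_mu = t sigma2_A (phibar - t sigma_D / 2) / phibar^2
        af, am = alphas(locus, pop)
        alpha = 0.5 * (af + am)
        sigma2_A = 2.0 * pq * alpha * alpha
        sigma_D = 2.0 * a * k1 * pq  # sqrt of the dominance variance, signed
        mendelian = t * sigma2_A * (phibar - 0.5 * t * sigma_D) / (phibar * phibar)
    if k1 == -k2:
        imprinting_only = 2.0 * a * a * pq * t / (1.0 + 2.0 * a * p2 * t)

    return SelectionOutcome(
        mean_fitness=phibar,
        S=S,
        p1_prime=p1p,
        p2_prime=p2p,
        delta_mu_f=delta_mu,
        delta_mu_m=delta_mu,
        delta_mu_breeder=breeders_prediction(locus, pop, sel),
        offspring_mean_diff=offspring_mean_sex_difference(locus, pop, sel),
        psi=psi,
        gamma=gamma,
        h2=h2,
        delta_mu_mendelian=mendelian,
        delta_mu_imprinting_only=imprinting_only,
    )


def iterate_selection(
    locus: ImprintingLocus,
    pop: PopulationState,
    sel: SelectionModel,
    generations: int = 1,
) -> pd.DataFrame:
    """Apply the one-generation closed form repeatedly with updated p1.

    The analysis behind the closed forms covers a single generation;
    iterating it (variance components re-derived each generation from the
    current allele frequency) is an extrapolation offered for exploration.
    Returns one row per generation with p1, mu, and the responses.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rows = []
    current = pop
    for gen in range(1, generations + 1):
        out = response_to_selection(locus, current, sel)
        rows.append(
            {
                "generation": gen,
                "p1": current.p1,
                "mu": population_mean(locus, current),
                "delta_mu": out.delta_mu_f,
                "delta_mu_breeder": out.delta_mu_breeder,
                "p1_prime": out.p1_prime,
            }
        )
        current = PopulationState(p1=out.p1_prime, f=0.0)
    return pd.DataFrame(rows).set_index("generation")


def devries_prediction(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> float:
    """Alternative published prediction S (h^2 + sigma_p^2 / 2) -- not implemented.

    The "variance due to imprinted genes" sigma_p^2 that this prediction
    requires is not defined in computable terms in the source analysis, so
    no faithful implementation is possible.
    """
    raise NotImplementedError(
        "sigma_p^2 (the variance due to imprinted genes) has no computable "
        "definition; this prediction is documented but not implemented"
    )
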