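"""Exact enumeration and Monte Carlo ground truth for the closed forms.

Nothing in this module uses the closed-form tables: means, variances,
breeding values, covariances between relatives and the selection response
are all obtained by exhaustively enumerating genotypes, matings, gamete
segregation (Mendelian 1/2:1/2) and offspring — or, for the Monte Carlo
sampler, by drawing individuals and applying the constructions to the
sample.  The rest of the package is tested against these quantities.

Conventions:

* Matings pair two independent draws from the population genotype
  distribution (under inbreeding the two-group mixture is a marginal
  genotype model, not a mating system, so relative covariances are only
  enumerated at f = 0).
* Maternal gametes land in the offspring's maternal slot, so reciprocal
  heterozygotes are produced and tracked distinctly.
* Half sibs share one parent; the other parent of each offspring is an
  independent draw.  Maternal half sibs share the mother.
* Approach-1 breeding values are reconstructed from offspring means with
  the standard doubling: BV = 2 (mean offspring of that parent - mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .core import (
    GENOTYPES,
    Genotype,
    ImprintingLocus,
    PopulationState,
    genotype_frequencies,
    genotypic_values,
    require_outbred,
)
from .decompose import Approach, RelativeCovariances, VarianceComponents
from .inbreeding import InbredVarianceComponents, inbred_additive_effects, mean_inbred
from .selection import SelectionModel, _validate as _validate_selection

_ALLELES = (1, 2)


def _freq_vector(pop: PopulationState) -> np.ndarray:
    freqs = genotype_frequencies(pop)
    return np.array([freqs[g] for g in GENOTYPES])


def _value_vector(locus: ImprintingLocus) -> np.ndarray:
    G = genotypic_values(locus)
    return np.array([G[g] for g in GENOTYPES])


def _gamete_matrix() -> np.ndarray:
    """(4 genotypes, 2 alleles): probability a parent transmits each allele."""
    M = np.zeros((4, 2))
    for gi, g in enumerate(GENOTYPES):
        M[gi, g.maternal - 1] += 0.5
        M[gi, g.paternal - 1] += 0.5
    return M


@dataclass(frozen=True)
class MatingTable:
    """Joint distribution over (mother, father, offspring) ordered genotypes.

    ``probs[m, f, o]`` indexes into :data:`imprintqg.core.GENOTYPES`; many of
    the 64 cells are structurally zero (a mating can only produce offspring
    carrying transmitted alleles).
    """

    probs: np.ndarray  # shape (4, 4, 4)

    def total(self) -> float:
        return float(self.probs.sum())

    def offspring_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, m in enumerate(GENOTYPES):
            for fi, fa in enumerate(GENOTYPES):
                for oi, o in enumerate(GENOTYPES):
                    p = self.probs[mi, fi, oi]
                    if p > 0.0:
                        rows.append(
                            {"mother": str(m), "father": str(fa), "offspring": str(o), "prob": p}
                        )
        return pd.DataFrame(rows)


def build_mating_table(locus: ImprintingLocus, pop: PopulationState) -> MatingTable:
    """Exhaustive random-mating table; parents drawn from the (mixture) frequencies."""
    w = _freq_vector(pop)
    gam = _gamete_matrix()
    # offspring genotype (maternal allele i, paternal allele j) from mother m, father f
    probs = np.zeros((4, 4, 4))
    for oi, o in enumerate(GENOTYPES):
        probs[:, :, oi] = np.outer(
            w * gam[:, o.maternal - 1], w * gam[:, o.paternal - 1]
        )
    return MatingTable(probs=probs)


def oracle_moments(locus: ImprintingLocus, pop: PopulationState) -> Tuple[float, float]:
    """Frequency-weighted mean and variance of the genotypic value."""
    w = _freq_vector(pop)
    y = _value_vector(locus)
    mean = float(w @ y)
    var = float(w @ (y * y) - mean * mean)
    return mean, var


def oracle_breeding_values(
    locus: ImprintingLocus, pop: PopulationState
) -> Dict[str, Dict[Genotype, float]]:
    """Approach-1 sex-specific breeding values from enumerated offspring means.

    BV_female(g) = 2 (E[offspring value | mother = g] - mu) under random
    mating in the outbred population; likewise through fathers.
    """
    require_outbred(pop, "oracle_breeding_values")
    w = _freq_vector(pop)
    y = _value_vector(locus)
    gam = _gamete_matrix()
    mu = float(w @ y)
    pal = w @ gam  # population allele frequencies (p1, p2)
    Gmat = np.array(
        [[genotypic_values(locus)[Genotype(i, j)] for j in _ALLELES] for i in _ALLELES]
    )
    female = {}
    male = {}
    for gi, g in enumerate(GENOTYPES):
        off_mother = float(gam[gi] @ Gmat @ pal)  # maternal gamete x random father
        off_father = float(pal @ Gmat @ gam[gi])
        female[g] = 2.0 * (off_mother - mu)
        male[g] = 2.0 * (off_father - mu)
    return {"female": female, "male": male}


def oracle_relative_covariances(
    locus: ImprintingLocus, pop: PopulationState
) -> RelativeCovariances:
    """Parent-offspring, full-sib and half-sib covariances by enumeration (f = 0)."""
    require_outbred(pop, "oracle_relative_covariances")
    w = _freq_vector(pop)
    y = _value_vector(locus)
    gam = _gamete_matrix()
    mu = float(w @ y)
    pal = w @ gam
    Gmat = np.array(
        [[genotypic_values(locus)[Genotype(i, j)] for j in _ALLELES] for i in _ALLELES]
    )
    # conditional offspring means
    off_given_mother = gam @ Gmat @ pal  # (4,)
    off_given_father = (pal @ Gmat @ gam.T).T  # (4,)
    off_given_pair = gam @ Gmat @ gam.T  # (4, 4): mother x father

    mo = float(w @ (y * off_given_mother) - mu * mu)
    fo = float(w @ (y * off_given_father) - mu * mu)
    # full sibs: conditionally independent given the shared parental pair
    fs = float(np.einsum("m,f,mf->", w, w, off_given_pair**2) - mu * mu)
    # half sibs: conditionally independent given the one shared parent
    hs_m = float(w @ (off_given_mother**2) - mu * mu)
    hs_p = float(w @ (off_given_father**2) - mu * mu)
    return RelativeCovariances(
        approach=Approach.A1,
        cov_mother_offspring=mo,
        cov_father_offspring=fo,
        cov_fullsib=fs,
        cov_halfsib_maternal=hs_m,
        cov_halfsib_paternal=hs_p,
    )


def oracle_inbred_components(
    locus: ImprintingLocus, pop: PopulationState
) -> InbredVarianceComponents:
    """A2b partition evaluated directly on the mixture genotype distribution.

    Breeding values are sums of the f-corrected average effects (maternal
    origin for the female decomposition, paternal for the male); dominance
    deviations are the residuals from mu(I).  Variances/covariances are
    frequency-weighted over the mixture.  Matches the closed forms exactly.
    """
    w = _freq_vector(pop)
    y = _value_vector(locus)
    mu = mean_inbred(locus, pop)
    eps = inbred_additive_effects(locus, pop)
    e_mat = {1: eps.eps_1_maternal, 2: eps.eps_2_maternal}
    e_pat = {1: eps.eps_1_paternal, 2: eps.eps_2_paternal}
    A_f = np.array([e_mat[g.maternal] + e_mat[g.paternal] for g in GENOTYPES])
    A_m = np.array([e_pat[g.maternal] + e_pat[g.paternal] for g in GENOTYPES])
    lam_f = y - mu - A_f
    lam_m = y - mu - A_m

    def cov(u: np.ndarray, v: np.ndarray) -> float:
        return float(w @ (u * v) - (w @ u) * (w @ v))

    return InbredVarianceComponents(
        sigma2_G=cov(y, y),
        sigma2_A_f=cov(A_f, A_f),
        sigma2_A_m=cov(A_m, A_m),
        sigma2_D_f=cov(lam_f, lam_f),
        sigma2_D_m=cov(lam_m, lam_m),
        sigma_AD_f=cov(A_f, lam_f),
        sigma_AD_m=cov(A_m, lam_m),
    )


def oracle_selection_response(
    locus: ImprintingLocus, pop: PopulationState, sel: SelectionModel
) -> Tuple[float, float, float]:
    """(delta_mu_f, delta_mu_m, p1') from the fitness-weighted recursion.

    Parents are weighted by relative fitness; sex-specific transmitted-allele
    frequencies form the offspring distribution with the maternal gamete in
    the maternal slot.  delta_mu_f tallies the response through mothers
    (each mated to the selected population) and delta_mu_m through fathers.
    """
    _validate_selection(locus, pop, sel)
    w = _freq_vector(pop)
    y = _value_vector(locus)
    gam = _gamete_matrix()
    mu = float(w @ y)
    phibar = 1.0 + sel.t * mu
    wsel = w * (1.0 + y * sel.t) / phibar  # post-selection genotype frequencies
    q = wsel @ gam  # transmitted-allele frequencies (same for both sexes here)
    Gmat = np.array(
        [[genotypic_values(locus)[Genotype(i, j)] for j in _ALLELES] for i in _ALLELES]
    )
    off_given_mother = gam @ Gmat @ q  # mother's gamete x selected father
    off_given_father = q @ Gmat @ gam.T
    delta_f = float(wsel @ off_given_mother) - mu
    delta_m = float(wsel @ off_given_father) - mu
    return delta_f, delta_m, float(q[0])


@dataclass(frozen=True)
class SimulatedPopulation:
    """A sampled population of ordered (maternal, paternal) allele pairs."""

    locus: ImprintingLocus
    maternal: np.ndarray  # int array of 1/2
    paternal: np.ndarray
    values: np.ndarray  # genotypic values
    seed: int

    @property
    def n(self) -> int:
        return self.maternal.size

    def genotype_counts(self) -> np.ndarray:
        """Counts in the canonical order A1A1, A2A1, A1A2, A2A2."""
        idx = 2 * (self.maternal - 1) + (self.paternal - 1)
        # idx: 0 -> A1A1, 1 -> A1A2, 2 -> A2A1, 3 -> A2A2; remap to canonical
        counts = np.bincount(idx, minlength=4)
        return counts[[0, 2, 1, 3]]

    def allele1_frequency(self) -> float:
        return float(((self.maternal == 1).mean() + (self.paternal == 1).mean()) / 2.0)


def sample_population(
    locus: ImprintingLocus, pop: PopulationState, n: int, seed: int
) -> SimulatedPopulation:
    """Draw n individuals from the (mixture) genotype distribution, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = _freq_vector(pop)
    idx = rng.choice(4, size=n, p=w)
    mat = np.array([g.maternal for g in GENOTYPES])[idx]
    pat = np.array([g.paternal for g in GENOTYPES])[idx]
    vals = _value_vector(locus)[idx]
    return SimulatedPopulation(locus=locus, maternal=mat, paternal=pat, values=vals, seed=seed)


def components_from_distribution(
    locus: ImprintingLocus,
    freqs: np.ndarray,
    p1: float,
    approach: "Approach | str",
) -> VarianceComponents:
    """Variance components from an arbitrary genotype distribution.

    Builds the approach's effects from the supplied allele frequency
    (outbred plug-in construction), assigns per-genotype additive values and
    residual deviations, and takes frequency-weighted central moments under
    ``freqs`` (canonical genotype order).  With the exact Hardy-Weinberg
    frequencies and the true p1 this reproduces the closed forms exactly;
    with observed sample frequencies it is the plug-in estimator.
    """
    approach = Approach.parse(approach)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("freqs must be 4 probabilities over the canonical genotypes")
    if not 0.0 < p1 < 1.0:
        raise ValueError("plug-in construction needs a polymorphic sample (0 < p1 < 1)")
    plug = PopulationState(p1=p1, f=0.0)
    y = _value_vector(locus)
    w = freqs

    def cov(u: np.ndarray, v: np.ndarray) -> float:
        return float(w @ (u * v) - (w @ u) * (w @ v))

    a, k1, k2 = locus.a, locus.k1, locus.k2
    mu = locus.a * plug.p2 * (2.0 + plug.p1 * (k1 + k2))
    af = a * (1.0 + k1 * plug.p1 - k2 * plug.p2)
    am = a * (1.0 + k2 * plug.p1 - k1 * plug.p2)
    e_mat = {1: -plug.p2 * af, 2: plug.p1 * af}
    e_pat = {1: -plug.p2 * am, 2: plug.p1 * am}
    sigma2_G = cov(y, y)

    if approach in (Approach.A1, Approach.A2b):
        A_f = np.array([e_mat[g.maternal] + e_mat[g.paternal] for g in GENOTYPES])
        A_m = np.array([e_pat[g.maternal] + e_pat[g.paternal] for g in GENOTYPES])
        lam_f = y - mu - A_f
        lam_m = y - mu - A_m
        s_af, s_am = cov(A_f, A_f), cov(A_m, A_m)
        return VarianceComponents(
            approach,
            s_af,
            s_am,
            0.5 * (s_af + s_am),
            0.5 * (cov(lam_f, lam_f) + cov(lam_m, lam_m)),
            cov(A_f, lam_f),
            cov(A_m, lam_m),
            sigma2_G,
        )
    if approach == Approach.A2a:
        A = np.array([e_mat[g.maternal] + e_pat[g.paternal] for g in GENOTYPES])
        lam = y - mu - A
        s_a = cov(A, A)
        return VarianceComponents(
            approach, s_a, s_a, s_a, cov(lam, lam), cov(A, lam), cov(A, lam), sigma2_G
        )
    # regression approaches: weighted least squares on the observed distribution
    if approach == Approach.A3a:
        X = np.column_stack(
            [np.ones(4), [float((g.maternal == 2) + (g.paternal == 2)) for g in GENOTYPES]]
        )
    else:  # A3b
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
    resid = y - fitted
    s_a = cov(fitted, fitted)
    return VarianceComponents(
        approach, s_a, s_a, s_a, cov(resid, resid), cov(fitted, resid), cov(fitted, resid), sigma2_G
    )


def empirical_components(
    simpop: SimulatedPopulation, approach: "Approach | str"
) -> VarianceComponents:
    """Monte Carlo estimates of the variance components from a sampled population.

    The construction plugs the sample allele frequency into the approach's
    effects and takes sample (co)variances, so every component is estimated
    from data alone.  Raises on a monomorphic sample, where the plug-in
    effects are undefined.
    """
    counts = simpop.genotype_counts()
    n = counts.sum()
    freqs = counts / n
    # allele-1 frequency over both slots of all individuals
    n1 = 2 * counts[0] + counts[1] + counts[2]
    p1_hat = n1 / (2 * n)
    if p1_hat in (0.0, 1.0):
        raise ValueError("monomorphic sample: empirical components are undefined")
    return components_from_distribution(simpop.locus, freqs, p1_hat, approach)
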