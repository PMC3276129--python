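"""Imprinting and inbreeding combined: the A2b partition at f > 0.

The inbred population is modelled exactly as a two-group mixture: a
Hardy-Weinberg group of weight ``1 - f`` and a fully homozygous group of
weight ``f``, with ``f`` held fixed across generations.  Like imprinting,
inbreeding induces a covariance between additive and dominance terms; when
both act, the dominance variance additionally differs between the female
(maternal-origin) and male (paternal-origin) decompositions.

Closed forms implemented here:

* population mean        mu(I) = a p2 (2 + p1 (1 - f)(k1 + k2))
* corrected average effects, e.g.
      eps_1.(I) = -a p2 (1 + k1 p1 - k2 p2 + f (1 - k1 p1 + k2 p2))
* total variance
      sigma2_G(I) = sigma2_G + f p1 p2 (4 a^2 - alpha_f^2 - alpha_m^2)
                    - a^2 f^2 p1^2 p2^2 (k1 + k2)^2
* sex-specific additive/dominance variances and AD covariances.

Every expression reduces to the outbred A1/A2b component at f = 0, and every
one matches the direct A2b construction (effects + residual deviations
evaluated over the mixture genotype distribution) to machine precision; the
enumeration oracle asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .core import ImprintingLocus, PopulationState, alphas


class InbredAdditiveEffects(NamedTuple):
    """Average effects corrected for inbreeding, by allele and parental origin.

    Each origin's effects are population deviations:
    p1*eps_1_maternal + p2*eps_2_maternal = 0, and likewise paternally.
    """

    eps_1_maternal: float
    eps_2_maternal: float
    eps_1_paternal: float
    eps_2_paternal: float


@dataclass(frozen=True)
class InbredVarianceComponents:
    """A2b variance partition of an inbred, imprinted population.

    Both sex-specific partitions sum to the same total:
    sigma2_A_f + sigma2_D_f + 2*sigma_AD_f = sigma2_G (and likewise for the
    male components).  At f = 0 each field reduces to the outbred A1/A2b
    component (where the two dominance variances coincide).
    """

    sigma2_G: float
    sigma2_A_f: float
    sigma2_A_m: float
    sigma2_D_f: float
    sigma2_D_m: float
    sigma_AD_f: float
    sigma_AD_m: float


def mean_inbred(locus: ImprintingLocus, pop: PopulationState) -> float:
    """Population mean with inbreeding: mu(I) = a p2 (2 + p1 (1 - f)(k1 + k2))."""
    return locus.a * pop.p2 * (2.0 + pop.p1 * (1.0 - pop.f) * (locus.k1 + locus.k2))


def inbred_additive_effects(
    locus: ImprintingLocus, pop: PopulationState
) -> InbredAdditiveEffects:
    """The four f-corrected average effects.

    The maternal-origin effects carry the alpha_f-like structure with an
    f-dependent correction toward the homozygote scale 2a (at f = 1 the
    effect of an allele collapses to +/- its homozygous-substitution value);
    the paternal-origin effects mirror them with alpha_m.
    """
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2, f = pop.p1, pop.p2, pop.f
    mat = 1.0 + k1 * p1 - k2 * p2 + f * (1.0 - k1 * p1 + k2 * p2)
    pat = 1.0 + k2 * p1 - k1 * p2 + f * (1.0 - k2 * p1 + k1 * p2)
    return InbredAdditiveEffects(
        eps_1_maternal=-a * p2 * mat,
        eps_2_maternal=a * p1 * mat,
        eps_1_paternal=-a * p2 * pat,
        eps_2_paternal=a * p1 * pat,
    )


def total_variance_inbred(locus: ImprintingLocus, pop: PopulationState) -> float:
    """Total genetic variance of the inbred, imprinted population.

    Quadratic in f in general; linear when there is no dominance
    (k1 = -k2), and equal to 4 a^2 p1 p2 at f = 1 regardless of imprinting.
    """
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2, f = pop.p1, pop.p2, pop.f
    af, am = alphas(locus, pop)
    pq = p1 * p2
    sigma2_G = pq * (af * af + am * am + a * a * pq * (k1 + k2) ** 2)
    return (
        sigma2_G
        + f * pq * (4.0 * a * a - af * af - am * am)
        - a * a * f * f * pq * pq * (k1 + k2) ** 2
    )


def inbred_variance_components(
    locus: ImprintingLocus, pop: PopulationState
) -> InbredVarianceComponents:
    """Sex-specific A2b components of the inbred, imprinted population.

    The additive variances take the compact form
    ``2 p1 p2 (1 + f) (alpha + f (2a - alpha))^2`` with the sex's own alpha:
    the f-corrected per-allele effect, inflated by the correlation ``f``
    between an individual's two alleles.  When k1 = k2 = k the two AD
    covariances coincide at ``-2 a^2 f p1 p2 (1 + f + k (1 - f)(p1 - p2))^2``
    and are therefore strictly negative under inbreeding alone.
    """
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2, f = pop.p1, pop.p2, pop.f
    af, am = alphas(locus, pop)
    pq = p1 * p2

    # outbred A1/A2b components, entering the f-corrections below
    sigma2_D = a * a * pq * ((k1 - k2) ** 2 + pq * (k1 + k2) ** 2)
    sigma_AD_f = a * pq * af * (k2 - k1)
    sigma_AD_m = a * pq * am * (k1 - k2)
    dom2 = a * a * pq * (k1 + k2) ** 2  # a^2 p1 p2 (k1+k2)^2 term reused below

    s_af = 2.0 * pq * (1.0 + f) * (af + f * (2.0 * a - af)) ** 2
    s_am = 2.0 * pq * (1.0 + f) * (am + f * (2.0 * a - am)) ** 2
    s_df = sigma2_D + f * pq * (
        af * af
        - am * am
        + 4.0 * (a - af) * (a - am)
        - f * (dom2 + 2.0 * (2.0 * a - af) * (2.0 * a - 2.0 * af - am))
        + 2.0 * f * f * (2.0 * a - af) ** 2
    )
    s_dm = sigma2_D + f * pq * (
        am * am
        - af * af
        + 4.0 * (a - af) * (a - am)
        - f * (dom2 + 2.0 * (2.0 * a - am) * (2.0 * a - 2.0 * am - af))
        + 2.0 * f * f * (2.0 * a - am) ** 2
    )
    c_f = sigma_AD_f - f * pq * (
        2.0 * a * (af - am)
        + 2.0 * af * am
        + f * (2.0 * a - af) * (3.0 * af + am + 2.0 * f * (2.0 * a - af))
    )
    c_m = sigma_AD_m - f * pq * (
        2.0 * a * (am - af)
        + 2.0 * af * am
        + f * (2.0 * a - am) * (3.0 * am + af + 2.0 * f * (2.0 * a - am))
    )
    return InbredVarianceComponents(
        sigma2_G=total_variance_inbred(locus, pop),
        sigma2_A_f=s_af,
        sigma2_A_m=s_am,
        sigma2_D_f=s_df,
        sigma2_D_m=s_dm,
        sigma_AD_f=c_f,
        sigma_AD_m=c_m,
    )
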