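"""One-locus, two-allele model of a quantitative trait under genomic imprinting.

An imprinted gene is expressed at a level that depends on the sex of the
parent it was inherited from, so the two reciprocal heterozygotes at a
diallelic autosomal locus may have different mean phenotypes.  Writing the
maternally inherited allele first, the genotypic values on the trait scale
are

    G(A1A1) = 0
    G(A2A1) = a(1 + k1)    (A2 inherited from the mother)
    G(A1A2) = a(1 + k2)    (A2 inherited from the father)
    G(A2A2) = 2a

with imprinting/dominance coefficients ``k1, k2 in [-1, 1]``.  ``k1 = k2``
recovers ordinary Mendelian dominance; ``k1 = -k2`` is pure imprinting with
no dominance (the heterozygote mean sits midway between the homozygotes);
``k1 = 1, k2 = -1`` is complete silencing of the paternal allele.

This module defines the parameter containers and the basic population
quantities: genotype frequencies (optionally with excess homozygosity ``f``),
the sex-specific average-effect terms

    alpha_f = a(1 + k1*p1 - k2*p2),   alpha_m = a(1 + k2*p1 - k1*p2),

the population mean and the total genetic variance of an outbred
(Hardy-Weinberg) population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, NamedTuple


class Genotype(NamedTuple):
    """Ordered genotype: the maternally inherited allele is written first.

    The ordering is load-bearing: ``Genotype(2, 1)`` (A2 from the mother) and
    ``Genotype(1, 2)`` (A2 from the father) are distinct reciprocal
    heterozygotes with different genotypic values under imprinting.  No
    unordered genotype type exists in this package.
    """

    maternal: int
    paternal: int

    def __str__(self) -> str:  # e.g. "A2A1"
        return f"A{self.maternal}A{self.paternal}"


G11 = Genotype(1, 1)
G21 = Genotype(2, 1)
G12 = Genotype(1, 2)
G22 = Genotype(2, 2)

#: Canonical genotype order used throughout: A1A1, A2A1, A1A2, A2A2.
GENOTYPES: tuple[Genotype, ...] = (G11, G21, G12, G22)


@dataclass(frozen=True)
class ImprintingLocus:
    """Genotypic-value parameters (a, k1, k2) of an imprinted diallelic locus.

    Parameters
    ----------
    a
        Half the homozygote difference: A2A2 has value ``2a``, A1A1 has 0.
    k1
        Coefficient of the heterozygote carrying a *maternally* inherited A2
        (genotype A2A1, value ``a(1 + k1)``).  Must lie in [-1, 1].
    k2
        Coefficient of the heterozygote carrying a *paternally* inherited A2
        (genotype A1A2, value ``a(1 + k2)``).  Must lie in [-1, 1].
    """

    a: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.a):
            raise ValueError(f"a must be finite, got {self.a!r}")
        for name in ("k1", "k2"):
            k = getattr(self, name)
            if not (math.isfinite(k) and -1.0 <= k <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1], got {k!r}")

    def swapped(self) -> "ImprintingLocus":
        """The locus with the roles of maternal and paternal silencing exchanged."""
        return ImprintingLocus(self.a, self.k2, self.k1)


@dataclass(frozen=True)
class PopulationState:
    """Allele frequency and inbreeding coefficient of the population.

    ``f`` is the probability-scale excess homozygosity: the population is a
    mixture of a Hardy-Weinberg group (weight ``1 - f``) and a fully
    homozygous group (weight ``f``).  ``f`` is treated as a fixed parameter,
    stable across generations.
    """

    p1: float
    f: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p1) and 0.0 <= self.p1 <= 1.0):
            raise ValueError(f"p1 must lie in [0, 1], got {self.p1!r}")
        if not (math.isfinite(self.f) and 0.0 <= self.f <= 1.0):
            raise ValueError(f"f must lie in [0, 1], got {self.f!r}")
        if self.p1 in (0.0, 1.0):
            warnings.warn(
                f"p1 = {self.p1}: the locus is fixed and all genetic variances are 0",
                stacklevel=3,
            )

    @property
    def p2(self) -> float:
        return 1.0 - self.p1

    @property
    def outbred(self) -> bool:
        return self.f == 0.0


class AlphaPair(NamedTuple):
    """Sex-specific average-effect terms (alpha_f maternal, alpha_m paternal).

    Satisfies the identity ``alpha_f - alpha_m = a (k1 - k2)``.
    """

    alpha_f: float
    alpha_m: float


def require_outbred(pop: PopulationState, what: str) -> None:
    """Raise if ``pop`` is inbred; the inbreeding module owns the f > 0 case."""
    if pop.f != 0.0:
        raise ValueError(
            f"{what} is defined for an outbred population (f = 0); "
            f"got f = {pop.f}. Use the inbreeding module for f > 0."
        )


def genotypic_values(locus: ImprintingLocus) -> Dict[Genotype, float]:
    """Map each ordered genotype to its genotypic value G_ij."""
    a, k1, k2 = locus.a, locus.k1, locus.k2
    return {
        G11: 0.0,
        G21: a * (1.0 + k1),
        G12: a * (1.0 + k2),
        G22: 2.0 * a,
    }


def genotype_frequencies(pop: PopulationState) -> Dict[Genotype, float]:
    """Genotype frequencies under the HW/homozygous two-group mixture.

    freq(A1A1) = p1^2 + f p1 p2, freq(A2A1) = freq(A1A2) = p1 p2 (1 - f),
    freq(A2A2) = p2^2 + f p1 p2; at f = 0 these are Hardy-Weinberg
    proportions with the reciprocal heterozygotes kept separate.
    """
    p1, p2, f = pop.p1, pop.p2, pop.f
    het = p1 * p2 * (1.0 - f)
    return {
        G11: p1 * p1 + f * p1 * p2,
        G21: het,
        G12: het,
        G22: p2 * p2 + f * p1 * p2,
    }


def alphas(locus: ImprintingLocus, pop: PopulationState) -> AlphaPair:
    """Female (maternal) and male (paternal) average-effect terms.

    These are the per-transmitted-allele slopes of the outbred model;
    inbreeding has its own corrected effects in the inbreeding module.
    """
    a, k1, k2 = locus.a, locus.k1, locus.k2
    p1, p2 = pop.p1, pop.p2
    return AlphaPair(
        alpha_f=a * (1.0 + k1 * p1 - k2 * p2),
        alpha_m=a * (1.0 + k2 * p1 - k1 * p2),
    )


def population_mean(locus: ImprintingLocus, pop: PopulationState) -> float:
    """Mean genotypic value, mu = a p2 (2 + p1 (k1 + k2)), of an outbred population."""
    require_outbred(pop, "population_mean")
    return locus.a * pop.p2 * (2.0 + pop.p1 * (locus.k1 + locus.k2))


def total_genetic_variance(locus: ImprintingLocus, pop: PopulationState) -> float:
    """Total genetic variance of an outbred population.

    sigma2_G = p1 p2 (alpha_f^2 + alpha_m^2 + a^2 p1 p2 (k1 + k2)^2).
    """
    require_outbred(pop, "total_genetic_variance")
    af, am = alphas(locus, pop)
    p1, p2 = pop.p1, pop.p2
    a, k1, k2 = locus.a, locus.k1, locus.k2
    return p1 * p2 * (af * af + am * am + a * a * p1 * p2 * (k1 + k2) ** 2)
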