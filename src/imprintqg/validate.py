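"""Random-grid identity checks: closed forms vs algebra vs enumeration.

Every identity the model guarantees is checked numerically on a seeded
random grid over (a, k1, k2, p1, f, t), each at a strict tolerance
(default 1e-12).  This is the machinery behind ``imprintqg validate`` and
the package's own acceptance checks.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .core import (
    GENOTYPES,
    ImprintingLocus,
    PopulationState,
    alphas,
    genotype_frequencies,
    genotypic_values,
    population_mean,
    total_genetic_variance,
)
from .decompose import (
    Approach,
    breeding_values,
    relative_covariances,
    variance_components,
)
from .inbreeding import inbred_variance_components, total_variance_inbred
from .oracle import (
    oracle_inbred_components,
    oracle_moments,
    oracle_relative_covariances,
    oracle_selection_response,
)
from .selection import (
    SelectionModel,
    allele_freqs_after_selection,
    mean_fitness,
    response_to_selection,
)

ALL_APPROACHES = tuple(Approach)


def draw_parameters(rng: np.random.Generator) -> tuple:
    """One admissible random parameter point (t kept inside the fitness domain)."""
    a = rng.uniform(-1.5, 1.5)
    k1 = rng.uniform(-1.0, 1.0)
    k2 = rng.uniform(-1.0, 1.0)
    p1 = rng.uniform(0.02, 0.98)
    f = rng.uniform(0.0, 1.0)
    gmax = max(abs(v) for v in (a * (1 + k1), a * (1 + k2), 2 * a))
    # keep every phi_ij = 1 + G t comfortably positive
    bound = 0.45 / gmax if gmax > 0 else 0.45
    t = rng.uniform(-bound, bound)
    return a, k1, k2, p1, f, t


def _point_errors(a: float, k1: float, k2: float, p1: float, f: float, t: float) -> Dict[str, float]:
    locus = ImprintingLocus(a=a, k1=k1, k2=k2)
    out = PopulationState(p1=p1, f=0.0)
    inb = PopulationState(p1=p1, f=f)
    sel = SelectionModel(t=t)
    errs: Dict[str, float] = {}

    af, am = alphas(locus, out)
    errs["alpha_difference_identity"] = abs((af - am) - a * (k1 - k2))

    G = genotypic_values(locus)
    freqs = genotype_frequencies(inb)
    errs["genotype_frequencies_sum_to_1"] = abs(sum(freqs.values()) - 1.0)

    mu = population_mean(locus, out)
    sigma2_G = total_genetic_variance(locus, out)
    o_mean, o_var = oracle_moments(locus, out)
    errs["mean_matches_enumeration"] = abs(mu - o_mean)
    errs["variance_matches_enumeration"] = abs(sigma2_G - o_var)

    # partition identity + zero-mean breeding values, every approach
    part_err = bv_err = 0.0
    hw = genotype_frequencies(out)
    for ap in ALL_APPROACHES:
        c = variance_components(locus, out, ap)
        part_err = max(
            part_err,
            abs(c.sigma2_A + c.sigma2_D + c.sigma_AD_f + c.sigma_AD_m - sigma2_G),
        )
        bv = breeding_values(locus, out, ap)
        bv_err = max(bv_err, abs(sum(hw[g] * bv.values[g] for g in GENOTYPES)))
        bv_err = max(bv_err, abs(bv.het_mean - 0.5 * (p1 - (1 - p1)) * (af + am)))
    errs["variance_partition_sums_to_total"] = part_err
    errs["breeding_values_mean_zero"] = bv_err

    # inbreeding: closed forms vs mixture-distribution construction; Eq-8 mixture split
    ic = inbred_variance_components(locus, inb)
    oc = oracle_inbred_components(locus, inb)
    errs["inbred_components_match_enumeration"] = max(
        abs(ic.sigma2_G - oc.sigma2_G),
        abs(ic.sigma2_A_f - oc.sigma2_A_f),
        abs(ic.sigma2_A_m - oc.sigma2_A_m),
        abs(ic.sigma2_D_f - oc.sigma2_D_f),
        abs(ic.sigma2_D_m - oc.sigma2_D_m),
        abs(ic.sigma_AD_f - oc.sigma_AD_f),
        abs(ic.sigma_AD_m - oc.sigma_AD_m),
    )
    c1 = variance_components(locus, out, Approach.A1)
    mixture = (
        (1 - f) * sigma2_G
        + f * 4 * a * a * p1 * (1 - p1)
        + 0.5
        * f
        * (1 - f)
        * (2 * c1.sigma2_D + 2 * c1.sigma_AD_f + 2 * c1.sigma_AD_m)
    )
    errs["inbred_variance_mixture_identity"] = abs(
        total_variance_inbred(locus, inb) - mixture
    )

    # relative covariances: closed A1/2b row vs enumeration
    closed = relative_covariances(locus, out, Approach.A1)
    orc = oracle_relative_covariances(locus, out)
    errs["relative_covariances_match_enumeration"] = max(
        abs(closed.cov_mother_offspring - orc.cov_mother_offspring),
        abs(closed.cov_father_offspring - orc.cov_father_offspring),
        abs(closed.cov_fullsib - orc.cov_fullsib),
        abs(closed.cov_halfsib_maternal - orc.cov_halfsib_maternal),
        abs(closed.cov_halfsib_paternal - orc.cov_halfsib_paternal),
    )

    # selection identities
    errs["mean_fitness_identity"] = abs(mean_fitness(locus, out, sel) - (1 + t * mu))
    p1p, p2p = allele_freqs_after_selection(locus, out, sel)
    errs["post_selection_frequencies_sum_to_1"] = abs(p1p + p2p - 1.0)
    resp = response_to_selection(locus, out, sel)
    df, dm, q1 = oracle_selection_response(locus, out, sel)
    errs["response_equal_across_parental_sexes"] = abs(df - dm)
    errs["response_matches_enumeration"] = max(
        abs(resp.delta_mu_f - df), abs(resp.delta_mu_m - dm)
    )
    errs["post_selection_frequency_matches_enumeration"] = abs(p1p - q1)

    # Mendelian collapse: k1 = k2 makes all approaches identical
    loc_k = ImprintingLocus(a=a, k1=k1, k2=k1)
    ref_c = variance_components(loc_k, out, Approach.A1)
    ref_r = relative_covariances(loc_k, out, Approach.A1)
    ref_b = breeding_values(loc_k, out, Approach.A1)
    collapse = 0.0
    for ap in ALL_APPROACHES[1:]:
        c = variance_components(loc_k, out, ap)
        r = relative_covariances(loc_k, out, ap)
        b = breeding_values(loc_k, out, ap)
        collapse = max(
            collapse,
            abs(c.sigma2_A - ref_c.sigma2_A),
            abs(c.sigma2_D - ref_c.sigma2_D),
            abs(c.sigma_AD_f - ref_c.sigma_AD_f),
            abs(c.sigma_AD_m - ref_c.sigma_AD_m),
            abs(r.cov_mother_offspring - ref_r.cov_mother_offspring),
            abs(r.cov_father_offspring - ref_r.cov_father_offspring),
            abs(r.cov_fullsib - ref_r.cov_fullsib),
            abs(r.cov_halfsib_maternal - ref_r.cov_halfsib_maternal),
            abs(r.cov_halfsib_paternal - ref_r.cov_halfsib_paternal),
            max(abs(b.values[g] - ref_b.values[g]) for g in GENOTYPES),
        )
    errs["mendelian_collapse_of_approaches"] = collapse
    return errs


def run_identity_checks(
    seed: int = 0, grid_size: int = 1000, tol: float = 1e-12
) -> pd.DataFrame:
    """Evaluate every identity on a seeded random grid.

    Returns one row per identity with the maximum absolute error observed
    over the grid and whether it stayed below ``tol``.
    """
    rng = np.random.default_rng(seed)
    worst: Dict[str, float] = {}
    for _ in range(grid_size):
        point = draw_parameters(rng)
        for name, err in _point_errors(*point).items():
            worst[name] = max(worst.get(name, 0.0), err)
    rows: List[dict] = [
        {"identity": name, "max_abs_error": err, "passed": err <= tol}
        for name, err in worst.items()
    ]
    return pd.DataFrame(rows).set_index("identity")
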