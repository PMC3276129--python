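"""Tabular rendering of decomposition results, including the worked scenarios.

Two reference scenarios are built in: near-complete *paternal* inactivation
(p1 = p2 = 1/2, a = 1/2, k1 = 9/10, k2 = -8/10) and near-complete *maternal*
inactivation (p1 = 1/3, a = 1/2, k1 = -7/10, k2 = 95/100).  ``render_table6``
regenerates every variance component and relative covariance for all five
approaches in both scenarios, rounded half-even to 4 decimals; raw doubles
are available from the JSON/record paths.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Optional, Tuple

from .core import ImprintingLocus, PopulationState
from .decompose import (
    Approach,
    relative_covariances,
    variance_components,
)

def round_printed(x: float, decimals: int) -> float:
    """Round with ties away from zero, the convention the printed tables use.

    (Binary round-half-even would turn the exact tie 0.03125 into 0.0312;
    the tables print 0.0313.)
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: (locus, population) for the two built-in worked scenarios.
SCENARIOS: Dict[str, Tuple[ImprintingLocus, PopulationState]] = {
    "paternal_inactivation": (
        ImprintingLocus(a=0.5, k1=0.9, k2=-0.8),
        PopulationState(p1=0.5),
    ),
    "maternal_inactivation": (
        ImprintingLocus(a=0.5, k1=-0.7, k2=0.95),
        PopulationState(p1=1.0 / 3.0),
    ),
}

#: Row labels of the scenario table, in display order.
TABLE6_ROWS = (
    "additive_variance_female",
    "additive_variance_male",
    "dominance_variance",
    "sigma_AD_female",
    "sigma_AD_male",
    "cov_offspring_parent_female",
    "cov_offspring_parent_male",
    "cov_halfsib_female",
    "cov_halfsib_male",
    "cov_fullsib",
)

#: Approach groups as the scenario table columns present them.
TABLE6_GROUPS = (("A1_2b", Approach.A1), ("A2a_3b", Approach.A2a), ("A3a", Approach.A3a))


def scenario_cells(
    locus: ImprintingLocus, pop: PopulationState, approach: Approach
) -> Dict[str, Optional[float]]:
    """The ten table cells for one approach group (None where the layout merges).

    For the pooled approaches the single value sits in the "female" row and
    the "male" row is blank, mirroring the merged cells of the layout.
    """
    comps = variance_components(locus, pop, approach)
    covs = relative_covariances(locus, pop, approach)
    pooled = approach not in (Approach.A1, Approach.A2b)
    return {
        "additive_variance_female": comps.sigma2_A if pooled else comps.sigma2_A_f,
        "additive_variance_male": None if pooled else comps.sigma2_A_m,
        "dominance_variance": comps.sigma2_D,
        "sigma_AD_female": comps.sigma_AD_f,
        "sigma_AD_male": None if pooled else comps.sigma_AD_m,
        "cov_offspring_parent_female": covs.cov_mother_offspring,
        "cov_offspring_parent_male": None if pooled else covs.cov_father_offspring,
        "cov_halfsib_female": covs.cov_halfsib_maternal,
        "cov_halfsib_male": None if pooled else covs.cov_halfsib_paternal,
        "cov_fullsib": covs.cov_fullsib,
    }


def table6_values(decimals: Optional[int] = 4) -> Dict[str, Dict[str, Dict[str, Optional[float]]]]:
    """Nested dict scenario -> approach group -> row -> value (rounded half-even)."""
    out: Dict[str, Dict[str, Dict[str, Optional[float]]]] = {}
    for scen, (locus, pop) in SCENARIOS.items():
        out[scen] = {}
        for col, approach in TABLE6_GROUPS:
            cells = scenario_cells(locus, pop, approach)
            if decimals is not None:
                cells = {
                    k: (None if v is None else round_printed(v, decimals))
                    for k, v in cells.items()
                }
            out[scen][col] = cells
    return out


def render_table6(decimals: int = 4) -> str:
    """TSV of both worked scenarios, one column per scenario x approach group."""
    values = table6_values(decimals)
    cols = [f"{scen}:{col}" for scen in SCENARIOS for col, _ in TABLE6_GROUPS]
    lines = ["\t".join(["quantity"] + cols)]
    for row in TABLE6_ROWS:
        cells = []
        for scen in SCENARIOS:
            for col, _ in TABLE6_GROUPS:
                v = values[scen][col][row]
                cells.append("" if v is None else f"{v:.{decimals}f}")
        lines.append("\t".join([row] + cells))
    return "\n".join(lines) + "\n"


def render_tsv(header: Iterable[str], rows: Iterable[Iterable[object]]) -> str:
    """Plain TSV with a header row; floats rendered at full precision."""

    def fmt(x: object) -> str:
        if x is None:
            return ""
        if isinstance(x, float):
            return repr(x)
        return str(x)

    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(fmt(x) for x in row))
    return "\n".join(lines) + "\n"
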