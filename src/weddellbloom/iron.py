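"""Fe:C stoichiometric iron budgets for bloom carbon accumulation.

Converts depth-integrated particulate organic carbon (g C m-2) or net
primary productivity series (mg C m-2 d-1) into areal iron demands
(umol Fe m-2) via cellular iron-to-carbon mole ratios.  Southern Ocean
phytoplankton span roughly 2.3e-6 (iron-replete) to 20e-6 (iron-
deplete) mol Fe : mol C; productivity-based demand conventionally uses
a mean ratio of 4.3e-6 (4.3 umol:mol).

The stoichiometry is exact and linear:

    demand [umol Fe m-2] = POC [g C m-2] / M_C [g mol-1] * (Fe:C) * 1e6

with the molar mass of carbon M_C = 12.011 g mol-1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CARBON_MOLAR_MASS = 12.011  # g mol-1


@dataclass(frozen=True)
class FeCRatio:
    """Cellular Fe:C mole ratio (mol Fe per mol C) with provenance."""

    value: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("Fe:C ratio must be positive")


#: Lower bound, iron-replete Southern Ocean waters.
FE_C_REPLETE = FeCRatio(2.3e-6, "Fe-replete lower bound")
#: Upper bound, iron-deplete Southern Ocean waters.
FE_C_DEPLETE = FeCRatio(20e-6, "Fe-deplete upper bound")
#: Mean ratio used to convert NPP into daily iron demand.
FE_C_MEAN_NPP = FeCRatio(4.3e-6, "sub-Antarctic mean for NPP conversion")


@dataclass(frozen=True)
class IronBudget:
    """An areal iron demand derived from a carbon input."""

    carbon_g_m2: float
    ratio: FeCRatio
    demand_umol_m2: float
    molar_mass: float = CARBON_MOLAR_MASS

    @property
    def demand_rounded(self) -> float:
        """Demand at reporting precision (1 decimal, umol Fe m-2)."""
        return round(self.demand_umol_m2, 1)


def carbon_to_iron(poc_g_m2: float, ratio: FeCRatio | float,
                   molar_mass: float = CARBON_MOLAR_MASS) -> IronBudget:
    """Iron required to build ``poc_g_m2`` of organic carbon."""
    if poc_g_m2 < 0:
        raise ValueError(f"POC must be >= 0, got {poc_g_m2}")
    if not isinstance(ratio, FeCRatio):
        ratio = FeCRatio(float(ratio))
    demand = poc_g_m2 / molar_mass * ratio.value * 1e6
    return IronBudget(carbon_g_m2=poc_g_m2, ratio=ratio,
                      demand_umol_m2=demand, molar_mass=molar_mass)


def iron_demand_range(poc_g_m2: float,
                      ratio_low: FeCRatio | float = FE_C_REPLETE,
                      ratio_high: FeCRatio | float = FE_C_DEPLETE,
                      molar_mass: float = CARBON_MOLAR_MASS,
                      ) -> tuple[IronBudget, IronBudget]:
    """Bracketing (low, high) iron demands from two Fe:C ratios."""
    low = carbon_to_iron(poc_g_m2, ratio_low, molar_mass)
    high = carbon_to_iron(poc_g_m2, ratio_high, molar_mass)
    if not low.ratio.value < high.ratio.value:
        raise ValueError("ratio_low must be < ratio_high")
    return low, high


def autotrophic_adjust(poc_g_m2: float, fraction: float) -> float:
    """Scale total POC down to its autotrophic (phytoplankton) share.

    Phytoplankton typically make up only 20-30% of total POC; the
    remainder is detrital and heterotrophic carbon that carries no
    growth iron demand.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"autotrophic fraction must be in (0, 1], got {fraction}")
    if poc_g_m2 < 0:
        raise ValueError("POC must be >= 0")
    return poc_g_m2 * fraction


def npp_to_fe_demand(npp_mgC_m2_d, ratio: FeCRatio | float = FE_C_MEAN_NPP,
                     molar_mass: float = CARBON_MOLAR_MASS):
    """Cumulative iron demand of a daily NPP series over a bloom period.

    ``npp_mgC_m2_d`` is a sequence (or pandas Series) of daily NPP in
    mg C m-2 d-1; each entry contributes one day of production.  Returns
    ``(total IronBudget, daily demand series in umol Fe m-2 d-1)``.
    """
    values = (npp_mgC_m2_d.to_numpy() if isinstance(npp_mgC_m2_d, pd.Series)
              else np.asarray(npp_mgC_m2_d, dtype=float))
    if np.any(values < 0):
        raise ValueError("NPP values must be >= 0")
    if not isinstance(ratio, FeCRatio):
        ratio = FeCRatio(float(ratio))
    daily = values / 1000.0 / molar_mass * ratio.value * 1e6
    if isinstance(npp_mgC_m2_d, pd.Series):
        daily = pd.Series(daily, index=npp_mgC_m2_d.index,
                          name="fe_demand_umol_m2_d")
    total_carbon = float(values.sum() / 1000.0)
    budget = IronBudget(carbon_g_m2=total_carbon, ratio=ratio,
                        demand_umol_m2=float(np.sum(daily)),
                        molar_mass=molar_mass)
    return budget, daily
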