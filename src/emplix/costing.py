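"""Electricity and dollar cost of electromicrobial lixiviant production.

Single-cell systems (enzymatic CO2 fixation): the charge to make one
molecule is e * nu_e, so the electricity per gram is

    C_E = F * dU_cell * nu_e / (MW * xi_I2)        [J/g]

Dual-cell systems (electrochemical CO2-to-formate, then microbial
assimilation): cell 1 spends e * nu_r * nu_er per molecule at dU_cell1,
degraded by its Faradaic efficiency and the carbon transfer efficiency;
cell 2 spends e * nu_e,add at dU_cell2:

    C_E = (F / MW) * [ dU_cell1 * nu_r * nu_er / (xi_I1 * xi_C)
                       + dU_cell2 * nu_e,add / xi_I2 ]

Dollar costs use the configurable electricity price (default 3 cents/kWh).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bioenergetics import (
    DEFAULT_PARAMS,
    DU_MEMBRANE_TRIPLET,
    ElectronTransportParams,
    electrons,
)
from .constants import CONSTANTS, E_CHARGE, F
from .lixiviants import get_lixiviant, lixiviant_registry
from .networks import balance, shipped_network
from .networks.library import CO2_PATHWAYS, FIXATION_PATHWAYS, LIXIVIANT_IDS
from .scenarios import EMPScenario, scenario_for


@dataclass(frozen=True)
class EnergyCost:
    """Electricity per gram with its membrane-potential uncertainty band."""

    lixiviant: str
    pathway: str
    mediator: str
    e_per_gram: float  # J/g at the central membrane potential
    lower: float  # J/g at the band-edge membrane potentials
    upper: float
    cost_per_tonne: float  # $/tonne at the configured electricity price
    production_rate_per_s: float  # molecules/s at the scenario's power

    def __post_init__(self) -> None:
        if not self.lower <= self.e_per_gram <= self.upper:
            raise ValueError(
                f"band endpoints disordered: {self.lower} <= {self.e_per_gram} "
                f"<= {self.upper} fails"
            )


def energy_per_gram_single(
    nu_e: float, delta_u_cell: float, mw: float, xi_i2: float = 1.0
) -> float:
    """Eq for the single bio-electrochemical cell; J per gram."""
    if mw <= 0 or delta_u_cell <= 0 or not 0 < xi_i2 <= 1:
        raise ValueError("inputs must be positive, xi_i2 in (0, 1]")
    if nu_e < 0:
        raise ValueError("nu_e must be nonnegative")
    return F * delta_u_cell * nu_e / (mw * xi_i2)


def energy_per_gram_dual(
    nu_e_add: float, nu_r: float, scenario: EMPScenario, mw: float
) -> float:
    """Dual-cell (electrochemical formate) configuration; J per gram."""
    if not scenario.is_formate:
        raise ValueError(
            f"scenario {scenario.id!r} has no abiotic CO2-reduction cell"
        )
    cell1 = (
        scenario.delta_u_cell1
        * nu_r
        * scenario.nu_er
        / (scenario.xi_i1 * scenario.xi_c)
    )
    cell2 = scenario.delta_u_cell2 * nu_e_add / scenario.xi_i2
    return (F / mw) * (cell1 + cell2)


def cost_per_tonne(e_per_gram: float, price: float | None = None) -> float:
    """Convert J/g to $/tonne: x 1e6 g/t, / 3.6e6 J/kWh, x price."""
    if e_per_gram < 0:
        raise ValueError("e_per_gram must be nonnegative")
    if price is None:
        price = CONSTANTS.electricity_price
    return e_per_gram * 1e6 / CONSTANTS.kwh_in_joules * price


def production_rate(
    p_electric: float, delta_u_cell: float, nu_e: float, xi_i2: float = 1.0
) -> float:
    """Lixiviant molecules made per second at electrical power P (watts)."""
    if p_electric < 0:
        raise ValueError("power must be nonnegative")
    if p_electric == 0:
        return 0.0
    return p_electric * xi_i2 / (delta_u_cell * E_CHARGE * nu_e)


def _energy_at(
    pathway: str,
    lixiviant: str,
    mediator: str,
    params: ElectronTransportParams,
) -> tuple[float, float]:
    """(J/g, nu_e) for one configuration at the given transport parameters."""
    spec = get_lixiviant(lixiviant)
    _, req = balance(shipped_network(pathway, lixiviant))
    formate = pathway == "formolase"
    scenario = scenario_for(mediator, formate=formate)
    nu = electrons(req, mediator, params).nu_e
    if formate:
        epg = energy_per_gram_dual(nu, req.nu_r, scenario, spec.mw)
    else:
        epg = energy_per_gram_single(nu, scenario.delta_u_cell2, spec.mw, scenario.xi_i2)
    return epg, nu


def energy_cost(
    lixiviant: str,
    pathway: str,
    mediator: str,
    du_membrane_triplet: tuple[float, float, float] = DU_MEMBRANE_TRIPLET,
    params: ElectronTransportParams = DEFAULT_PARAMS,
    price: float | None = None,
) -> EnergyCost:
    """Full costed result for one (lixiviant, pathway, mediator) combination.

    The central value uses the middle membrane potential of the triplet; the
    band spans the values at all three (the requirement is a step function,
    so band endpoints are evaluated, not interpolated).
    """
    lo_du, mid_du, hi_du = sorted(du_membrane_triplet)
    values = {
        du: _energy_at(pathway, lixiviant, mediator, params.at_membrane_potential(du))
        for du in (lo_du, mid_du, hi_du)
    }
    central, nu_central = values[mid_du]
    band = [values[du][0] for du in (lo_du, mid_du, hi_du)]
    scenario = scenario_for(mediator, formate=(pathway == "formolase"))
    rate = production_rate(
        scenario.p_electric, scenario.delta_u_cell2, nu_central, scenario.xi_i2
    ) if nu_central > 0 else 0.0
    return EnergyCost(
        lixiviant=lixiviant,
        pathway=pathway,
        mediator=mediator,
        e_per_gram=central,
        lower=min(band),
        upper=max(band),
        cost_per_tonne=cost_per_tonne(central, price),
        production_rate_per_s=rate,
    )


def cost_table(
    lixiviants: tuple[str, ...] | None = None,
    pathways: tuple[str, ...] | None = None,
    mediators: tuple[str, ...] = ("H2", "EEU"),
    du_membrane_triplet: tuple[float, float, float] = DU_MEMBRANE_TRIPLET,
    params: ElectronTransportParams = DEFAULT_PARAMS,
    price: float | None = None,
) -> pd.DataFrame:
    """One row per (lixiviant, pathway, mediator) combination.

    Columns: lixiviant, pathway, mediator, kj_per_g, kj_per_g_lo,
    kj_per_g_hi, usd_per_tonne.
    """
    lixiviants = lixiviants or tuple(lixiviant_registry())
    pathways = pathways or FIXATION_PATHWAYS
    rows = []
    for lix in lixiviants:
        for pw in pathways:
            for med in mediators:
                ec = energy_cost(lix, pw, med, du_membrane_triplet, params, price)
                rows.append(
                    {
                        "lixiviant": lix,
                        "pathway": pw,
                        "mediator": med,
                        "kj_per_g": ec.e_per_gram / 1e3,
                        "kj_per_g_lo": ec.lower / 1e3,
                        "kj_per_g_hi": ec.upper / 1e3,
                        "usd_per_tonne": ec.cost_per_tonne,
                    }
                )
    return pd.DataFrame(rows)


__all__ = [
    "EnergyCost",
    "energy_per_gram_single",
    "energy_per_gram_dual",
    "cost_per_tonne",
    "production_rate",
    "energy_cost",
    "cost_table",
    "CO2_PATHWAYS",
    "LIXIVIANT_IDS",
]
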