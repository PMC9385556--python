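"""Forsterite and lixiviant demand for a target CO2 drawdown.

Forsterite (Mg2SiO4, MW 140.69) carries two Mg atoms per formula unit, each
of which can capture one carbon atom as magnesite, so the mineral demand is

    M_forsterite = M_C * MW_forsterite / (MW_C * n_C)

The lixiviant demand folds in the four high-uncertainty process parameters —
lixiviant concentration c_lix, Mg extraction efficiency eta_ex, carbonate
precipitation efficiency eta_precip, and pulp density rho_pulp — through
their aggregate, the inverse mineralization performance

    zeta = c_lix / (eta_ex * eta_precip * rho_pulp)      [mol/g]

    M_lix = M_C * MW_forsterite * MW_lix * zeta / (MW_C * n_C)

Masses are in grams of carbon internally; helpers convert from mass of CO2
(x 12/44). Biomass-equivalent thresholds convert bio-energy withdrawals to
dry mass at 15 GJ per dry tonne of cellulosic material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lixiviants import LixiviantSpec, get_lixiviant


@dataclass(frozen=True)
class MineralConstants:
    mw_forsterite: float = 140.69  # g/mol
    mw_carbon: float = 12.0  # g/mol (the round value used in the demand formula)
    n_c_forsterite: int = 2  # C atoms sequestered per formula unit
    co2_to_c: float = 12.0 / 44.0
    rho_forsterite: float = 3.27e6  # g/m^3; cancels out, stored for completeness


MINERAL = MineralConstants()

#: dry cellulosic biomass energy density, J per gram (15 GJ/tonne)
BIOMASS_ENERGY_DENSITY = 15e9 / 1e6

GT = 1e15  # grams per gigatonne
TONNE = 1e6  # grams per tonne


@dataclass
class MineralizationScenario:
    """One draw of the four high-uncertainty process parameters."""

    c_lix: float  # mol/m^3
    eta_ex: float  # fraction
    eta_precip: float  # fraction
    pulp_density: float  # g/m^3
    v_forsterite: float | None = None  # m^3, optional bookkeeping
    v_lix: float | None = None  # m^3

    def __post_init__(self) -> None:
        if not 0 < self.eta_ex <= 1 or not 0 < self.eta_precip <= 1:
            raise ValueError("efficiencies must lie in (0, 1]")
        if self.c_lix <= 0 or self.pulp_density <= 0:
            raise ValueError("c_lix and pulp_density must be positive")

    @property
    def zeta(self) -> float:
        """Inverse CO2 mineralization performance, mol per gram."""
        return self.c_lix / (self.eta_ex * self.eta_precip * self.pulp_density)


def pulp_density_from_percent(percent_wv: float) -> float:
    """Convert pulp density in % w/v (g per 100 mL) to g/m^3 (x 1e4)."""
    return percent_wv * 1e4


def carbon_mass_from_co2(m_co2: float) -> float:
    """Grams of carbon in a given mass of CO2."""
    return m_co2 * MINERAL.co2_to_c


def forsterite_mass(m_c: float) -> float:
    """Minimum forsterite (g) to sequester m_c grams of carbon."""
    if m_c < 0:
        raise ValueError("carbon mass must be nonnegative")
    return m_c * MINERAL.mw_forsterite / (MINERAL.mw_carbon * MINERAL.n_c_forsterite)


def lixiviant_mass(
    m_c: float, lixiviant: LixiviantSpec | str, zeta: float
) -> float:
    """Dry lixiviant mass (g) to sequester m_c grams of carbon at a given zeta."""
    if isinstance(lixiviant, str):
        lixiviant = get_lixiviant(lixiviant)
    if m_c < 0 or zeta <= 0:
        raise ValueError("m_c must be >= 0 and zeta > 0")
    return (
        m_c
        * MINERAL.mw_forsterite
        * lixiviant.mw
        * zeta
        / (MINERAL.mw_carbon * MINERAL.n_c_forsterite)
    )


def zeta_for_mass(
    target_mass: float, m_c: float, lixiviant: LixiviantSpec | str
) -> float:
    """Invert lixiviant_mass: the zeta at which demand equals target_mass."""
    if isinstance(lixiviant, str):
        lixiviant = get_lixiviant(lixiviant)
    if target_mass <= 0 or m_c <= 0:
        raise ValueError("masses must be positive")
    return (
        target_mass
        * MINERAL.mw_carbon
        * MINERAL.n_c_forsterite
        / (m_c * MINERAL.mw_forsterite * lixiviant.mw)
    )


def optimistic_zeta(
    c_lix: float = 100.0,
    eta_ex: float = 1.0,
    eta_precip: float = 1.0,
    pulp_density: float = 5e5,
) -> float:
    """The optimistic parameter point: 100 mM, perfect efficiencies, 50% w/v.

    Defaults give 100 / (1 * 1 * 5e5) = 2e-4 mol/g.
    """
    return MineralizationScenario(c_lix, eta_ex, eta_precip, pulp_density).zeta


def biomass_mass_from_energy(
    energy_j: float, energy_density: float = BIOMASS_ENERGY_DENSITY
) -> float:
    """Dry biomass (g) equivalent to a bio-energy withdrawal (J)."""
    if energy_j < 0:
        raise ValueError("energy must be nonnegative")
    return energy_j / energy_density


@dataclass(frozen=True)
class ZetaThreshold:
    zeta: float
    mass_gt: float  # lixiviant demand at 20 GtCO2/yr, gigatonnes
    label: str


def fig_thresholds(
    m_co2: float = 20 * GT, lixiviant: str = "gluconic"
) -> list[ZetaThreshold]:
    """The six annotated zeta values for a 20 GtCO2/yr program.

    zeta_1: the optimistic parameter point; zeta_2: demand equal to annual US
    cellulosic biomass (1.4 Gt); zeta_3..5: demand equal to the 100/300/600
    EJ/yr bio-energy withdrawal transitions (at 15 GJ/t); zeta_6: demand
    equal to global net primary productivity (80 Gt dry biomass).
    """
    m_c = carbon_mass_from_co2(m_co2)
    anchors = [
        ("optimistic parameter point", lixiviant_mass(m_c, lixiviant, optimistic_zeta())),
        ("all US cellulosic biomass", 1.4 * GT),
        ("100 EJ/yr bio-energy withdrawal", biomass_mass_from_energy(100e18)),
        ("300 EJ/yr bio-energy withdrawal", biomass_mass_from_energy(300e18)),
        ("600 EJ/yr bio-energy withdrawal", biomass_mass_from_energy(600e18)),
        ("global net primary productivity", 80 * GT),
    ]
    out = []
    for label, mass in anchors:
        out.append(
            ZetaThreshold(
                zeta=zeta_for_mass(mass, m_c, lixiviant),
                mass_gt=mass / GT,
                label=label,
            )
        )
    return out
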