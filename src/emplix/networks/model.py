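"""Domain types for small stoichiometric networks.

Bookkeeping conventions
-----------------------
Metabolite formulas track C, H and O only. Redox carrier pairs use
pseudo-formulas: the reduced member (nadh, fdred) is "+H2" relative to its
oxidized partner, so a balanced reaction is balanced in real atoms once the
carrier's 2 H (= 2 e- + 2 H+) are counted. ATP/ADP have empty formulas —
phosphoryl groups and their hydrolysis waters are not tracked. The single
``nadh`` species stands for the whole NAD(P)H/quinol 2-electron pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from ..constants import degree_of_reduction

#: carrier pairs: reduced species -> oxidized partner
CARRIER_PAIRS = {"nadh": "nad", "fdred": "fdox", "atp": "adp"}


@dataclass(frozen=True)
class Reaction:
    """A single reaction: metabolite -> signed stoichiometric coefficient.

    Negative coefficients are consumed, positive produced. Coefficients are
    rational; no integrality is imposed on fluxes.
    """

    id: str
    stoich: dict[str, Fraction]
    reversible: bool = False

    def check_elemental_balance(self, formulas: dict[str, dict[str, int]]) -> None:
        """Assert C/H/O balance given the network's metabolite formulas."""
        for element in ("C", "H", "O"):
            total = Fraction(0)
            for met, coeff in self.stoich.items():
                if met not in formulas:
                    raise ValueError(f"{self.id}: no formula for metabolite {met!r}")
                total += coeff * formulas[met].get(element, 0)
            if total != 0:
                raise ValueError(
                    f"reaction {self.id!r} unbalanced in {element} (net {total})"
                )


@dataclass
class MetabolicNetwork:
    """An ordered reaction list plus the exchange contract.

    ``exchange_species`` are the metabolites allowed a nonzero net flux
    (carbon source, water, protons/O2, and the carrier pairs); everything
    else is internal and must balance exactly. ``target`` is produced at
    unit net flux when the network is balanced.
    """

    name: str
    reactions: list[Reaction]
    exchange_species: set[str]
    target: str
    carbon_source: str  # "co2" or "formate"
    formulas: dict[str, dict[str, int]] = field(default_factory=dict)
    pathway: str = ""
    lixiviant: str = ""

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for met in rxn.stoich:
                seen.setdefault(met)
        return list(seen)

    @property
    def internal_metabolites(self) -> list[str]:
        allowed = self.exchange_species | {self.target}
        return [m for m in self.metabolites if m not in allowed]

    def validate(self) -> None:
        if self.carbon_source not in ("co2", "formate"):
            raise ValueError(f"{self.name}: bad carbon source {self.carbon_source!r}")
        if self.target not in self.metabolites:
            raise ValueError(f"{self.name}: target {self.target!r} never produced")
        for rxn in self.reactions:
            rxn.check_elemental_balance(self.formulas)


@dataclass(frozen=True)
class CofactorRequirement:
    """Net cofactor demand per lixiviant molecule, after the surplus clamp.

    Surplus cofactors (a network that nets out producing ATP or NAD(P)H)
    are clamped to zero demand rather than credited — the reading consistent
    with the degenerate error bars on the most ATP-frugal pathway. The
    pre-clamp net values are retained for conservation checks.
    """

    nu_nadh: float  # NAD(P)H per lixiviant molecule
    nu_fd: float  # reduced ferredoxin per lixiviant molecule
    nu_atp: float  # ATP per lixiviant molecule
    nu_r: float  # primary C1 molecules (formate) consumed; 0 for CO2 networks
    carbon_in: float  # C1 molecules (CO2 or formate) consumed, net
    raw_nadh: float = 0.0  # pre-clamp net values
    raw_fd: float = 0.0
    raw_atp: float = 0.0

    def validate(self) -> None:
        for name in ("nu_nadh", "nu_fd", "nu_atp", "nu_r", "carbon_in"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} negative: {getattr(self, name)}")

    def check_conservation(self, network: MetabolicNetwork) -> None:
        """Carbon and electron conservation against the target's formula.

        CO2-source networks: net C1 influx equals the target's carbon count
        and all product electrons arrive on the 2-electron carriers,
        2*(nu_nadh + nu_fd) = degree of reduction. Formate-source networks:
        formate itself carries 2 electrons per molecule, so
        2*(nu_nadh + nu_fd) + 2*nu_r = degree of reduction.
        """
        formula = network.formulas[network.target]
        n_c = formula.get("C", 0)
        gamma = degree_of_reduction(formula)
        if abs(self.carbon_in - n_c) > 1e-9:
            raise ValueError(
                f"{network.name}: carbon_in {self.carbon_in} != target carbons {n_c}"
            )
        electrons = 2 * (self.raw_nadh + self.raw_fd)
        if network.carbon_source == "formate":
            electrons += 2 * self.nu_r
        if abs(electrons - gamma) > 1e-9:
            raise ValueError(
                f"{network.name}: carrier electrons {electrons} != "
                f"degree of reduction {gamma}"
            )
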