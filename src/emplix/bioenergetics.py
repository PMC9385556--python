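"""Electron requirements for lixiviant synthesis.

Converts a network's cofactor demand (NAD(P)H, reduced ferredoxin, ATP per
lixiviant molecule) into electrons delivered at the electrode, for the two
electron-delivery mechanisms:

* **H2 mediation** — electrons arrive at the hydrogenase level
  (U_H2 = -0.41 V), comfortably below NAD(P)H, so each carrier costs its two
  electrons and only ATP regeneration adds overhead: each electron falling
  from H2 to the terminal acceptor can pump ``floor((U_acceptor - U_H2)/
  dU_membrane)`` protons, and one ATP costs ``ceil(dG_ATP / (F*dU_membrane))``
  protons.

* **EEU (extracellular electron uptake)** — electrons enter at the quinone
  level (U_Q = -0.0885 V), *above* NAD(P)H and ferredoxin, so reverse
  electron transport must pump them uphill: each NAD(P)H costs an extra
  ``ceil((U_Q - U_NADH)/dU_membrane)`` protons *per electron* — and each
  NAD(P)H carries two electrons, so a carrier costs ``2*ceil(...)`` pumped
  protons (similarly for Fd). The proton-pumping span is the smaller drop
  from U_Q to the acceptor.

All proton bookkeeping is integer (floor/ceil of potential ratios), which
makes the electron requirement a step function of the membrane potential;
the requirement itself stays fractional (no rounding), as sub-integer
uncertainty-band widths require.

Note on signs and factors: the source equations print the pumping span as
``floor((U_donor - U_acceptor)/dU)``, which is negative for a downhill drop;
it is implemented here as ``floor((U_acceptor - U_donor)/dU)``, the number
of protons pumpable per electron. The printed EEU expression also writes
the reverse-transport cost per *carrier* rather than per electron; the
per-electron (factor-two) form is implemented because it is the one that
reproduces the published orderings (H2 delivery cheaper than EEU per gram,
and the citric/Wood-Ljungdahl/H2 global minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .constants import F
from .networks.model import CofactorRequirement

#: central / lower / upper membrane potentials (V) used for uncertainty bands
DU_MEMBRANE_TRIPLET = (0.08, 0.14, 0.24)

_ROUND = 9  # guard digits before floor/ceil to avoid FP edge artifacts


@dataclass(frozen=True)
class ElectronTransportParams:
    """Cellular electron-transport chain parameters (volts, joules/mol)."""

    delta_u_membrane: float = 0.14  # inner-membrane potential difference, V
    u_h2: float = -0.41  # H+/H2 couple
    u_acceptor: float = 0.82  # terminal acceptor (O2/H2O)
    u_q: float = -0.0885  # inner-membrane quinone pool
    u_nadh: float = -0.32  # NAD(P)+/NAD(P)H
    u_fd: float = -0.42  # ferredoxin
    u_mtr: float = -0.1  # Mtr EET complex (stored; EEU entry uses u_q)
    dg_atp: float = 50000.0  # ATP regeneration free energy, J/mol
    p_out: float | None = None  # protons pumped per e-; None = unlimited

    def validate(self) -> None:
        if not self.u_acceptor > self.u_q > self.u_nadh:
            raise ValueError("potentials must satisfy u_acceptor > u_q > u_nadh")
        if not 0.05 <= self.delta_u_membrane <= 0.4:
            raise ValueError(
                f"delta_u_membrane {self.delta_u_membrane} V outside [0.05, 0.4]"
            )

    def at_membrane_potential(self, du: float) -> "ElectronTransportParams":
        return replace(self, delta_u_membrane=du)


DEFAULT_PARAMS = ElectronTransportParams()
DEFAULT_PARAMS.validate()


@dataclass(frozen=True)
class ElectronRequirement:
    """Electrons per lixiviant molecule with the per-term breakdown."""

    nu_e: float
    mediator: str  # "H2" or "EEU"
    breakdown: dict[str, float]  # base / atp / nadh_uphill / fd_uphill terms


def _floor(x: float) -> int:
    return math.floor(round(x, _ROUND))


def _ceil(x: float) -> int:
    return math.ceil(round(x, _ROUND))


def protons_per_atp(params: ElectronTransportParams) -> int:
    """Protons needed to regenerate one ATP: ceil(dG_ATP / (F * dU_membrane)).

    F*dU_membrane is the energy a mole of protons releases crossing the
    membrane. Clamped at a minimum of one proton.
    """
    if params.delta_u_membrane <= 0:
        raise ValueError("delta_u_membrane must be positive")
    return max(1, _ceil(params.dg_atp / (F * params.delta_u_membrane)))


def _pump_span(params: ElectronTransportParams, u_entry: float) -> int:
    """Protons one electron pumps falling from the entry level to the acceptor."""
    span = _floor((params.u_acceptor - u_entry) / params.delta_u_membrane)
    if span < 1:
        raise ValueError(
            "membrane potential too large: an electron falling from "
            f"{u_entry} V to {params.u_acceptor} V cannot pump a proton, "
            "so no ATP can be regenerated"
        )
    return span


def electrons_h2(
    req: CofactorRequirement, params: ElectronTransportParams = DEFAULT_PARAMS
) -> ElectronRequirement:
    """Electrons per molecule with H2-mediated delivery.

    nu_e = 2 nu_NADH + 2 nu_Fd + nu_ATP * ceil(dG/(F dU)) / floor((U_acc - U_H2)/dU)
    """
    base = 2.0 * req.nu_nadh + 2.0 * req.nu_fd
    atp_term = 0.0
    if req.nu_atp > 0:
        span = _pump_span(params, params.u_h2)
        atp_term = req.nu_atp * protons_per_atp(params) / span
    breakdown = {"base": base, "atp": atp_term}
    return ElectronRequirement(base + atp_term, "H2", breakdown)


def electrons_eeu(
    req: CofactorRequirement, params: ElectronTransportParams = DEFAULT_PARAMS
) -> ElectronRequirement:
    """Electrons per molecule with extracellular electron uptake.

    The first term mirrors the H2 case with the quinone entry potential;
    the second and third add the reverse-electron-transport proton cost of
    lifting both electrons of each NAD(P)H and each ferredoxin above the
    quinone pool.
    """
    span = _pump_span(params, params.u_q)
    base = 2.0 * req.nu_nadh + 2.0 * req.nu_fd
    atp_term = req.nu_atp * protons_per_atp(params) / span if req.nu_atp else 0.0
    nadh_up = (
        2.0 * req.nu_nadh
        * _ceil((params.u_q - params.u_nadh) / params.delta_u_membrane) / span
    )
    fd_up = (
        2.0 * req.nu_fd
        * _ceil((params.u_q - params.u_fd) / params.delta_u_membrane) / span
    )
    breakdown = {
        "base": base,
        "atp": atp_term,
        "nadh_uphill": nadh_up,
        "fd_uphill": fd_up,
    }
    return ElectronRequirement(base + atp_term + nadh_up + fd_up, "EEU", breakdown)


def electrons(
    req: CofactorRequirement,
    mediator: str,
    params: ElectronTransportParams = DEFAULT_PARAMS,
) -> ElectronRequirement:
    """Dispatch on mediator id ("H2" or "EEU")."""
    if mediator == "H2":
        return electrons_h2(req, params)
    if mediator == "EEU":
        return electrons_eeu(req, params)
    raise ValueError(f"unknown mediator {mediator!r}; expected 'H2' or 'EEU'")
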