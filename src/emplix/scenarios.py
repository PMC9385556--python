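"""Electrochemical production scenarios.

Four configurations are shipped, spanning the two electron-delivery
mechanisms (H2 oxidation vs extracellular electron uptake) with and without
an upstream abiotic CO2-to-formate cell:

* ``H2``          - single bio-cell, H2 mediation, enzymatic CO2 fixation
* ``EEU``         - single bio-cell, direct electron uptake
* ``H2+formate``  - dual cell: electrochemical formate, then H2-mediated assimilation
* ``EEU+formate`` - dual cell with EEU in the bio-cell

Total cell voltages are derived from the four component potentials using

    delta_u = (cathode_0 + cathode_bias) - anode_0 + anode_bias

and validated against this bookkeeping on load (0.01 V tolerance).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

_VOLTAGE_TOL = 0.01


@dataclass(frozen=True)
class EMPScenario:
    """One column of the production-parameter table."""

    id: str
    mediator: str  # "H2" or "EEU"
    fixation_route: str  # "enzymatic" or "electrochemical-formate"
    # bio-cell (cell 2)
    u_cell2_anode0: float
    u_cell2_anode_bias: float
    u_cell2_cathode0: float
    u_cell2_cathode_bias: float
    xi_i2: float
    # abiotic CO2-reduction cell (cell 1); None for single-cell scenarios
    u_cell1_cathode0: float | None = None
    u_cell1_cathode_bias: float | None = None
    u_cell1_anode0: float | None = None
    u_cell1_anode_bias: float | None = None
    xi_i1: float | None = None
    xi_c: float | None = None
    nu_cr: int | None = None  # carbons per primary fixation product
    nu_er: int | None = None  # electrons per primary fixation product
    # metadata only: solar input and usable electrical power
    p_solar: float = 1000.0
    p_electric: float = 330.0

    @property
    def delta_u_cell2(self) -> float:
        return (
            self.u_cell2_cathode0
            + self.u_cell2_cathode_bias
            - self.u_cell2_anode0
            + self.u_cell2_anode_bias
        )

    @property
    def delta_u_cell1(self) -> float | None:
        if self.u_cell1_cathode0 is None:
            return None
        return (
            self.u_cell1_cathode0
            + self.u_cell1_cathode_bias
            - self.u_cell1_anode0
            + self.u_cell1_anode_bias
        )

    @property
    def is_formate(self) -> bool:
        return self.fixation_route == "electrochemical-formate"

    def validate(self) -> None:
        for xi in (self.xi_i2, self.xi_i1, self.xi_c):
            if xi is not None and not 0 < xi <= 1:
                raise ValueError(f"{self.id}: Faradaic efficiency {xi} outside (0, 1]")
        # recompute the published totals from the component potentials
        expected = {"H2": 2.00, "EEU": 1.59, "H2+formate": 2.00, "EEU+formate": 1.59}
        if abs(self.delta_u_cell2 - expected[self.id]) > _VOLTAGE_TOL:
            raise ValueError(
                f"{self.id}: bio-cell voltage {self.delta_u_cell2:.3f} V does not "
                f"reproduce the tabulated {expected[self.id]} V"
            )
        if self.is_formate and abs(self.delta_u_cell1 - 3.02) > _VOLTAGE_TOL:
            raise ValueError(
                f"{self.id}: cell-1 voltage {self.delta_u_cell1:.3f} V != 3.02 V"
            )


def _load_all() -> dict[str, EMPScenario]:
    text = resources.files("emplix").joinpath("data/scenarios.toml").read_text()
    raw = tomllib.loads(text)
    out: dict[str, EMPScenario] = {}
    for sid, entry in raw.items():
        scn = EMPScenario(id=sid, **entry)
        scn.validate()
        out[sid] = scn
    return out


_SCENARIOS: dict[str, EMPScenario] | None = None


def scenario_registry() -> dict[str, EMPScenario]:
    global _SCENARIOS
    if _SCENARIOS is None:
        _SCENARIOS = _load_all()
    return dict(_SCENARIOS)


def load_scenario(sid: str) -> EMPScenario:
    """Return the named scenario; raises with the list of valid ids otherwise."""
    registry = scenario_registry()
    try:
        return registry[sid]
    except KeyError:
        raise KeyError(
            f"unknown scenario {sid!r}; valid ids: {sorted(registry)}"
        ) from None


def scenario_for(mediator: str, formate: bool = False) -> EMPScenario:
    """Convenience lookup by mediator ("H2"/"EEU") and formate flag."""
    sid = mediator + ("+formate" if formate else "")
    return load_scenario(sid)
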