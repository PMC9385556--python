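"""End-to-end reporting: sequestration costs and figure-style data tables.

Composes the demand model (lixiviant mass per tonne of CO2 at a given zeta)
with the production-cost model ($ per tonne of lixiviant) to give the
electricity cost of sequestering one tonne of CO2. Tables behind the three
headline figures are emitted as DataFrames with CSV/JSON writers.

The sequestration-cost default configuration is Calvin-cycle fixation with
H2 mediation (the "Bionic Leaf" arrangement); any other pathway/mediator
pair is selectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .costing import cost_table, energy_cost
from .lixiviants import get_lixiviant, lixiviant_registry
from .mineralization import (
    TONNE,
    carbon_mass_from_co2,
    fig_thresholds,
    lixiviant_mass,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequestrationCost:
    """Cost of enough lixiviant to sequester one tonne of CO2."""

    lixiviant: str
    pathway: str
    mediator: str
    zeta: float  # mol/g
    lixiviant_mass_per_tonne_co2: float  # grams of lixiviant per tonne CO2
    usd_per_tonne_lixiviant: float
    usd_per_tonne_co2: float


def sequestration_cost(
    lixiviant: str,
    pathway: str = "calvin",
    mediator: str = "H2",
    zeta: float = 2e-4,
    price: float | None = None,
) -> SequestrationCost:
    """Electricity cost ($/tCO2) of the lixiviant for one tonne of CO2."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    spec = get_lixiviant(lixiviant)
    m_c = carbon_mass_from_co2(TONNE)  # grams of C in one tonne of CO2
    mass_g = lixiviant_mass(m_c, spec, zeta)
    ec = energy_cost(lixiviant, pathway, mediator, price=price)
    usd = mass_g / TONNE * ec.cost_per_tonne
    log.info(
        "seqcost %s/%s/%s zeta=%.3g: %.1f kg lixiviant per tCO2 at $%.2f/t -> $%.2f/tCO2",
        lixiviant, pathway, mediator, zeta, mass_g / 1e3, ec.cost_per_tonne, usd,
    )
    return SequestrationCost(
        lixiviant=lixiviant,
        pathway=pathway,
        mediator=mediator,
        zeta=zeta,
        lixiviant_mass_per_tonne_co2=mass_g,
        usd_per_tonne_lixiviant=ec.cost_per_tonne,
        usd_per_tonne_co2=usd,
    )


def demand_table(
    m_co2: float = 20e15,
    lixiviant: str = "gluconic",
    zeta_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Lixiviant demand (Gt) vs zeta for a yearly CO2 target (default 20 Gt)."""
    if zeta_grid is None:
        zeta_grid = np.geomspace(1e-4, 2e-2, 60)
    m_c = carbon_mass_from_co2(m_co2)
    masses = [lixiviant_mass(m_c, lixiviant, z) / 1e15 for z in zeta_grid]
    return pd.DataFrame({"zeta": zeta_grid, "mass_gt": masses})


def seqcost_table(
    pathway: str = "calvin",
    mediator: str = "H2",
    zeta_grid: np.ndarray | None = None,
    price: float | None = None,
) -> pd.DataFrame:
    """$/tCO2 vs zeta for all four lixiviants at one production configuration."""
    if zeta_grid is None:
        zeta_grid = np.geomspace(1e-4, 2e-2, 60)
    rows = []
    for lix in lixiviant_registry():
        unit = sequestration_cost(lix, pathway, mediator, zeta=1e-4, price=price)
        # cost is linear in zeta; scale the unit result
        for z in zeta_grid:
            rows.append(
                {
                    "lixiviant": lix,
                    "zeta": z,
                    "usd_per_tonne_co2": unit.usd_per_tonne_co2 * (z / 1e-4),
                }
            )
    return pd.DataFrame(rows)


def figure_tables(which: str, **kwargs) -> pd.DataFrame:
    """Data behind the headline figures: 'demand', 'energy' or 'seqcost'.

    'demand'  - lixiviant mass vs zeta (with the six threshold annotations
                available via mineralization.fig_thresholds)
    'energy'  - the full production cost table over all configurations
    'seqcost' - $/tCO2 vs zeta for the four lixiviants
    """
    if which in ("demand", "fig3"):
        return demand_table(**kwargs)
    if which in ("energy", "fig4"):
        return cost_table(**kwargs)
    if which in ("seqcost", "fig5"):
        return seqcost_table(**kwargs)
    raise ValueError(f"unknown figure id {which!r}; use demand|energy|seqcost")


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write a CSV plus a JSON sidecar with run metadata."""
    path = Path(path)
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.json")
    payload = {"rows": int(len(frame)), "columns": list(frame.columns)}
    payload.update(metadata or {})
    sidecar.write_text(json.dumps(payload, indent=2, default=str))


def thresholds_sidecar() -> list[dict]:
    """The six zeta thresholds as JSON-ready records."""
    return [asdict(t) for t in fig_thresholds()]
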