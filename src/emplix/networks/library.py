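"""Shipped reaction networks: 7 fixation/assimilation routes x 4 lixiviants.

The six CO2-fixation routes are the Calvin cycle, the reductive TCA cycle,
the Wood-Ljungdahl pathway, the 3-hydroxypropionate/4-hydroxybutyrate
pathway, the 3-hydroxypropionate bicycle and the dicarboxylate/
4-hydroxybutyrate cycle; the seventh route is the synthetic formolase
formate-assimilation pathway (fed by an abiotic CO2-to-formate cell).

Network files live in ``emplix/data/networks`` and are regenerated by
``scripts/build_network_files.py``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .model import MetabolicNetwork
from .parser import parse_network

#: fixation/assimilation route ids, in rough order of increasing ATP cost
FIXATION_PATHWAYS = (
    "wood_ljungdahl",
    "rtca",
    "calvin",
    "hp_4hb",
    "hp",
    "fourhb",
    "formolase",
)

#: the six routes that draw carbon directly from CO2 (single-cell scenarios)
CO2_PATHWAYS = tuple(p for p in FIXATION_PATHWAYS if p != "formolase")

LIXIVIANT_IDS = ("acetic", "citric", "gluconic", "dkg")


@lru_cache(maxsize=None)
def shipped_network(pathway: str, lixiviant: str) -> MetabolicNetwork:
    """Load one shipped network by (pathway, lixiviant) id pair."""
    if pathway not in FIXATION_PATHWAYS:
        raise KeyError(
            f"unknown pathway {pathway!r}; known: {FIXATION_PATHWAYS}"
        )
    if lixiviant not in LIXIVIANT_IDS:
        raise KeyError(
            f"unknown lixiviant {lixiviant!r}; known: {LIXIVIANT_IDS}"
        )
    name = f"{pathway}__{lixiviant}.txt"
    text = resources.files("emplix").joinpath(f"data/networks/{name}").read_text()
    return parse_network(text, name=f"{pathway}__{lixiviant}")


def shipped_networks() -> dict[tuple[str, str], MetabolicNetwork]:
    """All 28 shipped networks keyed by (pathway id, lixiviant id)."""
    return {
        (p, l): shipped_network(p, l)
        for p in FIXATION_PATHWAYS
        for l in LIXIVIANT_IDS
    }
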