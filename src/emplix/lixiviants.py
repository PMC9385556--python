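"""Lixiviant registry.

The four candidate leaching acids (acetic, citric, gluconic and
2,5-diketo-gluconic) are shipped as a human-editable TOML file and validated
at load time: the stored molecular weight must agree with the weight
recomputed from the formula, and the degree of reduction must be a positive
integer equal to 4*nC + nH - 2*nO.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

from .constants import degree_of_reduction, molecular_weight

_MW_TOLERANCE = 0.05  # g/mol


@dataclass(frozen=True)
class LixiviantSpec:
    """One lixiviant acid: identity, formula, acidity and redox bookkeeping."""

    name: str
    formula: dict[str, int]
    mw: float  # g/mol
    pka: float
    metabolite: str  # id of the target species in the reaction networks

    @property
    def n_carbon(self) -> int:
        return int(self.formula.get("C", 0))

    @property
    def degree_of_reduction(self) -> int:
        gamma = degree_of_reduction(self.formula)
        return int(round(gamma))

    def validate(self) -> None:
        mw_calc = molecular_weight(self.formula)
        if abs(mw_calc - self.mw) > _MW_TOLERANCE:
            raise ValueError(
                f"{self.name}: stored MW {self.mw} differs from formula MW "
                f"{mw_calc:.3f} by more than {_MW_TOLERANCE} g/mol"
            )
        gamma = degree_of_reduction(self.formula)
        if gamma <= 0 or abs(gamma - round(gamma)) > 1e-9:
            raise ValueError(
                f"{self.name}: degree of reduction {gamma} is not a positive integer"
            )


def _load_registry() -> dict[str, LixiviantSpec]:
    text = resources.files("emplix").joinpath("data/lixiviants.toml").read_text()
    raw = tomllib.loads(text)
    registry: dict[str, LixiviantSpec] = {}
    for name, entry in raw.items():
        spec = LixiviantSpec(
            name=name,
            formula={k: int(v) for k, v in entry["formula"].items()},
            mw=float(entry["mw"]),
            pka=float(entry["pka"]),
            metabolite=str(entry["metabolite"]),
        )
        spec.validate()
        registry[name] = spec
    return registry


_REGISTRY: dict[str, LixiviantSpec] | None = None


def lixiviant_registry() -> dict[str, LixiviantSpec]:
    """All shipped lixiviants, keyed by id (acetic, citric, gluconic, dkg)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return dict(_REGISTRY)


def get_lixiviant(name: str) -> LixiviantSpec:
    registry = lixiviant_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown lixiviant {name!r}; known ids: {sorted(registry)}"
        ) from None
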