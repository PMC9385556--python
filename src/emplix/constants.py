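"""Physical constants and shared unit conversions.

All energies are in joules, potentials in volts, masses in grams unless a
function says otherwise. The electricity price default is the US DOE 2030
solar target of 3 cents per kWh.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Standard atomic masses (g/mol) for the elements tracked by the reaction files.
ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "P": 30.974,
    "S": 32.06,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used throughout the model."""

    faraday_constant: float = 96485.33212  # C per mole of electrons
    avogadro: float = 6.02214076e23  # 1/mol
    elementary_charge: float = 1.602176634e-19  # C
    kwh_in_joules: float = 3.6e6  # J
    electricity_price: float = 0.03  # $ per kWh

    def validate(self) -> None:
        """F must equal N_A * e to numerical precision."""
        derived = self.avogadro * self.elementary_charge
        rel = abs(derived - self.faraday_constant) / self.faraday_constant
        if rel > 1e-6:
            raise ValueError(
                f"faraday_constant inconsistent with N_A*e (rel err {rel:.2e})"
            )


CONSTANTS = PhysicalConstants()
CONSTANTS.validate()

F = CONSTANTS.faraday_constant
N_A = CONSTANTS.avogadro
E_CHARGE = CONSTANTS.elementary_charge


def molecular_weight(formula: dict[str, int | float]) -> float:
    """Molecular weight (g/mol) from an element->count map."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def degree_of_reduction(formula: dict[str, int | float]) -> float:
    """Available electrons per molecule relative to the CO2/H2O reference.

    For C,H,O(,N) compounds: 4*nC + nH - 2*nO (- 3*nN). This is the number
    of electrons released on complete combustion to CO2 and H2O and hence
    the minimum number of carrier electrons needed to build the molecule
    from CO2.
    """
    gamma = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "P": 5.0, "S": 6.0}
    return sum(gamma[el] * n for el, n in formula.items())
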