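"""pH of mono-protic weak-acid lixiviant solutions.

From Ka = [H+][B-]/[HB] with [H+] = [B-] and [HB] = C - x, the proton
concentration is the positive root of x^2 + Ka*x - C*Ka = 0. The quadratic
is evaluated in the conjugate (cancellation-free) form

    x = 2*C*Ka / (Ka + sqrt(Ka^2 + 4*C*Ka))

Water autoionization is neglected, so results below [H+] ~ 1e-6 M are
flagged unreliable. Citric acid is treated mono-protically with its first
pKa only — a documented simplification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .lixiviants import get_lixiviant

_RELIABLE_MIN_H = 1e-6  # mol/L


@dataclass(frozen=True)
class AcidSolution:
    pka: float
    concentration: float  # analytical concentration C, mol/L
    proton_conc: float  # x = [H+], mol/L
    ph: float
    reliable: bool  # False when [H+] approaches the autoionization scale

    def residual(self) -> float:
        """Relative residual of x^2 + Ka x - C Ka = 0 at the solved root."""
        ka = 10.0 ** (-self.pka)
        x = self.proton_conc
        return (x * x + ka * x - self.concentration * ka) / (self.concentration * ka)


def proton_concentration(pka: float, concentration: float) -> float:
    """Positive root of the weak-acid quadratic, numerically stable form."""
    if concentration <= 0:
        raise ValueError("analytical concentration must be positive")
    if not 0 < pka < 14:
        raise ValueError("pKa must lie in (0, 14)")
    ka = 10.0 ** (-pka)
    return 2.0 * concentration * ka / (ka + math.sqrt(ka * ka + 4.0 * concentration * ka))


def ph_weak_acid(pka: float, concentration: float) -> float:
    """pH of a mono-protic weak acid at analytical concentration C (mol/L)."""
    x = proton_concentration(pka, concentration)
    if x < _RELIABLE_MIN_H:
        warnings.warn(
            "computed [H+] below 1e-6 M; water autoionization neglected, "
            "result unreliable",
            stacklevel=2,
        )
    return -math.log10(x)


def solve_acid(pka: float, concentration: float) -> AcidSolution:
    """Full solution record for one acid/concentration pair."""
    x = proton_concentration(pka, concentration)
    return AcidSolution(
        pka=pka,
        concentration=concentration,
        proton_conc=x,
        ph=-math.log10(x),
        reliable=x >= _RELIABLE_MIN_H,
    )


def lixiviant_ph(name: str, concentration: float = 0.1) -> float:
    """pH of a registered lixiviant at the given concentration (default 100 mM)."""
    return ph_weak_acid(get_lixiviant(name).pka, concentration)
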