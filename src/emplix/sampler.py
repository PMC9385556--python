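"""Scenario sampler for the mineralization parameter space.

Stands in for the supplementary parameter-combination tables: draws
(c_lix, eta_ex, eta_precip, rho_pulp) scenarios over stated ranges, and
enumerates multiplier combinations of the optimistic point that achieve a
target zeta. Efficiencies and lixiviant concentration are sampled uniformly
on a linear scale; pulp density log-uniformly (zeta spans orders of
magnitude). Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .mineralization import MineralizationScenario

DEFAULT_RANGES = {
    "c_lix": (100.0, 600.0),  # mol/m^3
    "eta_ex": (0.2, 1.0),
    "eta_precip": (0.2, 1.0),
    "pulp_density": (1e5, 5e5),  # g/m^3
    "delta_u_membrane": (0.08, 0.27),  # V; carried for joint sweeps
}

OPTIMISTIC = {
    "c_lix": 100.0,
    "eta_ex": 1.0,
    "eta_precip": 1.0,
    "pulp_density": 5e5,
}


@dataclass(frozen=True)
class SamplerConfig:
    n_draws: int = 100
    seed: int = 0
    mode: str = "random"  # random | grid
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def validate(self) -> None:
        if self.n_draws < 0:
            raise ValueError("n_draws must be nonnegative")
        if self.mode not in ("random", "grid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for key, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {key} must satisfy lo < hi, got {lo}, {hi}")


def sample_scenarios(config: SamplerConfig) -> list[MineralizationScenario]:
    """Draw n_draws mineralization scenarios, reproducibly under a fixed seed."""
    config.validate()
    if config.n_draws == 0:
        return []
    r = config.ranges
    if config.mode == "grid":
        per_axis = max(2, round(config.n_draws ** 0.25))
        axes = [
            np.linspace(*r["c_lix"], per_axis),
            np.linspace(*r["eta_ex"], per_axis),
            np.linspace(*r["eta_precip"], per_axis),
            np.geomspace(*r["pulp_density"], per_axis),
        ]
        combos = list(product(*axes))[: config.n_draws]
        return [MineralizationScenario(*combo) for combo in combos]
    rng = np.random.default_rng(config.seed)
    c = rng.uniform(*r["c_lix"], config.n_draws)
    ex = rng.uniform(*r["eta_ex"], config.n_draws)
    pr = rng.uniform(*r["eta_precip"], config.n_draws)
    lo, hi = r["pulp_density"]
    rho = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_draws))
    return [
        MineralizationScenario(c[i], ex[i], pr[i], rho[i])
        for i in range(config.n_draws)
    ]


def scenarios_frame(scenarios: list[MineralizationScenario]) -> pd.DataFrame:
    """Tabulate scenarios with their derived zeta (mol/g)."""
    return pd.DataFrame(
        {
            "c_lix": [s.c_lix for s in scenarios],
            "eta_ex": [s.eta_ex for s in scenarios],
            "eta_precip": [s.eta_precip for s in scenarios],
            "pulp_density": [s.pulp_density for s in scenarios],
            "zeta": [s.zeta for s in scenarios],
        }
    )


DEFAULT_MULTIPLIERS = {
    # factors applied to the optimistic point, echoing the worked patterns
    # (x5 concentration, halvings, thirds, quarters, small percent shifts)
    "c_lix": (1.0, 1.03, 1.1, 1.5, 2.0, 2.8, 3.0, 4.0, 5.3),
    "eta_ex": (1.0, 0.97, 0.9, 2 / 3, 0.5, 1 / 3, 0.25, 0.2),
    "eta_precip": (1.0, 0.97, 0.9, 2 / 3, 0.5, 1 / 3, 0.25, 0.2),
    "pulp_density": (1.0, 0.97, 0.9, 2 / 3, 0.5, 1 / 3, 0.25, 0.2),
}


def combinations_for_zeta(
    target_zeta: float,
    multipliers: dict | None = None,
    rel_tol: float = 0.05,
) -> pd.DataFrame:
    """Multiplier combinations of the optimistic point that reach a target zeta.

    Returns every grid combination whose zeta lies within rel_tol of the
    target (5% by default, matching the source's "approximately" language).
    An empty result is a warning case, not an error — widen the grid or the
    tolerance.
    """
    if target_zeta <= 0:
        raise ValueError("target_zeta must be positive")
    multipliers = multipliers or DEFAULT_MULTIPLIERS
    rows = []
    for mc, me, mp, mr in product(
        multipliers["c_lix"],
        multipliers["eta_ex"],
        multipliers["eta_precip"],
        multipliers["pulp_density"],
    ):
        scn = MineralizationScenario(
            c_lix=OPTIMISTIC["c_lix"] * mc,
            eta_ex=min(1.0, OPTIMISTIC["eta_ex"] * me),
            eta_precip=min(1.0, OPTIMISTIC["eta_precip"] * mp),
            pulp_density=OPTIMISTIC["pulp_density"] * mr,
        )
        if abs(scn.zeta - target_zeta) / target_zeta <= rel_tol:
            rows.append(
                {
                    "c_lix": scn.c_lix,
                    "eta_ex": scn.eta_ex,
                    "eta_precip": scn.eta_precip,
                    "pulp_density": scn.pulp_density,
                    "zeta": scn.zeta,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["c_lix", "eta_ex", "eta_precip", "pulp_density", "zeta"]
    )
    return frame.drop_duplicates().reset_index(drop=True)
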