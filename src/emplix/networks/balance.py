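"""Flux balancing of lixiviant synthesis networks.

The problem is tiny (tens of reactions) and linear: find reaction fluxes v
such that every internal metabolite is exactly mass-balanced and one unit of
the target lixiviant is exported. Exchange species (carbon source, water,
O2 and the carrier pairs) are given free import/export variables whose
solved values are the per-molecule cofactor requirements.

Degenerate solution spaces are resolved deterministically by a lexicographic
linear program: minimize total ATP import, then NAD(P)H import, then the
L1 norm of the flux vector (which removes futile cycles).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linprog

from .model import CofactorRequirement, MetabolicNetwork

log = logging.getLogger(__name__)

_BOUND = 1e4
_TOL = 1e-9


class BalanceError(ValueError):
    """Raised when a network cannot produce its target."""


def _solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    return res


def stoichiometric_matrix(network: MetabolicNetwork) -> tuple[np.ndarray, list[str]]:
    """Dense S (metabolites x reactions) and the metabolite row order."""
    mets = network.metabolites
    index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.stoich.items():
            S[index[met], j] = float(coeff)
    return S, mets


def balance(
    network: MetabolicNetwork,
) -> tuple[dict[str, float], CofactorRequirement]:
    """Balance the network for one unit of target.

    Returns the reaction->flux map and the clamped cofactor requirement.
    Raises :class:`BalanceError` naming the unbalanceable metabolites when
    the target cannot be produced.
    """
    network.validate()
    S, mets = stoichiometric_matrix(network)
    n_rxn = S.shape[1]
    exchange = [m for m in mets if m in network.exchange_species]
    n_exch = len(exchange)

    # Columns: reaction fluxes, then import fluxes for exchange species.
    # Mass balance: S.v + x_import = 0 for exchange rows, S.v = 0 internal,
    # S.v = +1 for the target row.
    A_eq = np.zeros((len(mets), n_rxn + n_exch))
    A_eq[:, :n_rxn] = S
    b_eq = np.zeros(len(mets))
    for k, m in enumerate(exchange):
        A_eq[mets.index(m), n_rxn + k] = 1.0
    b_eq[mets.index(network.target)] = 1.0

    bounds = [
        (None, _BOUND) if rxn.reversible else (0.0, _BOUND)
        for rxn in network.reactions
    ] + [(None, None)] * n_exch
    for j, rxn in enumerate(network.reactions):
        if rxn.reversible:
            bounds[j] = (-_BOUND, _BOUND)

    def import_objective(species: str) -> np.ndarray:
        c = np.zeros(n_rxn + n_exch)
        if species in exchange:
            c[n_rxn + exchange.index(species)] = 1.0
        return c

    # stage 1: minimize net ATP import
    c1 = import_objective("atp")
    res = _solve_lp(c1, A_eq, b_eq, None, None, bounds)
    if res.status != 0:
        raise BalanceError(_diagnose(network, S, mets))
    atp_opt = float(c1 @ res.x)

    # stage 2: minimize net NAD(P)H import with ATP fixed
    c2 = import_objective("nadh")
    A2 = np.vstack([A_eq, c1])
    b2 = np.append(b_eq, atp_opt)
    res = _solve_lp(c2, A2, b2, None, None, bounds)
    if res.status != 0:  # pragma: no cover - stage 1 feasible implies this is
        raise BalanceError(f"{network.name}: stage-2 LP failed: {res.message}")
    nadh_opt = float(c2 @ res.x)

    # stage 3: minimize L1 flux norm (removes futile cycles, deterministic)
    n = n_rxn + n_exch
    c3 = np.concatenate([np.zeros(n), np.ones(n_rxn)])
    A3_eq = np.hstack([np.vstack([A_eq, c1, c2]), np.zeros((len(mets) + 2, n_rxn))])
    b3_eq = np.concatenate([b_eq, [atp_opt, nadh_opt]])
    # t_j >= |v_j|
    A_ub = np.zeros((2 * n_rxn, n + n_rxn))
    for j in range(n_rxn):
        A_ub[2 * j, j] = 1.0
        A_ub[2 * j, n + j] = -1.0
        A_ub[2 * j + 1, j] = -1.0
        A_ub[2 * j + 1, n + j] = -1.0
    b_ub = np.zeros(2 * n_rxn)
    bounds3 = bounds + [(0.0, _BOUND)] * n_rxn
    res = _solve_lp(c3, A3_eq, b3_eq, A_ub, b_ub, bounds3)
    if res.status != 0:  # pragma: no cover
        raise BalanceError(f"{network.name}: stage-3 LP failed: {res.message}")
    v = res.x[:n_rxn]
    x = res.x[n_rxn : n_rxn + n_exch]

    # verify the balance residual
    resid = S @ v
    for i, m in enumerate(mets):
        expected = 1.0 if m == network.target else 0.0
        if m in network.exchange_species:
            continue
        if abs(resid[i] - expected) > 1e-7:
            raise BalanceError(
                f"{network.name}: residual {resid[i]:.2e} on metabolite {m!r}"
            )
    for j, rxn in enumerate(network.reactions):
        if not rxn.reversible and v[j] < -1e-8:
            raise BalanceError(f"{network.name}: negative flux on irreversible {rxn.id}")

    dof = n_rxn - np.linalg.matrix_rank(S[[mets.index(m) for m in
          network.internal_metabolites + [network.target]], :])
    if dof > 0:
        log.warning(
            "%s: flux solution space has %d degrees of freedom; "
            "lexicographic min-ATP/min-NADH/min-|v| selection applied",
            network.name, dof,
        )

    imports = {m: float(x[k]) for k, m in enumerate(exchange)}
    raw_nadh = imports.get("nadh", 0.0)
    raw_fd = imports.get("fdred", 0.0)
    raw_atp = imports.get("atp", 0.0)
    if network.carbon_source == "formate":
        nu_r = imports.get("formate", 0.0)
        carbon_in = nu_r + imports.get("co2", 0.0)
    else:
        nu_r = 0.0
        carbon_in = imports.get("co2", 0.0)

    def _clean(value: float) -> float:
        return 0.0 if abs(value) < _TOL * 10 else round(value, 9)

    req = CofactorRequirement(
        nu_nadh=max(0.0, _clean(raw_nadh)),
        nu_fd=max(0.0, _clean(raw_fd)),
        nu_atp=max(0.0, _clean(raw_atp)),
        nu_r=_clean(nu_r),
        carbon_in=_clean(carbon_in),
        raw_nadh=_clean(raw_nadh),
        raw_fd=_clean(raw_fd),
        raw_atp=_clean(raw_atp),
    )
    req.validate()
    flux = {rxn.id: float(round(v[j], 9)) for j, rxn in enumerate(network.reactions)}
    return flux, req


def _diagnose(network: MetabolicNetwork, S: np.ndarray, mets: list[str]) -> str:
    """Least-squares diagnosis of which internal metabolites cannot balance."""
    rows = [mets.index(m) for m in network.internal_metabolites]
    rows.append(mets.index(network.target))
    A = S[rows, :]
    b = np.zeros(len(rows))
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ sol - b
    labels = network.internal_metabolites + [network.target]
    bad = [labels[i] for i in range(len(labels)) if abs(resid[i]) > 1e-6]
    return (
        f"{network.name}: infeasible — cannot balance metabolite(s) "
        f"{bad or '<bounds/irreversibility>'} while producing {network.target}"
    )
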