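"""Plain-text reaction file format.

One network per file. Grammar::

    # free comment
    @name        wl__acetic
    @pathway     wood_ljungdahl
    @lixiviant   acetic
    @source      co2
    @target      acetate
    @exchange    co2 h2o o2 nadh nad fdred fdox atp adp
    ! acetate    C2H4O2
    ! co2        CO2
    fdh: co2 + nadh -> formate + nad
    mtb: formate + 2 nadh + atp -> ch3x + 2 nad + adp + h2o
    eno: pg3 <-> pep + h2o

``!`` lines declare metabolite formulas (C/H/O Hill-style strings, carriers
may be empty: ``! nad .``). ``->`` marks irreversible, ``<->`` reversible
reactions. Coefficients may be integers, decimals or fractions (``3/2``).
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path

from .model import MetabolicNetwork, Reaction

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse 'C6H12O7' into {'C': 6, 'H': 12, 'O': 7}; '.' means empty."""
    text = text.strip()
    if text in (".", ""):
        return {}
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        raise ValueError(f"malformed formula {text!r}")
    out: dict[str, int] = {}
    for el, num in _FORMULA_RE.findall(text):
        if el:
            out[el] = out.get(el, 0) + (int(num) if num else 1)
    return out


def format_formula(formula: dict[str, int]) -> str:
    if not formula:
        return "."
    order = ["C", "H", "O"] + sorted(set(formula) - {"C", "H", "O"})
    return "".join(
        f"{el}{formula[el] if formula[el] != 1 else ''}"
        for el in order
        if el in formula and formula[el]
    )


def _parse_side(side: str, sign: int, stoich: dict[str, Fraction]) -> None:
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ValueError(f"empty term in reaction side {side!r}")
        parts = term.split()
        if len(parts) == 1:
            coeff, met = Fraction(1), parts[0]
        elif len(parts) == 2:
            coeff, met = Fraction(parts[0]), parts[1]
        else:
            raise ValueError(f"malformed term {term!r}")
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff
        if stoich[met] == 0:
            del stoich[met]


def parse_reaction(line: str) -> Reaction:
    """Parse 'id: A + 2 B -> C' (or '<->' for reversible)."""
    if ":" not in line:
        raise ValueError(f"reaction line missing 'id:': {line!r}")
    rid, _, body = line.partition(":")
    reversible = "<->" in body
    arrow = "<->" if reversible else "->"
    if arrow not in body:
        raise ValueError(f"reaction {rid!r}: no arrow in {body!r}")
    lhs, _, rhs = body.partition(arrow)
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    return Reaction(id=rid.strip(), stoich=stoich, reversible=reversible)


def format_reaction(rxn: Reaction) -> str:
    def side(sign: int) -> str:
        terms = []
        for met, coeff in rxn.stoich.items():
            if (coeff < 0) == (sign < 0) and coeff != 0:
                c = abs(coeff)
                terms.append(met if c == 1 else f"{c} {met}")
        return " + ".join(terms)

    arrow = "<->" if rxn.reversible else "->"
    return f"{rxn.id}: {side(-1)} {arrow} {side(+1)}"


def parse_network(text: str, name: str = "") -> MetabolicNetwork:
    meta: dict[str, str] = {}
    formulas: dict[str, dict[str, int]] = {}
    reactions: list[Reaction] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            key, _, value = line[1:].partition(" ")
            meta[key.strip()] = value.strip()
        elif line.startswith("!"):
            parts = line[1:].split()
            if len(parts) == 1:
                formulas[parts[0]] = {}
            elif len(parts) == 2:
                formulas[parts[0]] = parse_formula(parts[1])
            else:
                raise ValueError(f"malformed formula line {raw!r}")
        else:
            reactions.append(parse_reaction(line))
    for key in ("target", "source", "exchange"):
        if key not in meta:
            raise ValueError(f"network file missing @{key} header")
    net = MetabolicNetwork(
        name=meta.get("name", name),
        reactions=reactions,
        exchange_species=set(meta["exchange"].split()),
        target=meta["target"],
        carbon_source=meta["source"],
        formulas=formulas,
        pathway=meta.get("pathway", ""),
        lixiviant=meta.get("lixiviant", ""),
    )
    net.validate()
    return net


def read_network(path: str | Path) -> MetabolicNetwork:
    path = Path(path)
    return parse_network(path.read_text(), name=path.stem)


def write_network(network: MetabolicNetwork, path: str | Path | None = None) -> str:
    """Serialize a network; returns the text and optionally writes it."""
    lines = [
        f"@name      {network.name}",
        f"@pathway   {network.pathway}",
        f"@lixiviant {network.lixiviant}",
        f"@source    {network.carbon_source}",
        f"@target    {network.target}",
        f"@exchange  {' '.join(sorted(network.exchange_species))}",
    ]
    for met in network.metabolites:
        lines.append(f"! {met:<12} {format_formula(network.formulas.get(met, {}))}")
    for rxn in network.reactions:
        lines.append(format_reaction(rxn))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
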