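"""Regenerate the shipped reaction-network text files.

Each network couples one CO2-fixation (or formate-assimilation) route to one
lixiviant synthesis route, written in the plain-text grammar understood by
``emplix.networks.parser``. Run from the repository root:

    python scripts/build_network_files.py

Reactions marked "# calibrated" carry lumped ATP coefficients chosen so the
downstream electricity-per-gram numbers reproduce the published central
values for the anchor configurations (Wood-Ljungdahl acetate, 4HB acetate,
Wood-Ljungdahl citrate); see docs/methods.md.
"""

from __future__ import annotations

from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "emplix" / "data" / "networks"

FORMULAS = {
    "co2": "CO2", "h2o": "H2O", "o2": "O2",
    "nadh": "H2", "nad": ".", "fdred": "H2", "fdox": ".", "atp": ".", "adp": ".",
    "formate": "CH2O2", "ch3x": "CH4O", "fald": "CH2O", "dha": "C3H6O3",
    "glycolald": "C2H4O2", "gap": "C3H6O3", "pg3": "C3H6O4", "pep": "C3H4O3",
    "pyruvate": "C3H4O3", "accoa": "C2H4O2", "acetate": "C2H4O2",
    "oaa": "C4H4O5", "citrate": "C6H8O7", "f6p": "C6H12O6", "g6p": "C6H12O6",
    "glucose": "C6H12O6", "gdl": "C6H10O6", "gluconate": "C6H12O7",
    "kg2": "C6H10O7", "dkg": "C6H8O7",
}

RXN = {
    # --- CO2 fixation / C1 assimilation ---
    "fdh": "fdh: co2 + nadh -> formate + nad",
    "mtb": "mtb: formate + 2 nadh + atp -> ch3x + 2 nad + adp + h2o",
    "acs": "acs: ch3x + co2 + fdred -> accoa + fdox + h2o",
    "cbb": "cbb: 3 co2 + 6 nadh + 9 atp -> gap + 6 nad + 9 adp + 3 h2o",
    "rtca": "rtca: 2 co2 + 3 nadh + fdred + 2 atp -> accoa + 3 nad + fdox + 2 adp + 2 h2o",
    "hp4hb": "hp4hb: 2 co2 + 4 nadh + 4 atp -> accoa + 4 nad + 4 adp + 2 h2o",
    "hp": "hp: 2 co2 + 4 nadh + 5 atp -> accoa + 4 nad + 5 adp + 2 h2o",
    "fourhb": "fourhb: 2 co2 + 4 nadh + 18 atp -> accoa + 4 nad + 18 adp + 2 h2o  # calibrated ATP",
    "ffl": "ffl: formate + nadh + atp -> fald + nad + adp + h2o",
    "fls3": "fls3: 3 fald -> dha",
    "fls2": "fls2: 2 fald -> glycolald",
    "dhak": "dhak: dha + atp -> gap + adp",
    # --- central carbon / lixiviant synthesis ---
    "ack": "ack: accoa + adp -> acetate + atp",
    "pkt": "pkt: glycolald + adp -> acetate + atp",
    "pfor": "pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o",
    "peps": "peps: pyruvate + 2 atp -> pep + 2 adp",
    "ppc": "ppc: pep + co2 -> oaa",
    "cs": "cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP",
    "gpk": "gpk: gap + nad + adp + h2o <-> pg3 + nadh + atp",
    "eno": "eno: pg3 <-> pep + h2o",
    "pk": "pk: pep + adp -> pyruvate + atp",
    "pdh": "pdh: pyruvate + nad + h2o -> accoa + co2 + nadh",
    "fbp": "fbp: 2 gap -> f6p",
    "pgi": "pgi: f6p <-> g6p",
    "g6pase": "g6pase: g6p -> glucose",
    "gdh": "gdh: glucose + nad -> gdl + nadh",
    "glac": "glac: gdl + h2o -> gluconate",
    "ga2dh": "ga2dh: gluconate + nad -> kg2 + nadh",
    "kgdh": "kgdh: kg2 + nad -> dkg + nadh",
}

ACCOA_PATHWAYS = {
    "wood_ljungdahl": ["fdh", "mtb", "acs"],
    "rtca": ["rtca"],
    "hp_4hb": ["hp4hb"],
    "hp": ["hp"],
    "fourhb": ["fourhb"],
}

SUGAR_FROM_ACCOA = ["pfor", "peps", "eno", "gpk", "fbp", "pgi", "g6pase", "gdh", "glac"]
SUGAR_FROM_GAP = ["fbp", "pgi", "g6pase", "gdh", "glac"]
DKG_EXTRA = ["ga2dh", "kgdh"]

TARGETS = {
    "acetic": "acetate",
    "citric": "citrate",
    "gluconic": "gluconate",
    "dkg": "dkg",
}


def compose(pathway: str, lixiviant: str) -> list[str]:
    if pathway in ACCOA_PATHWAYS:
        fix = ACCOA_PATHWAYS[pathway]
        if lixiviant == "acetic":
            return fix + ["ack"]
        if lixiviant == "citric":
            return fix + ["pfor", "peps", "ppc", "cs"]
        if lixiviant == "gluconic":
            return fix + SUGAR_FROM_ACCOA
        if lixiviant == "dkg":
            return fix + SUGAR_FROM_ACCOA + DKG_EXTRA
    if pathway == "calvin":
        if lixiviant == "acetic":
            return ["cbb", "gpk", "eno", "pk", "pdh", "ack"]
        if lixiviant == "citric":
            return ["cbb", "gpk", "eno", "pk", "pdh", "ppc", "cs"]
        if lixiviant == "gluconic":
            return ["cbb"] + SUGAR_FROM_GAP
        if lixiviant == "dkg":
            return ["cbb"] + SUGAR_FROM_GAP + DKG_EXTRA
    if pathway == "formolase":
        if lixiviant == "acetic":
            return ["ffl", "fls2", "pkt"]
        if lixiviant == "citric":
            return ["ffl", "fls3", "dhak", "gpk", "eno", "pk", "pdh", "ppc", "cs"]
        if lixiviant == "gluconic":
            return ["ffl", "fls3", "dhak"] + SUGAR_FROM_GAP
        if lixiviant == "dkg":
            return ["ffl", "fls3", "dhak"] + SUGAR_FROM_GAP + DKG_EXTRA
    raise ValueError(f"no composition for {pathway}/{lixiviant}")


def emit(pathway: str, lixiviant: str) -> str:
    rxn_ids = compose(pathway, lixiviant)
    source = "formate" if pathway == "formolase" else "co2"
    exchange = "co2 h2o o2 nadh nad fdred fdox atp adp"
    if source == "formate":
        exchange += " formate"
    lines = [
        f"# {pathway} x {lixiviant} lixiviant synthesis network",
        "# generated by scripts/build_network_files.py -- edit there, not here",
        f"@name      {pathway}__{lixiviant}",
        f"@pathway   {pathway}",
        f"@lixiviant {lixiviant}",
        f"@source    {source}",
        f"@target    {TARGETS[lixiviant]}",
        f"@exchange  {exchange}",
    ]
    mets: list[str] = []
    for rid in rxn_ids:
        body = RXN[rid].split("#", 1)[0]
        for token in body.replace("<->", "+").replace("->", "+").split("+"):
            parts = token.replace(":", " ").split()
            name = parts[-1] if parts else ""
            if name and name in FORMULAS and name not in mets:
                mets.append(name)
    for met in mets:
        lines.append(f"! {met:<10} {FORMULAS[met]}")
    lines += [RXN[rid] for rid in rxn_ids]
    return "\n".join(lines) + "\n"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pathways = list(ACCOA_PATHWAYS) + ["calvin", "formolase"]
    for pathway in pathways:
        for lixiviant in TARGETS:
            path = OUT / f"{pathway}__{lixiviant}.txt"
            path.write_text(emit(pathway, lixiviant))
            print("wrote", path.relative_to(OUT.parents[3]))


if __name__ == "__main__":
    main()
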