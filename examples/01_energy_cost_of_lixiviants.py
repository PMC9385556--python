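"""Electricity cost of producing each lixiviant, over every configuration.

Balances each CO2-fixation x lixiviant reaction network, converts the
cofactor demand to electrons for both delivery mechanisms, and prints the
kJ/g and $/tonne table with its membrane-potential uncertainty band.
"""

from emplix.costing import cost_table

table = cost_table()
print(table.round(2).to_string(index=False))

best = table.loc[table.kj_per_g.idxmin()]
worst = table.loc[table.kj_per_g.idxmax()]
print(
    f"\nCheapest: {best.lixiviant} via {best.pathway} + {best.mediator} at "
    f"{best.kj_per_g:.1f} kJ/g (${best.usd_per_tonne:.0f}/t at 3 cents/kWh)."
)
print(
    f"Most expensive: {worst.lixiviant} via {worst.pathway} + {worst.mediator} "
    f"at {worst.kj_per_g:.1f} kJ/g (${worst.usd_per_tonne:.0f}/t)."
)
print(
    "\nkj_per_g_lo/hi span membrane potentials of 80-240 mV; a zero-width "
    "band means the pathway is ATP-neutral, so the proton bookkeeping drops out."
)
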