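"""Balance one reaction network and inspect the overall stoichiometry.

Loads the Wood-Ljungdahl -> acetate network, solves the flux balance for
one acetate exported, and shows the per-molecule cofactor demand that feeds
the bioenergetic model.
"""

from emplix.bioenergetics import electrons_eeu, electrons_h2
from emplix.networks import balance, shipped_network, write_network

net = shipped_network("wood_ljungdahl", "acetic")
print(write_network(net))

flux, req = balance(net)
print("reaction fluxes per acetate:")
for rid, v in flux.items():
    print(f"  {rid:6s} {v:6.3f}")
print(
    f"\ncofactor demand: {req.nu_nadh:g} NAD(P)H, {req.nu_fd:g} Fd_red, "
    f"{req.nu_atp:g} ATP per acetate ({req.carbon_in:g} CO2 fixed)"
)
print(
    f"electrons per acetate: {electrons_h2(req).nu_e:g} (H2 delivery), "
    f"{electrons_eeu(req).nu_e:g} (extracellular uptake)"
)
print(
    "\nAcetogenesis is ATP-neutral here (formyl-THF activation repaid by "
    "acetate kinase), so the 8 carrier electrons are the whole bill under H2."
)
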