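# emplix

Techno-economic and bioenergetic model of **electromicrobially produced
lixiviants for CO₂ mineralization**.

Weathering ultramafic rock (forsterite, Mg₂SiO₄) locks atmospheric CO₂ into
stable carbonates, but the dissolution step is slow unless helped by a
leaching acid (*lixiviant*). Producing those acids from plant biomass could
monopolize the world's biomass supply; producing them electromicrobially —
feeding renewable electrons into engineered CO₂-fixing microbes — could not.
`emplix` is the desk-scale model chain that quantifies this trade-off for
four candidate acids (acetic, citric, gluconic, 2,5-diketo-gluconic):

1. **Reaction networks** (`emplix.networks`): 7 CO₂-fixation /
   formate-assimilation routes × 4 acids, shipped as plain-text reaction
   files and balanced by a small lexicographic LP to give the NAD(P)H,
   reduced-ferredoxin and ATP demand per molecule, with carbon and
   degree-of-reduction conservation enforced.
2. **Bioenergetics** (`emplix.bioenergetics`): electrons per molecule.
   For H₂-mediated delivery

   ν_e = 2ν_NADH + 2ν_Fd + ν_ATP · ⌈ΔG_ATP/(F·ΔU_m)⌉ / ⌊(U_acc − U_H2)/ΔU_m⌋

   and for extracellular electron uptake (EEU) the electrons enter at the
   quinone level, so reverse electron transport adds
   2ν_carrier·⌈(U_Q − U_carrier)/ΔU_m⌉ pumped protons per carrier, paid for
   by electrons falling through the span ⌊(U_acc − U_Q)/ΔU_m⌋.
3. **Costing** (`emplix.costing`): C_E = F·ΔU_cell·ν_e/(MW·ξ_I2) J/g for
   single-cell systems, the two-cell charge accounting for the
   electrochemical-formate route, and $/tonne at a configurable electricity
   price (default: 3 ¢/kWh).
4. **Mineralization demand** (`emplix.mineralization`): M_lix = M_C ·
   MW_forsterite · MW_lix · ζ / (MW_C · n_C), where
   ζ = c_lix/(η_ex·η_precip·ρ_pulp) aggregates the four highly uncertain
   process parameters.
5. **Acid chemistry, sampling, reporting**: mono-protic weak-acid pH,
   seeded scenario draws over the uncertain parameters, and composed
   $/tonne-CO₂ tables.

## Worked example

```python
>>> from emplix import shipped_network, balance, electrons_h2, energy_cost
>>> net = shipped_network("wood_ljungdahl", "acetic")
>>> flux, req = balance(net)
>>> (req.nu_nadh, req.nu_fd, req.nu_atp)
(3.0, 1.0, 0.0)
>>> electrons_h2(req).nu_e
8.0
>>> ec = energy_cost("acetic", "wood_ljungdahl", "H2")
>>> round(ec.e_per_gram / 1e3, 1), round(ec.cost_per_tonne)
(25.7, 214)
```

Acetogenesis via the Wood-Ljungdahl pathway needs 4 carrier pairs
(8 electrons, exactly acetate's degree of reduction) and no net ATP, so a
2.0 V bio-cell spends 25.7 kJ per gram of acetic acid — $214/tonne at
3 ¢/kWh, independent of the membrane potential. Composing with the demand
model:

```python
>>> from emplix import sequestration_cost
>>> sc = sequestration_cost("gluconic", "calvin", "H2", zeta=2e-4)
>>> round(sc.lixiviant_mass_per_tonne_co2 / 1e3, 1), round(sc.usd_per_tonne_co2)
(62.7, 16)
```

i.e. at the optimistic mineralization performance (100 mM acid, perfect
extraction and precipitation, 50% w/v pulp density), sequestering a tonne
of CO₂ takes ~63 kg of gluconic acid and ~$16 of electricity.

The `examples/` directory holds one narrative script per capability
(`python examples/01_energy_cost_of_lixiviants.py`, …).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the model's headline quantities end-to-end — per-gram
electricity costs for the anchor configurations and the table-wide minimum,
the gigatonne-scale gluconic-acid demand, the three 100 mM pH values, and
the composed $/tonne-CO₂ at two mineralization performances — and writes
them as JSON keyed by target id.

## Layout

```
src/emplix/            the library (constants, lixiviants, scenarios,
                       networks/, bioenergetics, costing, mineralization,
                       acids, sampler, reporting)
src/emplix/data/       lixiviant + scenario TOML, reaction-network files
examples/              one runnable narrative script per capability
scripts/               acceptance.py, build_network_files.py
docs/methods.md        model description, assumptions and limitations
tests/                 pytest suite
```
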