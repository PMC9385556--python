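# Methods

`emplix` chains five small models: reaction-network balancing → electron
accounting → electricity costing → mineralization demand → composed
sequestration cost, plus a weak-acid pH helper and a scenario sampler.
This note records the assumptions, parameter choices and numerical
decisions behind each, and what the tests do and do not establish.

## 1. Reaction networks and flux balancing

Each of the 28 shipped networks (7 carbon-assimilation routes × 4 acids)
is a plain-text reaction list (`src/emplix/data/networks/`, regenerated by
`scripts/build_network_files.py`). Pathways with well-constrained textbook
stoichiometry (Wood-Ljungdahl, Calvin, glycolysis/gluconeogenesis, the
periplasmic glucose → gluconate → 2-keto → 2,5-diketo oxidations, the
synthetic formolase route) are written step-by-step; the rTCA, 3HP-4HB,
3HP and dicarboxylate/4HB cycles are single lumped reactions.

**Bookkeeping conventions.** Metabolite formulas track C, H, O. Redox
carriers use pseudo-formulas — the reduced member of a pair (NADH, Fd_red)
is "+H₂" relative to its oxidized partner, so every reaction balances in
real atoms once a carrier's two electrons (plus charge-compensating
protons) are counted. ATP/ADP carry empty formulas; phosphoryl groups and
their hydrolysis waters are untracked. A single `nadh` species stands for
the entire 2-electron pool (NADH, NADPH, quinol-level FADH₂): the
downstream model only distinguishes NAD(P)H-level from ferredoxin-level
electrons.

**Balancing.** The network is solved as a linear program (scipy HiGHS):
internal metabolites balance exactly, one unit of the target acid is
exported, irreversible fluxes are nonnegative, and exchange species
(carbon source, water, O₂, carrier pairs) get free import variables whose
solved values are the per-molecule demands. Degeneracy is resolved
lexicographically — minimum ATP import, then minimum NAD(P)H import, then
minimum L1 flux norm — which is deterministic and removes futile cycles; a
warning is logged when the flux space has residual degrees of freedom.
Fluxes are rational, no integrality imposed.

**Surplus clamp.** Cofactors the network *nets out producing* (e.g. the
ATP acetogenesis regains via acetate kinase) are clamped to zero demand,
not credited against other costs. This is what makes the Wood-Ljungdahl
acetate configuration exactly ATP-neutral and its uncertainty band
degenerate. Dehydrogenase oxidation steps deposit their electrons into the
NAD(P)H pool *before* the clamp (so gluconate "costs" 11 rather than 12
pairs); both behaviours are visible in the pre-clamp `raw_*` fields.

**Calibration.** The original supplementary reaction matrices are not
available, so two lumped ATP coefficients are calibrated (and marked
`# calibrated` in the files) so that the downstream per-gram electricity
reproduces the published central anchors: the citrate-synthesis step
carries +2 ATP (Wood-Ljungdahl citrate totals 6 ATP → 21.1 kJ/g) and the
dicarboxylate/4HB lumped fixation carries 18 ATP per acetyl-CoA (4HB
acetate totals 17 → 56.2 kJ/g under EEU). The 4HB figure is far above
literature estimates (~5 ATP); it is what the published energy for that
pathway implies under this electron model, and we prefer an explicit,
greppable calibration to a hidden fudge factor. The Calvin→gluconate
network is *not* calibrated: it uses the canonical 6 CO₂ + 12 NAD(P)H +
18 ATP → hexose stoichiometry, giving 31 electrons per gluconate under H₂
delivery; the composed sequestration costs are therefore ~6–8% below the
published curve-read values, which we accept rather than inventing ATP.

## 2. Electron accounting

Parameters (`ElectronTransportParams`): membrane potential ΔU_m (central
140 mV; band 80–240 mV, the 270 mV literature upper bound selectable),
U_H2 = −0.41 V, U_Q = −0.0885 V, U_NADH = −0.32 V, U_Fd = −0.42 V,
U_acceptor = +0.82 V (O₂/H₂O), U_Mtr = −0.1 V (stored; the EEU entry point
is the quinone pool), ΔG_ATP/ADP = 50 kJ/mol (never published for this
model; chosen so one ATP costs 4 protons at 140 mV), protons-per-electron
unlimited.

H₂ delivery: electrons enter below NAD(P)H, so carriers cost their face
value and only ATP adds overhead — ⌈ΔG/(F·ΔU_m)⌉ protons per ATP, paid by
electrons that each pump ⌊(U_acc − U_H2)/ΔU_m⌋ protons on their way to the
acceptor. EEU delivery: electrons enter at the quinone pool, above
NAD(P)H, so reverse electron transport must lift *each of the two
electrons* of every carrier by ⌈(U_Q − U_carrier)/ΔU_m⌉ pumped protons,
with the pumping span shortened to ⌊(U_acc − U_Q)/ΔU_m⌋. The per-electron
(factor-two) uphill form is a deliberate correction to the source
equation's per-carrier printing: only the per-electron form reproduces the
published orderings (H₂ cheaper than EEU per gram; citric acid via
Wood-Ljungdahl + H₂ the global minimum). The floor/ceil terms are also
implemented with the physically meaningful sign (the printed forms are
negative). Ratios are rounded to 9 decimals before floor/ceil to avoid
floating-point edge artifacts; requirements are never rounded to integers.

Consequently ν_e is a step function of ΔU_m, and the uncertainty band on
any energy number is evaluated at the three triplet potentials, not
interpolated. With ΔG_ATP unpublished, the *widths* of the published
sub-integer error bars are not reproduced exactly (central values are);
only the ATP-neutral configuration's zero-width band is load-bearing.

## 3. Costing

Single cell: C_E = F·ΔU_cell·ν_e/(MW·ξ_I2) with the tabulated cell
voltages (2.00 V for H₂ scenarios, 1.59 V for EEU, both recomputed from
their four component potentials at load time). Dual cell (electrochemical
formate at 3.02 V, ξ_I1 = 0.8, then microbial assimilation): per-molecule
charge ν_r·ν_er in cell 1 (divided by ξ_I1·ξ_C, carbon-transfer
efficiency ξ_C defaulting to 1) plus ν_e,add in cell 2 — a first-
principles restatement of a typographically garbled source formula, exact
for the shipped ν_Cr = 1. Dollar conversion: ×10⁶ g/t ÷ 3.6×10⁶ J/kWh ×
price, price defaulting to the 2030 solar target of $0.03/kWh.
Production rate Ṅ = P·ξ_I2/(ΔU_cell·e·ν_e) closes the power balance to
machine precision.

## 4. Mineralization demand

M_forsterite = M_C·MW_fo/(MW_C·n_C) with MW_fo = 140.69, n_C = 2 (two Mg
per formula unit, one carbonate each), MW_C = 12. The lixiviant demand
multiplies by MW_lix·ζ. Forsterite density cancels through the pulp-
density definition and is stored only for completeness. Inputs are grams
of carbon; CO₂ masses convert by 12/44; pulp densities in % w/v convert
×10⁴ to g/m³. The optimistic operating point (100 mol/m³, η = 1, 1,
ρ_pulp = 5×10⁵ g/m³) gives ζ = 2×10⁻⁴ mol/g exactly. Biomass-equivalent
thresholds use 15 GJ per dry tonne of cellulosic material — the unique
round value consistent with all three published EJ↔Gt pairs — and the
six annotated ζ thresholds use the 1.4 Gt US-biomass and 80 Gt NPP mass
anchors (the published NPP energy figure is internally inconsistent and
is not used).

## 5. Acid chemistry

pH of a mono-protic weak acid at analytical concentration C: positive root
of x² + K_a·x − C·K_a = 0, evaluated in the conjugate form
x = 2CK_a/(K_a + √(K_a² + 4CK_a)) to avoid cancellation at small K_a.
Citric acid is treated mono-protically with its first pK_a (3.13) — a
knowing simplification that the triprotic system would sharpen by a few
hundredths of a pH unit. Water autoionization is neglected; solutions with
[H⁺] < 10⁻⁶ M are flagged unreliable.

## 6. Scenario sampler

Emulates the parameter-combination tables: c_lix ∈ [100, 600] mol/m³ and
the efficiencies ∈ [0.2, 1] sampled uniformly on a linear scale, ρ_pulp ∈
[10⁵, 5×10⁵] g/m³ log-uniformly (ζ spans orders of magnitude); membrane
potential range carried for joint sweeps. Seeded `numpy` Generator; a
fixed seed gives byte-identical output. `combinations_for_zeta` filters a
multiplier grid around the optimistic point to tuples within a relative
tolerance (default 5%, the source's "approximately") of a target ζ. The
sampler is a scenario enumerator, not Bayesian uncertainty quantification.

## What the tests establish — and don't

The suite verifies internal conservation laws (elemental balance of every
shipped reaction, carbon and degree-of-reduction closure of every balanced
network), agreement of the LP with an independent least-squares oracle,
hand-derived arithmetic for every formula, the published central anchors
and orderings, and determinism of the sampler. It does **not** establish
that the lumped pathway ATP coefficients are biochemically accurate (two
are explicitly calibrated), that the uncertainty-band *widths* match the
published figure, or anything about dissolution/precipitation kinetics,
DAC costs, capital costs or land use — all outside the model, which prices
electricity only, as its source does.
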