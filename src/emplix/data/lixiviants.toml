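# Registry of the four environmentally benign lixiviant acids.
#
# formula maps element -> atom count for the neutral (fully protonated) acid.
# pka is the first acid dissociation constant used by the mono-protic pH model.
# mw values are the conventional tabulated molecular weights; they are
# cross-checked against the formula at load time (0.05 g/mol tolerance).
#
# 2,5-diketo-gluconic acid (dkg) is taken as C6H8O7 (MW 192.12, degree of
# reduction 18), the double oxidation product of gluconic acid; override here
# if a different tautomer bookkeeping is preferred.

[acetic]
formula = { C = 2, H = 4, O = 2 }
mw = 60.05
pka = 4.75
metabolite = "acetate"

[citric]
formula = { C = 6, H = 8, O = 7 }
mw = 192.12
pka = 3.13
metabolite = "citrate"

[gluconic]
formula = { C = 6, H = 12, O = 7 }
mw = 196.16
pka = 3.72
metabolite = "gluconate"

[dkg]
formula = { C = 6, H = 8, O = 7 }
mw = 192.12
pka = 3.72
metabolite = "dkg"
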