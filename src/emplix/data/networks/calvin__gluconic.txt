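# calvin x gluconic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      calvin__gluconic
@pathway   calvin
@lixiviant gluconic
@source    co2
@target    gluconate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! atp        .
! gap        C3H6O3
! nad        .
! adp        .
! h2o        H2O
! f6p        C6H12O6
! g6p        C6H12O6
! glucose    C6H12O6
! gdl        C6H10O6
! gluconate  C6H12O7
cbb: 3 co2 + 6 nadh + 9 atp -> gap + 6 nad + 9 adp + 3 h2o
fbp: 2 gap -> f6p
pgi: f6p <-> g6p
g6pase: g6p -> glucose
gdh: glucose + nad -> gdl + nadh
glac: gdl + h2o -> gluconate
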