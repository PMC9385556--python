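# formolase x gluconic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      formolase__gluconic
@pathway   formolase
@lixiviant gluconic
@source    formate
@target    gluconate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp formate
! formate    CH2O2
! nadh       H2
! atp        .
! fald       CH2O
! nad        .
! adp        .
! h2o        H2O
! dha        C3H6O3
! gap        C3H6O3
! f6p        C6H12O6
! g6p        C6H12O6
! glucose    C6H12O6
! gdl        C6H10O6
! gluconate  C6H12O7
ffl: formate + nadh + atp -> fald + nad + adp + h2o
fls3: 3 fald -> dha
dhak: dha + atp -> gap + adp
fbp: 2 gap -> f6p
pgi: f6p <-> g6p
g6pase: g6p -> glucose
gdh: glucose + nad -> gdl + nadh
glac: gdl + h2o -> gluconate
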