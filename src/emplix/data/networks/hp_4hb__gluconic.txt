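# hp_4hb x gluconic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      hp_4hb__gluconic
@pathway   hp_4hb
@lixiviant gluconic
@source    co2
@target    gluconate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! atp        .
! accoa      C2H4O2
! nad        .
! adp        .
! h2o        H2O
! fdred      H2
! pyruvate   C3H4O3
! fdox       .
! pep        C3H4O3
! pg3        C3H6O4
! gap        C3H6O3
! f6p        C6H12O6
! g6p        C6H12O6
! glucose    C6H12O6
! gdl        C6H10O6
! gluconate  C6H12O7
hp4hb: 2 co2 + 4 nadh + 4 atp -> accoa + 4 nad + 4 adp + 2 h2o
pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o
peps: pyruvate + 2 atp -> pep + 2 adp
eno: pg3 <-> pep + h2o
gpk: gap + nad + adp + h2o <-> pg3 + nadh + atp
fbp: 2 gap -> f6p
pgi: f6p <-> g6p
g6pase: g6p -> glucose
gdh: glucose + nad -> gdl + nadh
glac: gdl + h2o -> gluconate
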