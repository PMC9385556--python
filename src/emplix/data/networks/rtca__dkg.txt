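# rtca x dkg lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      rtca__dkg
@pathway   rtca
@lixiviant dkg
@source    co2
@target    dkg
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! fdred      H2
! atp        .
! accoa      C2H4O2
! nad        .
! fdox       .
! adp        .
! h2o        H2O
! pyruvate   C3H4O3
! pep        C3H4O3
! pg3        C3H6O4
! gap        C3H6O3
! f6p        C6H12O6
! g6p        C6H12O6
! glucose    C6H12O6
! gdl        C6H10O6
! gluconate  C6H12O7
! kg2        C6H10O7
! dkg        C6H8O7
rtca: 2 co2 + 3 nadh + fdred + 2 atp -> accoa + 3 nad + fdox + 2 adp + 2 h2o
pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o
peps: pyruvate + 2 atp -> pep + 2 adp
eno: pg3 <-> pep + h2o
gpk: gap + nad + adp + h2o <-> pg3 + nadh + atp
fbp: 2 gap -> f6p
pgi: f6p <-> g6p
g6pase: g6p -> glucose
gdh: glucose + nad -> gdl + nadh
glac: gdl + h2o -> gluconate
ga2dh: gluconate + nad -> kg2 + nadh
kgdh: kg2 + nad -> dkg + nadh
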