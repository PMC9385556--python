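# rtca x acetic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      rtca__acetic
@pathway   rtca
@lixiviant acetic
@source    co2
@target    acetate
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
! acetate    C2H4O2
rtca: 2 co2 + 3 nadh + fdred + 2 atp -> accoa + 3 nad + fdox + 2 adp + 2 h2o
ack: accoa + adp -> acetate + atp
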