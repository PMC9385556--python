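# hp x acetic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      hp__acetic
@pathway   hp
@lixiviant acetic
@source    co2
@target    acetate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! atp        .
! accoa      C2H4O2
! nad        .
! adp        .
! h2o        H2O
! acetate    C2H4O2
hp: 2 co2 + 4 nadh + 5 atp -> accoa + 4 nad + 5 adp + 2 h2o
ack: accoa + adp -> acetate + atp
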