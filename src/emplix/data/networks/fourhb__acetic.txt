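# fourhb x acetic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      fourhb__acetic
@pathway   fourhb
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
fourhb: 2 co2 + 4 nadh + 18 atp -> accoa + 4 nad + 18 adp + 2 h2o  # calibrated ATP
ack: accoa + adp -> acetate + atp
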