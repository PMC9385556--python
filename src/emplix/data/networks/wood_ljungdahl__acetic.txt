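# wood_ljungdahl x acetic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      wood_ljungdahl__acetic
@pathway   wood_ljungdahl
@lixiviant acetic
@source    co2
@target    acetate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! formate    CH2O2
! nad        .
! atp        .
! ch3x       CH4O
! adp        .
! h2o        H2O
! fdred      H2
! accoa      C2H4O2
! fdox       .
! acetate    C2H4O2
fdh: co2 + nadh -> formate + nad
mtb: formate + 2 nadh + atp -> ch3x + 2 nad + adp + h2o
acs: ch3x + co2 + fdred -> accoa + fdox + h2o
ack: accoa + adp -> acetate + atp
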