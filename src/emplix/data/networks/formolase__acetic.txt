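# formolase x acetic lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      formolase__acetic
@pathway   formolase
@lixiviant acetic
@source    formate
@target    acetate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp formate
! formate    CH2O2
! nadh       H2
! atp        .
! fald       CH2O
! nad        .
! adp        .
! h2o        H2O
! glycolald  C2H4O2
! acetate    C2H4O2
ffl: formate + nadh + atp -> fald + nad + adp + h2o
fls2: 2 fald -> glycolald
pkt: glycolald + adp -> acetate + atp
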