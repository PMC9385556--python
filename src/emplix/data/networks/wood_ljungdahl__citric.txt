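# wood_ljungdahl x citric lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      wood_ljungdahl__citric
@pathway   wood_ljungdahl
@lixiviant citric
@source    co2
@target    citrate
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
! pyruvate   C3H4O3
! pep        C3H4O3
! oaa        C4H4O5
! citrate    C6H8O7
fdh: co2 + nadh -> formate + nad
mtb: formate + 2 nadh + atp -> ch3x + 2 nad + adp + h2o
acs: ch3x + co2 + fdred -> accoa + fdox + h2o
pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o
peps: pyruvate + 2 atp -> pep + 2 adp
ppc: pep + co2 -> oaa
cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP
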