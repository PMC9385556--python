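# rtca x citric lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      rtca__citric
@pathway   rtca
@lixiviant citric
@source    co2
@target    citrate
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
! oaa        C4H4O5
! citrate    C6H8O7
rtca: 2 co2 + 3 nadh + fdred + 2 atp -> accoa + 3 nad + fdox + 2 adp + 2 h2o
pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o
peps: pyruvate + 2 atp -> pep + 2 adp
ppc: pep + co2 -> oaa
cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP
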