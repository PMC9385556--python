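# fourhb x citric lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      fourhb__citric
@pathway   fourhb
@lixiviant citric
@source    co2
@target    citrate
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
! oaa        C4H4O5
! citrate    C6H8O7
fourhb: 2 co2 + 4 nadh + 18 atp -> accoa + 4 nad + 18 adp + 2 h2o  # calibrated ATP
pfor: accoa + co2 + fdred -> pyruvate + fdox + h2o
peps: pyruvate + 2 atp -> pep + 2 adp
ppc: pep + co2 -> oaa
cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP
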