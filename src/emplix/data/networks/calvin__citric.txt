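# calvin x citric lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      calvin__citric
@pathway   calvin
@lixiviant citric
@source    co2
@target    citrate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp
! co2        CO2
! nadh       H2
! atp        .
! gap        C3H6O3
! nad        .
! adp        .
! h2o        H2O
! pg3        C3H6O4
! pep        C3H4O3
! pyruvate   C3H4O3
! accoa      C2H4O2
! oaa        C4H4O5
! citrate    C6H8O7
cbb: 3 co2 + 6 nadh + 9 atp -> gap + 6 nad + 9 adp + 3 h2o
gpk: gap + nad + adp + h2o <-> pg3 + nadh + atp
eno: pg3 <-> pep + h2o
pk: pep + adp -> pyruvate + atp
pdh: pyruvate + nad + h2o -> accoa + co2 + nadh
ppc: pep + co2 -> oaa
cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP
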