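# formolase x citric lixiviant synthesis network
# generated by scripts/build_network_files.py -- edit there, not here
@name      formolase__citric
@pathway   formolase
@lixiviant citric
@source    formate
@target    citrate
@exchange  co2 h2o o2 nadh nad fdred fdox atp adp formate
! formate    CH2O2
! nadh       H2
! atp        .
! fald       CH2O
! nad        .
! adp        .
! h2o        H2O
! dha        C3H6O3
! gap        C3H6O3
! pg3        C3H6O4
! pep        C3H4O3
! pyruvate   C3H4O3
! accoa      C2H4O2
! co2        CO2
! oaa        C4H4O5
! citrate    C6H8O7
ffl: formate + nadh + atp -> fald + nad + adp + h2o
fls3: 3 fald -> dha
dhak: dha + atp -> gap + adp
gpk: gap + nad + adp + h2o <-> pg3 + nadh + atp
eno: pg3 <-> pep + h2o
pk: pep + adp -> pyruvate + atp
pdh: pyruvate + nad + h2o -> accoa + co2 + nadh
ppc: pep + co2 -> oaa
cs: oaa + accoa + 2 atp -> citrate + 2 adp  # calibrated ATP
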