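# Electromicrobial lixiviant production scenarios (four electrochemical
# configurations). Voltages in volts, powers in watts.
#
# Sign convention for the total cell voltage:
#   delta_u = (cathode_0 + cathode_bias) - anode_0 + anode_bias
# which reproduces the three published totals (2.00, 1.59 and 3.02 V).
#
# xi_c (carbon transfer efficiency between cells) has no tabulated value;
# default 1.0, configurable here.

[H2]
mediator = "H2"
fixation_route = "enzymatic"
u_cell2_anode0 = -0.41
u_cell2_anode_bias = 0.30
u_cell2_cathode0 = 0.82
u_cell2_cathode_bias = 0.47
xi_i2 = 1.0
p_solar = 1000.0
p_electric = 330.0

[EEU]
mediator = "EEU"
fixation_route = "enzymatic"
u_cell2_anode0 = -0.10
u_cell2_anode_bias = 0.20
u_cell2_cathode0 = 0.82
u_cell2_cathode_bias = 0.47
xi_i2 = 1.0
p_solar = 1000.0
p_electric = 330.0

["H2+formate"]
mediator = "H2"
fixation_route = "electrochemical-formate"
u_cell1_cathode0 = 0.82
u_cell1_cathode_bias = 0.47
u_cell1_anode0 = -0.43
u_cell1_anode_bias = 1.30
xi_i1 = 0.8
xi_c = 1.0
nu_cr = 1
nu_er = 2
u_cell2_anode0 = -0.41
u_cell2_anode_bias = 0.30
u_cell2_cathode0 = 0.82
u_cell2_cathode_bias = 0.47
xi_i2 = 1.0
p_solar = 1000.0
p_electric = 330.0

["EEU+formate"]
mediator = "EEU"
fixation_route = "electrochemical-formate"
u_cell1_cathode0 = 0.82
u_cell1_cathode_bias = 0.47
u_cell1_anode0 = -0.43
u_cell1_anode_bias = 1.30
xi_i1 = 0.8
xi_c = 1.0
nu_cr = 1
nu_er = 2
u_cell2_anode0 = -0.10
u_cell2_anode_bias = 0.20
u_cell2_cathode0 = 0.82
u_cell2_cathode_bias = 0.47
xi_i2 = 1.0
p_solar = 1000.0
p_electric = 330.0
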