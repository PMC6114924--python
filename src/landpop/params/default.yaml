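# Packaged baseline parameter set.
#
# Land-side rates and efficiencies are set by magnitude arguments against
# coarse historical global land-cover paths (see docs/methods.md); the
# recruitment rate b and the resource-mortality coefficient q are calibrated
# to the 1960-2016 global population series by trajectory matching
# (analysis/01_calibrate_baseline.py reproduces the fit from
# data/history_world_1960_2016.csv).
units:
  land: billion_ha
  population: billion
  time: year
r: 0.001
delta_N: 0.001
delta_A: 0.005
d_N: 0.00015
d_A: 0.0005
c_NA: 0.00005
c_ND: 0.0005
c_AN: 0.00065
c_AD: 0.0002
p_N: 0.5
p_A: 0.5
eta_N: 1.0
eta_A: 1.2
b: 0.039095
beta: 0.25
m: 0.010
q: 0.071602
q_N: 2.0
q_A: 2.0
E_N: 0.5
E_A: 1.2
phi: 0.5
N_th: 5.2
L: 13.0
initial:
  t: 1960
  N: 7.55
  A: 1.36
  H: 3.03
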