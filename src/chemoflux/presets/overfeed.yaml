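# Nutrient-excess condition: total feed 120 g/h split 60/60 between substrate
# and water feed, so the effective feed concentration exceeds the culture's
# uptake capacity and both carbon sources accumulate in the broth (MSG much
# faster than glucose).  Amino acids are secreted in addition to trehalose and
# the measured carbon balance closes at 0.79.
name: overfeed
v_reactor: 2.0
feed_conc:
  msg: 38.0        # 76 * 60 / 120
  glucose: 18.0    # 36 * 60 / 120
tfr: 120.0
sfr: 60.0
wfr: 60.0
density: 1000.0
evaporation: 0.012
true_mu: 0.054
true_q:
  msg: 0.1076757       # leaves 0.18 g/L/h accumulating at the initial broth state
  glucose: 0.0572432   # leaves 0.0048 g/L/h accumulating
  trehalose: -0.009
  valine: -0.008
  glycine: -0.004
  alanine: -0.003
unmeasured_sink_fraction: 0.21
x0: 18.5
c0:
  msg: 2.0
  glucose: 0.3
  trehalose: 0.3
  valine: 0.1
  glycine: 0.05
  alanine: 0.04
gas_flow: 30.0
noise_cv:
  dcw: 0.01
  conc: 0.01
  offgas: 0.02
grid: [0.0, 6.0, 12.0, 18.0, 24.0]
seed: 3
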