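# Elevated condition: total feed 120 g/h (40 substrate + 80 water), higher cell
# density and uptake, still no substrate accumulation.  The unmeasured carbon
# sink makes the measured carbon balance close at 0.80.
name: high
v_reactor: 2.0
feed_conc:
  msg: 25.333333333333332   # 76 * 40 / 120
  glucose: 12.0             # 36 * 40 / 120
tfr: 120.0
sfr: 40.0
wfr: 80.0
density: 1000.0
evaporation: 0.046
true_mu: 0.037
true_q:
  msg: 0.093142      # steady-state balance at 0.3 g/L residual MSG
  glucose: 0.044216  # steady-state balance at 0.1 g/L residual glucose
  trehalose: -0.009
unmeasured_sink_fraction: 0.20
x0: 16.2
gas_flow: 30.0
noise_cv:
  dcw: 0.01
  conc: 0.01
  offgas: 0.02
grid: [0.0, 6.0, 12.0, 18.0, 24.0]
seed: 2
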