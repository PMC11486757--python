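# Baseline chemostat condition: moderate cell density, no substrate accumulation.
# Total feed 90 g/h (22.5 g/h substrate feed + 67.5 g/h water) on a 2 L working
# volume; stock feed 76 g/L MSG + 36 g/L glucose diluted to the effective
# concentrations below.  Evaporation reconciles the feed-based dilution rate
# (0.045 1/h) with the steady-state growth rate 0.031 1/h.
name: low
v_reactor: 2.0
feed_conc:
  msg: 19.0        # 76 * 22.5 / 90
  glucose: 9.0     # 36 * 22.5 / 90
tfr: 90.0
sfr: 22.5
wfr: 67.5
density: 1000.0
evaporation: 0.028
true_mu: 0.031
true_q:
  msg: 0.169760      # steady-state balance at 0.2 g/L residual MSG
  glucose: 0.080380  # steady-state balance at 0.1 g/L residual glucose
  trehalose: -0.003
unmeasured_sink_fraction: 0.0
x0: 5.0
gas_flow: 30.0
noise_cv:
  dcw: 0.01
  conc: 0.01
  offgas: 0.02
grid: [0.0, 6.0, 12.0, 18.0, 24.0]
seed: 1
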