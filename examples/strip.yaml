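# Planar-wave strip for the APD/CV temperature study.
# A planar wave is y-invariant, so a thin strip reproduces the full sheet.
protocol:
  name: planar_q10
  tstar: 37.0
  domain: [10.0, 0.1]
  dx: 0.025
  dt: 0.1
  duration: 750.0
  probes: [[6.0, 0.05], [6.5, 0.05], [7.0, 0.05]]
solver:
  dt: 0.1
output:
  snapshot_stride: 30.0
  out_dir: runs
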