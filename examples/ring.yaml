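# A 400-unit planar ring of radius 10 with six stable fixed points.
ring:
  n_units: 400
  n_dim: 2
  radius: 10.0
  seed: 0
drift:
  amplitude: 0.1
  n_fp: 6
  baseline: 0.0
synthesis:
  tau: 0.1
  n_setpoints: 64
  sigma_reg: 1.0e-6
  seed: 0
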