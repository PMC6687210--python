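# Volume-growth sweep on an arc whose curvature is 0.01 at mid-span and
# decays to zero near the ends (radius of curvature 100); active mantle
# width fixed at delta_s = 1. The arc extent (19) is the calibrated value
# documented in docs/methods.md.
schema_version: 1
geometry:
  kind: varying
  length: 19.0
  kappa_xi2: [0.0, 2.28, 7.6, 11.4, 16.72, 19.0]
  kappa_values: [0.0, 0.0, 0.01, 0.01, 0.0, 0.0]
  bend: in_surface
  n_elem_s2: 52
  layers: 1
  basis_order: 2
  h: 0.35
growth:
  increments:
    - {delta_s: 1.0, delta_g: 0.12, rows: 2}
material: {mu: 1.0, lam: 2.0}
bcs: {variant: trailing_fixed_rest_free}
solver: {load_steps: 10, imperfection_seed: 0}
sweep:
  delta_g_multipliers: [1.0, 2.0, 3.0, 4.0]
  delta_g_step: 0.01
  delta_g_max: 0.56
  detection_amplitude_h: 0.02
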