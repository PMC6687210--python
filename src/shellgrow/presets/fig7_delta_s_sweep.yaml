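# Single-increment runs on a uniform-curvature arc (kappa = 0.01, radius 100)
# at a family of active mantle widths; mode number falls as the strip widens.
schema_version: 1
geometry:
  kind: arc
  radius: 100.0
  length: 20.0
  n_elem_s2: 56
  layers: 1
  basis_order: 2
  h: 0.2
growth:
  increments:
    - {delta_s: 1.0, delta_g: 0.07, rows: 2}
material: {mu: 1.0, lam: 2.0}
bcs: {variant: trailing_fixed_rest_free}
solver: {load_steps: 10, imperfection_seed: 0}
sweep:
  delta_s_multipliers: [1.0, 1.414, 2.0, 2.828, 4.0, 5.657, 8.0]
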