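# Base configuration for small (delta_s, delta_g, kappa) phase-diagram sweeps.
schema_version: 1
geometry:
  kind: arc
  radius: 100.0
  length: 12.0
  n_elem_s2: 24
  layers: 1
  basis_order: 2
  h: 0.2
growth:
  increments:
    - {delta_s: 1.0, delta_g: 0.06, rows: 2}
material: {mu: 1.0, lam: 2.0}
bcs: {variant: trailing_fixed_rest_free}
solver: {load_steps: 8, imperfection_seed: 0}
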