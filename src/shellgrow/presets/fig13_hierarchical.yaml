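# Hierarchical ornamentation: full-width strip, then a half-width strip at
# the same growth increment, then pure volume growth at double increment
# with a stationary calcification front.
schema_version: 1
geometry:
  kind: line
  length: 8.0
  n_elem_s2: 26
  layers: 1
  basis_order: 2
  h: 0.3
growth:
  increments:
    - {delta_s: 2.0, delta_g: 0.11, rows: 4}
    - {delta_s: 1.0, delta_g: 0.11, rows: 2}
    - {delta_s: 0.0, delta_g: 0.22, rows: 1}
material: {mu: 1.0, lam: 2.0}
bcs: {variant: trailing_and_lateral_fixed}
solver: {load_steps: 10, imperfection_seed: 0}
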