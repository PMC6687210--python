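# Out-of-surface reference curvature changing sign along the margin:
# local crest direction follows the local curvature sign.
schema_version: 1
geometry:
  kind: varying
  length: 15.0
  kappa_xi2: [0.0, 6.0, 9.0, 15.0]
  kappa_values: [0.08, 0.08, -0.08, -0.08]
  bend: out_of_surface
  n_elem_s2: 44
  layers: 1
  basis_order: 2
  h: 0.2
growth:
  increments:
    - {delta_s: 1.0, delta_g: 0.08, rows: 2}
material: {mu: 1.0, lam: 2.0}
bcs: {variant: trailing_and_lateral_fixed}
solver: {load_steps: 10, imperfection_seed: 0}
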