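# Growth-strain rate increasing (convexly) from the trailing to the leading
# edge of a wide strip: the mantle arches backward and the ornamentation
# carries negative Gaussian curvature.
schema_version: 1
geometry:
  kind: line
  length: 15.0
  n_elem_s2: 44
  layers: 1
  basis_order: 2
  h: 0.2
growth:
  increments:
    - delta_s: 3.0
      delta_g: 0.0
      rows: 3
      profile_xi1: [[0.0, 0.02], [0.4, 0.035], [0.7, 0.07], [1.0, 0.16]]
material: {mu: 1.0, lam: 2.0}
bcs: {variant: fig14_variant}
solver: {load_steps: 10, imperfection_seed: 0}
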