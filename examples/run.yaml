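# Example run configuration for the brachysim CLI:
#   brachysim run examples/run.yaml --out out/
# A scaled phantom with 2 anchor needles + 8 catheters; every default of the
# simulator can be overridden here (see brachysim/config.py for the schema).
phantom:
  prostate_semi_axes: [12, 9, 9]   # mm, ellipsoid gland
  block_dims: [36, 36, 36]         # mm, surrounding tissue block
  nodal_spacing: 3.0               # mm
  insertion_axis: [0, 0, 1]
  rng_seed: 0
plan:
  n_anchor: 2
  n_catheter: 8
  template_pitch: 4.0              # mm, template hole spacing
  sequence: alternate_lb_rt        # or alternate_rb_lb
materials:
  prostate:    {young_kpa: 25.0, poisson: 0.49, density: 1000.0}
  surrounding: {young_kpa: 10.0, poisson: 0.49, density: 1000.0}
insertion:
  influence_radius: 3.0            # mm, tip-following region
  decay: linear                    # or exponential
  increment: 3.0                   # mm advanced per relaxation
  stiffening_factor: 30.0          # anchor / placed-catheter stiffening
  catheter_stiffening_radius: 2.0  # mm
  max_drag: 2.0                    # mm, per-node tip-following cap
  anchor_stiffening: true          # false reproduces the ablation scenario
solver:
  dilation: 2.0                    # support radius / nodal spacing
  safety: 0.5                      # CFL safety factor
  relax_tol: 1.0e-3                # mm, relaxation convergence
  max_iter: 2000
  mass_scaling: true
output:
  voxel_size: 1.0                  # mm, Dice evaluation grid
  write_vtk: true
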