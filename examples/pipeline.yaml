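# Demo pipeline: 64^3 plate-lattice phantom standing in for a scanned
# 5 x 5 x 5 mm^3 articular-process ROI cube.  Plates are oriented
# parallel to the loading (z) axis so the lattice carries load.
seed: 1
output_dir: trabmech_out
volume:
  phantom:
    shape_voxels: [64, 64, 64]
    voxel_size: 0.078125        # mm -> 5 mm cube
    architecture: plate_lattice
    target_bvtv: 0.25
    element_thickness: 0.390625 # mm = 5 voxels
    bone_hu: 2000.0
    marrow_hu: 0.0
    noise_sd: 80.0
    normal_axis: 2              # plates normal to x, spanning z
threshold: midpoint
bmd_calibration:
  slope: 0.35                   # (mg/cc)/HU, scanner-phantom calibration
  intercept: 0.0
theta: 45.0                     # facet-plane angle, degrees
fe:
  enabled: true
  mode: fixed_top_tangential
  strain: 0.01
  quantile: 0.75
  write_vtk: true
curves:
  yield_strain: 0.008
  hardening_ratio: 0.05
  max_strain: 0.03
  n_points: 200
  noise_sd: 0.0
stats:
  synthetic_n: 144
  synthetic_slope: 299.667
  synthetic_intercept: -76.9
  synthetic_noise_sd: 30.0
  ridge_lambda: 1.0
  alpha: 0.05
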