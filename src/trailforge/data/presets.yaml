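# Substrate and donor presets for resorption simulations.
#
# Intensities, roughness targets, adhesion densities, geometry-moment
# targets and donor depth plateaus are taken from published in vitro
# measurements of human osteoclasts cultured on bovine cortical bone and
# elephant-ivory dentin.  Smooth-surface event intensities are not
# published separately (differences between rough and smooth surfaces
# were reported as non-significant, with a trend to higher values on
# rough); smooth presets therefore reuse the rough-geometry targets with
# the event intensity scaled by 0.8.

presets:
  bone_rough:
    event_intensity_per_cm2: 449.0
    trail_fraction: 0.5
    ra_target_um: 6.27
    rq_target_um: 7.71
    adhesion_cells_per_cm2: 11400.0
    geometry_targets:
      mean_area_um2: 580.0
      mean_length_um: 53.0
      mean_width_um: 9.5
  bone_smooth:
    event_intensity_per_cm2: 359.2
    trail_fraction: 0.5
    ra_target_um: 1.05
    rq_target_um: 2.27
    adhesion_cells_per_cm2: 11400.0
    geometry_targets:
      mean_area_um2: 580.0
      mean_length_um: 53.0
      mean_width_um: 9.5
  dentin_rough:
    event_intensity_per_cm2: 3134.0
    trail_fraction: 0.5
    ra_target_um: 15.14
    rq_target_um: 18.51
    adhesion_cells_per_cm2: 17200.0
    geometry_targets:
      mean_area_um2: 700.0
      mean_length_um: 59.0
      mean_width_um: 11.0
  dentin_smooth:
    event_intensity_per_cm2: 2507.2
    trail_fraction: 0.5
    ra_target_um: 3.75
    rq_target_um: 5.21
    adhesion_cells_per_cm2: 17200.0
    geometry_targets:
      mean_area_um2: 700.0
      mean_length_um: 59.0
      mean_width_um: 11.0

# Donor-specific maximum resorption depths (depth plateaus, μm) from two
# independent experiments on the same three blood donors.
donors:
  donor1_exp1: {d_max_um: 35.0}
  donor2_exp1: {d_max_um: 55.0}
  donor3_exp1: {d_max_um: 68.0}
  donor1_exp2: {d_max_um: 32.0}
  donor2_exp2: {d_max_um: 59.0}
  donor3_exp2: {d_max_um: 62.0}

# Pooled observed summary values kept as reference inputs for
# fold-change arithmetic (they are observables, not simulator knobs).
reference_observations:
  resorbed_area_pct: {bone: 0.6, dentin: 6.7}
  events_per_cm2: {bone: 449.0, dentin: 3134.0}
  adhesion_cells_per_cm2: {bone: 11400.0, dentin: 17200.0}
  mean_event_area_um2: {bone: 580.0, dentin: 700.0}
  mean_event_length_um: {bone: 53.0, dentin: 59.0}
  mean_event_width_um: {bone: 9.5, dentin: 11.0}
  donor_depth_plateaus_um:
    exp1: {donor1: 35.0, donor2: 55.0, donor3: 68.0}
    exp2: {donor1: 32.0, donor2: 59.0, donor3: 62.0}

# Free mechanistic parameters shared by all presets (not published;
# see the package methods note for the rationale behind each default).
defaults:
  depth_saturation_area_um2: 150.0
  depth_noise_cv: 0.08
  heading_sd_deg: 2.0
  correlation_length_um: 20.0
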