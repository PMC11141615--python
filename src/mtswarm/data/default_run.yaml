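analysis:
  block: 16
  wavelengths_um:
  - 6.1
  - 46.7
  window: 25
controller_rates: {}
controller_species: {}
enzymes:
  nickase_activity: 1.0
  polymerase_activity: 1.0
  restriction_activity: 1.0
render:
  frame_interval: 20.0
  n_frames: 180
  photon_scale: 40.0
  pixel_size: 0.5
  psf_sigma: 0.6
  read_noise: 2.0
seed: 0
swarm:
  alignment_rate: 2.0
  arena:
  - 64.0
  - 64.0
  binding_radius: 0.5
  k_off_scale: 0.004
  k_on_scale: 0.004
  length_mean: 6.2
  length_sd: 2.2
  n_filaments: 80
  rotational_diffusion: 0.02
  seed: 0
  speed_mean: 29.4
  speed_sd: 1.2
  sticking_rate: 0.008
t_end_min: 90.0
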