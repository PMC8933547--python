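# Full pipeline example: simulate a connected chain spanning ~3x the
# memory-effect range, demix it, and reconstruct beyond the ME limit.
mode: simulate_and_reconstruct
seed: 1
output_dir: out
simulate:
  n_emitters: 10
  layout: connected_chain
  chain_step: 6.7        # < me_range so consecutive emitters share a patch
  fov_radius: 42.0
  min_separation: 3.0
  n_frames: 1000
  weight_model: iid_exponential
  optics:
    frame_height: 96
    frame_width: 96
    grain_size: 4.0
    me_range: 20.0
    noise_photons: 2.0e4
    read_noise_sigma: 1.0
preprocess:
  highpass_sigma: 2.0
  clip_mode: clip_zero
demix:
  rank: auto
  rank_min: 2
  rank_max: 16
  rank_step: 2
  restarts: 2
  scan_max_iter: 80
  dtype: float32
fbr:
  quality_threshold: 3.0
  consistency_tol: 2.0
  deconv:
    mu: 100.0
    max_iter: 200
evaluate:
  match_radius_grains: 2.0
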