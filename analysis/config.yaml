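# Study conditions for the synthetic cohort analysis.
#
# Ten subjects, 10-minute sessions, alternating wakeful/drowsy episodes.
# Drowsiness doubles theta band power and halves alpha; channel F4 is the
# designated high-SNR channel (lower broadband noise and band-weight
# jitter), emulating a montage in which one channel expresses the
# state contrast most cleanly.
n_subjects: 10
session_length: 600.0
episode_duration_range_wakeful: [60.0, 120.0]
episode_duration_range_drowsy: [45.0, 90.0]
eeg_fs: 200.0
ear_fps: 30.0
band_power_profile:
  wakeful: {delta: 0.6, theta: 0.4, alpha: 1.0, beta: 0.3}
  drowsy: {delta: 0.8, theta: 0.8, alpha: 0.5, beta: 0.3}
blink_profile:
  wakeful: {rate_per_min: 15.0, closure_mean_s: 0.15, closure_sd_s: 0.05}
  drowsy: {rate_per_min: 10.0, closure_mean_s: 2.5, closure_sd_s: 0.8}
noise_sd: 1.0
band_weight_jitter: 0.6
channel_noise_scale: {F4: 0.3}
seed: 1
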