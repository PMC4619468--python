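"""Simulate one subject's walk and extract their gait features.

Builds a calibrated walking recording (5 segments of ~4 m at 30 fps with
5 mm sensor noise), runs the full pipeline — gross-error frame rejection,
Savitzky-Golay smoothing, walk-span detection, step counting — and prints
the recovered features next to the generator's ground truth.
"""

from kinegait import calibrated_walk_spec, extract_features, simulate_walk

spec = calibrated_walk_spec(
    target_sl=0.54,       # stride length [m], controls preset
    target_gv=0.81,       # gait velocity [m/s]
    leg_length=0.785,     # hip-knee + knee-ankle [m]
    asymmetry=0.004,      # left-right leg difference [m]
    noise_sd=0.005,
    seed=42,
)
recording, truth = simulate_walk(spec)
features = extract_features(recording)

print(f"segments simulated : {recording.n_segments}")
print(f"steps per segment  : {truth.step_counts}")
print(f"stride length  : {features.sl_m:.3f} m   (truth {truth.sl_m:.3f})")
print(f"gait velocity  : {features.gv_mps:.3f} m/s (truth {truth.gv_mps:.3f})")
print(f"leg length     : {features.leg_length_m:.4f} m (truth {truth.leg_mean_m:.4f})")
print(f"L-R asymmetry  : {features.leg_asymmetry_m * 1000:.1f} mm")
# Stride length is walking distance between the first and last detected
# step divided by the step count; velocity divides by the elapsed time.
# Recovery within a few percent shows the pipeline survives sensor noise.
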