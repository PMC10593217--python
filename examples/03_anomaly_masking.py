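"""How the decomposition-based anomaly mask protects the ROM estimate.

Simulates a neck-rotation trial whose tracking glitches (Bernoulli
landmark spikes) would otherwise inflate the maximum angle, and shows
the angle series before/after masking.
"""

import numpy as np

from romkit import (
    KinematicScenario,
    NoiseModel,
    compute_angle_series,
    compute_trial_rom,
    lookup,
    simulate_trial,
)

spec = lookup("Neck Rotation")
scenario = KinematicScenario(movement=spec, true_rom=70.0)
noise = NoiseModel(landmark_sigma=0.003, outlier_rate=0.04,
                   outlier_scale=0.3, seed=5)

trial = simulate_trial(scenario, noise)
series = compute_angle_series(trial, spec)
result = compute_trial_rom(trial, spec)

raw_max = float(series.alpha.max())
print(f"injected spike frames: {trial.provenance['outlier_frames']}")
print(f"frames flagged:        {np.flatnonzero(series.anomaly_mask).tolist()}")
print(f"raw max angle:         {raw_max:.2f} deg")
print(f"masked ROM:            {result.rom:.2f} deg   (true 70.00)")
# The raw maximum rides on a tracking spike; the residual of the additive
# trend/seasonal decomposition exposes the spikes (|z| > 3 SD) and the
# ROM is taken over the remaining frames.
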