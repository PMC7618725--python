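"""From raw epochs to baseline-corrected band power in 100 ms bins.

Morlet-wavelet power is computed per trial, region and frequency,
expressed as percent change from each trial's -0.8..-0.1 s baseline, and
averaged into beta / gamma / high-gamma values for each 100 ms bin.
"""

import numpy as np

from gaspread import SimulationConfig, bandpower_pipeline
from gaspread.simulate import simulate_participant_epochs

cfg = SimulationConfig(n_hc=1, n_als=0, n_regions=12, n_trials=8, seed=1)
ep = simulate_participant_epochs(cfg, "HC", np.random.default_rng(1), "hc001")
bp = bandpower_pipeline(ep)

print(f"band power: trials x regions x bands x bins = {bp.value.shape}")
print(f"bands = {bp.band_names}, bin pitch = "
      f"{bp.bin_edges[1] - bp.bin_edges[0]:.1f} s, {bp.n_bins} bins")

centers = bp.bin_centers()
tm = bp.trial_mean()  # regions x bands x bins
move = (centers >= 0.0) & (centers <= 3.0)
tonic = (centers >= 1.0) & (centers <= 3.0)

beta_motor = tm[:cfg.n_motor_regions, 0, :]
print(f"\nbeta, motor regions: baseline {beta_motor[:, centers < 0].mean():+.2f}"
      f" -> movement {beta_motor[:, move].mean():+.2f}  (negative = ERD)")
gamma = tm[:, 1, :]
print(f"gamma, all regions:  baseline {gamma[:, centers < 0].mean():+.2f}"
      f" -> tonic grip {gamma[:, tonic].mean():+.2f}  (positive = activation)")
print("\nvalues are unitless relative power change; 1.0 means double the "
      "trial's baseline power")
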