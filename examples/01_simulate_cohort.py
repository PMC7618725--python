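"""Simulate a small ALS/HC cohort of parcellated MEG epochs.

Each participant gets trials x regions x samples of 1/f background noise
plus band-limited oscillatory structure: beta desynchronization in motor
regions during movement, gamma/high-gamma bursts in a per-trial subset
of regions during the 1-3 s tonic grip window (broader and longer in the
ALS-like group), and a gamma background suppressed in a few regions
(fewer in ALS). Clinical and behavioral tables come with it.
"""

import numpy as np

from gaspread import SimulationConfig, simulate_clinical_table, \
    simulate_behavior_table
from gaspread.simulate import participant_rngs, simulate_participant_epochs

cfg = SimulationConfig(n_hc=3, n_als=3, n_regions=52, n_trials=10, seed=0)

for pid, group, rng in participant_rngs(cfg):
    ep, truth = simulate_participant_epochs(cfg, group, rng, pid,
                                            return_truth=True)
    active = truth["gamma"].sum(axis=1).mean()
    print(f"{pid} ({group}): data {ep.data.shape}, "
          f"mean gamma-active regions/trial = {active:.1f}")

clinical = simulate_clinical_table(cfg)
print("\nALS clinical rows (progression_rate = (48 - ALSFRS_R) / duration):")
print(clinical[clinical.group == "ALS"]
      [["participant_id", "age", "sex", "ALSFRS_R", "symptom_duration",
        "progression_rate"]].to_string(index=False))

behavior = simulate_behavior_table(cfg)
print(f"\ngrip strength mean = {behavior.grip_strength.mean():.1f} N "
      "(task target is 12 N; groups share one distribution -> null difference)")
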