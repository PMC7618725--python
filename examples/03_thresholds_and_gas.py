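"""Calibrate HC thresholds, binarize activations, compute spread and GAS.

Cut-offs are the pooled HC mean +/- 2 pooled SD of the trial-averaged
power time course, one pair per region x band; every trial x region x
band x bin is then scored +1 / 0 / -1, region counts are averaged over
trials, and GAS is the mean gamma activated count over 1-3 s.
"""

import numpy as np

from gaspread import (SimulationConfig, bandpower_pipeline,
                      binarize_activation, calibrate_thresholds, compute_gas,
                      spread_timeseries)
from gaspread.simulate import participant_rngs, simulate_participant_epochs

cfg = SimulationConfig(n_hc=4, n_als=4, n_regions=52, n_trials=6, seed=2)

bandpower = {}
groups = {}
for pid, group, rng in participant_rngs(cfg):
    ep = simulate_participant_epochs(cfg, group, rng, pid)
    bandpower[pid] = bandpower_pipeline(ep)
    groups[pid] = group

thresholds = calibrate_thresholds(
    [bandpower[p] for p in bandpower if groups[p] == "HC"])
gi = thresholds.band_names.index("gamma")
print(f"gamma cut-offs (mean over regions): "
      f"upper {thresholds.upper[:, gi].mean():+.2f}, "
      f"lower {thresholds.lower[:, gi].mean():+.2f}")

print("\nper-participant gamma activation spread (GAS), 1-3 s window:")
for pid, bp in bandpower.items():
    spread = spread_timeseries(binarize_activation(bp, thresholds),
                               participant_id=pid, group=groups[pid])
    gas = compute_gas(spread)
    print(f"  {pid} ({groups[pid]}): GAS = {gas.gas:5.2f} of 52 regions")
print("\nALS-like participants activate several times more regions than "
      "HCs during sustained grip - the disease phenotype this statistic "
      "quantifies.")
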