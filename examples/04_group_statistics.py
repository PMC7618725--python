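"""Permutation GLM inference: group contrast and clinical association.

The ALS-vs-HC contrast runs over every spread element (activated and
deactivated counts per band and 100 ms bin, plus the scalar GAS values)
with age, sex and missing-MRI confounds, Freedman-Lane permutations, and
max-|t| family-wise correction across the whole family. The clinical
model regresses progression rate on GAS within the ALS group.
"""

import numpy as np
import pandas as pd

from gaspread import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(sim=SimulationConfig(n_hc=6, n_als=6, n_regions=52,
                                     n_trials=6),
                n_perm=300, seed=4, out_dir="scratch/example_stats")
run_pipeline(cfg)

gas = pd.read_csv("scratch/example_stats/gas.csv")
print("group GAS means:",
      gas.groupby("group").gas_gamma.mean().round(2).to_dict())

stats = pd.read_csv("scratch/example_stats/stats_group.csv")
row = stats[stats.element == "gas:gamma"].iloc[0]
print(f"gas:gamma contrast: beta = {row.beta:+.2f}, t = {row.t:+.2f}, "
      f"p_fwe = {row.p_fwe:.4f} ({row.n_perm} permutations)")

sig = stats[stats.p_fwe < 0.05]
print(f"{len(sig)} of {len(stats)} family elements significant after "
      "max-statistic correction; the significant gamma bins all fall in "
      "the 1-3 s tonic window:")
print(sig[sig.element.str.startswith("activated:gamma")].element.tolist()[:8])

clin = pd.read_csv("scratch/example_stats/stats_clinical.csv")
prog = clin[clin.element == "progression_rate"].iloc[0]
print(f"\nprogression_rate ~ GAS (ALS only): beta = {prog.beta:+.3f}, "
      f"p = {prog.p_uncorrected:.3f}  (tiny n here; see tests for the "
      "powered n=42 recovery)")
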