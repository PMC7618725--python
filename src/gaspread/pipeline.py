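"""End-to-end pipeline driver: simulate -> band power -> activation -> stats -> report.

A run is fully described by a RunConfig (serializable to/from YAML) and
is deterministic: rerunning with the same config and seed reproduces
every CSV byte for byte; the manifest records a checksum per output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .activation import (binarize_activation, calibrate_thresholds, compute_gas,
                         spread_timeseries)
from .behavior import compare_behavior
from .layout import default_layout
from .report import (plot_region_map, plot_spread_timecourse,
                     region_activation_proportion, render_activation_frames)
from .simulate import SimulationConfig, participant_rngs, simulate_behavior_table, \
    simulate_clinical_table, simulate_participant_epochs
from .spectral import bandpower_pipeline
from .stats import CLINICAL_OUTCOMES, clinical_association, group_contrast_spread

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("gaspread")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    baseline_window: tuple[float, float] = (-0.8, -0.1)
    bin_width: float = 0.1
    sd_multiplier: float = 2.0
    gas_window: tuple[float, float] = (1.0, 3.0)
    n_perm: int = 5000
    seed: int = 0
    out_dir: str = "gas_run"
    make_videos: bool = False
    n_video_participants: int = 1
    clinical_outcomes: tuple[str, ...] = ("ALSFRS_R", "progression_rate",
                                          "ECAS", "UMN_score", "NfL",
                                          "fine_motor_subscore")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["burst_params"] = {
            band: {g: dataclasses.asdict(bp) for g, bp in per.items()}
            for band, per in self.sim.burst_params.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .simulate import BandBurstParams

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        sim_raw = raw.pop("sim", {})
        bp_raw = sim_raw.pop("burst_params", None)
        for key in ("epoch_window", "beta_erd_window", "suppression_window"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "behavior_means" in sim_raw:
            sim_raw["behavior_means"] = {k: tuple(v) for k, v in
                                         sim_raw["behavior_means"].items()}
        sim_kwargs = dict(sim_raw)
        if bp_raw is not None:
            sim_kwargs["burst_params"] = {
                band: {g: BandBurstParams(**{**d, "active_window":
                                             tuple(d.get("active_window", (1.0, 3.0)))})
                       for g, d in per.items()}
                for band, per in bp_raw.items()}
        for key in ("baseline_window", "gas_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "clinical_outcomes" in raw:
            raw["clinical_outcomes"] = tuple(raw["clinical_outcomes"])
        cfg = cls(sim=SimulationConfig(**sim_kwargs), **raw)
        cfg.sim.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated cohort.

    Writes, under config.out_dir: gas.csv (participant-level GAS),
    thresholds.csv, spread.h5, stats_group.csv, stats_clinical.csv,
    behavior_tests.csv, clinical.csv, behavior.csv, figures, optional
    video frames, and manifest.json (config + per-file sha256 for CSVs).
    Returns the manifest dict.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    stage = "config"
    try:
        sim.validate()

        stage = "simulate"
        log.info("simulating %d HC + %d ALS participants", sim.n_hc, sim.n_als)
        behavior = simulate_behavior_table(sim)

        stage = "tfr"
        spreads, gas_rows = [], []
        bandpower_hc = []
        per_part = []
        for pid, group, rng in participant_rngs(sim):
            ep = simulate_participant_epochs(sim, group, rng, participant_id=pid)
            bp = bandpower_pipeline(ep, baseline_window=config.baseline_window,
                                    bin_width=config.bin_width)
            per_part.append((pid, group, bp))
            if group == "HC":
                bandpower_hc.append(bp)
            log.debug("band power done for %s", pid)

        stage = "activate"
        thresholds = calibrate_thresholds(bandpower_hc,
                                          sd_multiplier=config.sd_multiplier)
        gio.write_thresholds(out / "thresholds.csv", thresholds)
        actmaps = {}
        for pid, group, bp in per_part:
            am = binarize_activation(bp, thresholds)
            actmaps[pid] = am
            s = spread_timeseries(am, participant_id=pid, group=group)
            spreads.append(s)
            row = {"participant_id": pid, "group": group}
            for band in ("gamma", "high_gamma"):
                if band in s.band_names:
                    row[f"gas_{band}"] = compute_gas(s, config.gas_window, band).gas
            gas_rows.append(row)
        gas_df = pd.DataFrame(gas_rows)
        gas_df.to_csv(out / "gas.csv", index=False)
        gio.write_spreads(out / "spread.h5", spreads)

        # clinical table regenerated with the measured GAS as the latent
        # spread, so the planted clinical association refers to the
        # participant's own measured phenotype
        stage = "clinical"
        als_gas = gas_df.loc[gas_df.group == "ALS", "gas_gamma"].to_numpy()
        clinical = simulate_clinical_table(sim, latent_spread=als_gas,
                                           participant_ids=list(gas_df.participant_id))
        clinical.to_csv(out / "clinical.csv", index=False)
        behavior.to_csv(out / "behavior.csv", index=False)

        stage = "stats"
        contrast = group_contrast_spread(spreads, clinical,
                                         n_perm=config.n_perm, seed=config.seed,
                                         gas_window=config.gas_window)
        contrast.to_frame().to_csv(out / "stats_group.csv", index=False)
        clin_frames = []
        for outcome in config.clinical_outcomes:
            if outcome not in CLINICAL_OUTCOMES:
                raise ValueError(f"unknown clinical outcome {outcome!r}")
            res = clinical_association(als_gas, clinical, outcome,
                                       n_perm=config.n_perm, seed=config.seed)
            clin_frames.append(res.to_frame())
        clin_df = (pd.concat(clin_frames, ignore_index=True) if clin_frames
                   else pd.DataFrame(columns=["element", "beta", "t",
                                              "p_uncorrected", "p_fwe",
                                              "family", "n_perm", "seed", "df"]))
        clin_df.to_csv(out / "stats_clinical.csv", index=False)
        compare_behavior(behavior).to_csv(out / "behavior_tests.csv", index=False)

        stage = "report"
        layout = default_layout(sim.n_regions)
        figures = []
        for band in spreads[0].band_names:
            p = out / f"spread_{band}.png"
            plot_spread_timecourse(spreads, band, window=config.gas_window, out=p)
            figures.append(p)
        gamma_i = spreads[0].band_names.index("gamma") if "gamma" in spreads[0].band_names else 0
        for group in ("HC", "ALS"):
            props = np.mean([region_activation_proportion(actmaps[pid], gamma_i,
                                                          config.gas_window)
                             for pid, g, _ in per_part if g == group], axis=0)
            p = out / f"region_map_{group}.png"
            plot_region_map(props, layout, title=f"gamma activation ({group})",
                            out=p, vmax=max(float(np.max(props)), 1e-9))
            figures.append(p)
        videos = []
        if config.make_videos:
            for pid, group, _ in per_part[:config.n_video_participants]:
                am = actmaps[pid]
                per_region = (am.state[:, :, gamma_i, :] == 1).mean(axis=0)
                frames = render_activation_frames(
                    per_region, layout, am.bin_edges,
                    out / f"video_{pid}", band="gamma")
                videos.append({"participant_id": pid, "n_frames": len(frames)})

        stage = "manifest"
        config.to_yaml(out / "config.yaml")
        csvs = sorted(str(p.name) for p in out.glob("*.csv"))
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t_start, 2),
            "outputs": {name: _sha256(out / name) for name in csvs},
            "other_outputs": sorted(str(p.name) for p in out.iterdir()
                                    if p.suffix not in (".csv",)
                                    and p.name != "manifest.json"),
            "videos": videos,
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        return manifest
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-tag with the failing stage
        raise PipelineError(stage, str(e)) from e
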