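"""Synthetic parcellated MEG cohorts for the gamma-activation-spread pipeline.

Emulates the data the analysis assumes: per-participant epoched source
time courses (trials x regions x samples) containing 1/f background
noise plus band-limited oscillatory events, together with a clinical
covariate table and a behavioral summary table.

Simulated signal phenomena
--------------------------
* beta (13-30 Hz) event-related desynchronization: an ongoing beta
  oscillation in a small set of "motor" regions whose amplitude dips
  during the movement period (0-3 s after the trigger cue);
* gamma (30-48 Hz) and high-gamma (52-80 Hz) activations: Hann-windowed
  sinusoid packets placed in a per-trial random subset of regions during
  the tonic grip window (1-3 s);
* gamma deactivations: an ongoing gamma-band oscillation present in all
  regions that is suppressed during the tonic window in a per-trial
  subset of regions.

The ALS-like group draws more active regions and longer burst durations
than the healthy-control (HC) group, and fewer suppressed regions, so the
downstream spread statistics separate the groups the way the disease
phenotype is described: spatially broader, longer-lasting gamma
activation and reduced gamma deactivation.

Every output is a pure function of (config, seed): per-participant RNG
streams are spawned from the master seed with ``numpy.random.SeedSequence``
spawn keys, so regenerating participant k alone reproduces exactly the
data participant k had in a full-cohort run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BandBurstParams",
    "SimulationConfig",
    "ParcelEpochs",
    "simulate_participant_epochs",
    "simulate_cohort_epochs",
    "simulate_clinical_table",
    "simulate_behavior_table",
    "default_burst_params",
]

GROUPS = ("HC", "ALS")

#: canonical band edges, Hz
BAND_EDGES = {"beta": (13.0, 30.0), "gamma": (30.0, 48.0), "high_gamma": (52.0, 80.0)}


@dataclass(frozen=True)
class BandBurstParams:
    """Burst-generation parameters for one band in one group.

    rate
        expected bursts per trial per active region (Poisson).
    duration_mean
        mean burst duration, s (truncated normal, sd = 0.25 * mean,
        floor 0.1 s).
    amplitude
        peak amplitude of the Hann-windowed sinusoid, a.u.
    n_active_regions_mean
        expected number of regions carrying bursts per trial (binomial
        draw over regions).
    active_window
        (start, end) s relative to the trigger in which bursts live.
    """

    rate: float = 2.5
    duration_mean: float = 0.5
    amplitude: float = 2.0
    n_active_regions_mean: float = 7.0
    active_window: tuple[float, float] = (1.0, 3.0)


def default_burst_params() -> dict[str, dict[str, BandBurstParams]]:
    """Per-band, per-group burst parameters.

    The gamma / high-gamma active-region means mirror the group spread
    phenotype the analysis is built to detect (ALS spatially broader and
    longer than HC); beta carries no group difference.
    """
    return {
        "gamma": {
            "HC": BandBurstParams(rate=4.0, duration_mean=1.0, amplitude=0.8,
                                  n_active_regions_mean=7.0),
            "ALS": BandBurstParams(rate=4.0, duration_mean=1.4, amplitude=0.8,
                                   n_active_regions_mean=20.0),
        },
        "high_gamma": {
            "HC": BandBurstParams(rate=4.0, duration_mean=0.6, amplitude=0.8,
                                  n_active_regions_mean=18.0),
            "ALS": BandBurstParams(rate=4.0, duration_mean=0.9, amplitude=0.8,
                                   n_active_regions_mean=34.0),
        },
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions the pipeline targets:
    33 HC / 42 ALS participants, 120 trials of 6 s (-1 to 5 s around the
    trigger cue), 52 cortical regions, tonic grip window 1-3 s.
    """

    n_hc: int = 33
    n_als: int = 42
    n_regions: int = 52
    n_trials: int = 120
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-1.0, 5.0)
    #: seconds of real signal generated beyond each epoch edge, trimmed
    #: after time-frequency filtering downstream
    pad: float = 0.5
    burst_params: Mapping[str, Mapping[str, BandBurstParams]] = field(
        default_factory=default_burst_params)
    noise_sd: float = 1.0
    # beta event-related desynchronization (shared by both groups)
    n_motor_regions: int = 6
    beta_amplitude: float = 1.2
    beta_erd_depth: float = 0.6
    beta_erd_window: tuple[float, float] = (0.0, 3.0)
    # ongoing gamma oscillation suppressed ("deactivated") during tonic grip
    gamma_background_amplitude: float = 4.0
    n_suppressed_regions_mean: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 8.0, "ALS": 4.0})
    suppression_depth: float = 1.0
    suppression_window: tuple[float, float] = (1.0, 3.0)
    # clinical model
    gas_progression_slope: float = 0.12
    progression_rate_mean: float = 0.4
    progression_noise_sd: float = 0.2
    fine_motor_slope: float = 0.8
    # behavioral model: per-metric (mean, sd); grip target is 12 N
    behavior_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "grip_length": (3.0, 0.3),
            "grip_strength": (12.0, 1.5),
            "reaction_time": (0.35, 0.08),
            "accuracy": (0.92, 0.05),
        })
    #: optional additive shift applied to the ALS group per metric (power checks)
    behavior_group_shift: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        f_max = max(hi for _, hi in BAND_EDGES.values())
        if self.fs <= 2 * f_max:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for simulated bands (max {f_max} Hz)")
        t0, t1 = self.epoch_window
        if not (t0 <= 1.0 and t1 >= 3.0):
            raise ValueError("epoch_window must span the 1-3 s tonic window")
        for band, per_group in self.burst_params.items():
            for g, bp in per_group.items():
                if bp.rate < 0 or bp.duration_mean <= 0:
                    raise ValueError(f"invalid burst params for {band}/{g}")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0 + 2 * self.pad) * self.fs))

    def times(self) -> np.ndarray:
        """Sample times (s, trigger-relative) including padding."""
        t0 = self.epoch_window[0] - self.pad
        return t0 + np.arange(self.n_samples) / self.fs


@dataclass
class ParcelEpochs:
    """One participant's epoched parcel time courses.

    data is trials x regions x samples; ``t0_offset`` is the time of the
    first sample relative to the trigger and ``pad`` the seconds of extra
    signal at each edge (generated rather than reflected, so that
    wavelet filtering sees real signal and the core -1..5 s window is
    artifact-free after trimming).
    """

    participant_id: str
    group: str
    data: np.ndarray
    fs: float
    t0_offset: float
    pad: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 3:
            raise ValueError("data must be trials x regions x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.data.shape[2]) / self.fs


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian noise with power-spectral slope -1 (amplitude ~ f^-1/2)."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** -0.5
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    std = out.std()
    if std > 0:
        out *= sd / std
    return out


def _dip_envelope(t: np.ndarray, window: tuple[float, float], depth: float,
                  ramp: float = 0.2) -> np.ndarray:
    """Envelope equal to 1 outside `window` and (1 - depth) inside, with
    raised-cosine ramps of `ramp` seconds just inside each edge."""
    w0, w1 = window
    dip = np.zeros_like(t)  # 0 outside, 1 fully inside
    inside = (t >= w0) & (t <= w1)
    dip[inside] = 1.0
    rise = inside & (t < w0 + ramp)
    dip[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - w0) / ramp))
    fall = inside & (t > w1 - ramp)
    dip[fall] = 0.5 * (1 - np.cos(np.pi * (w1 - t[fall]) / ramp))
    return 1.0 - depth * dip


def _tukey(n: int, alpha: float = 0.3) -> np.ndarray:
    """Flat-topped taper: raised-cosine ramps over alpha/2 of each end.

    Burst packets use this rather than a full raised cosine so that a
    burst's power sits near its plateau for most of its duration —
    tonic-grip gamma synchronization is sustained, not a single swell."""
    from scipy.signal import windows

    return windows.tukey(n, alpha)


def _draw_count(rng: np.random.Generator, mean: float, n_max: int) -> int:
    """Binomial draw over n_max slots with the requested mean (clipped)."""
    p = min(max(mean / n_max, 0.0), 1.0)
    return int(rng.binomial(n_max, p))


def _add_bursts(data: np.ndarray, t: np.ndarray, fs: float,
                rng: np.random.Generator, band: tuple[float, float],
                bp: BandBurstParams, n_regions: int) -> np.ndarray:
    """Place Hann-windowed sinusoid packets; returns per-trial active-region
    indicator (trials x regions) for ground-truth bookkeeping."""
    n_trials = data.shape[0]
    f_lo, f_hi = band
    w0, w1 = bp.active_window
    active = np.zeros((n_trials, n_regions), dtype=bool)
    for tr in range(n_trials):
        n_active = _draw_count(rng, bp.n_active_regions_mean, n_regions)
        if n_active == 0:
            continue
        regions = rng.choice(n_regions, size=n_active, replace=False)
        active[tr, regions] = True
        for r in regions:
            n_bursts = max(1, rng.poisson(bp.rate))
            for _ in range(n_bursts):
                dur = max(0.1, rng.normal(bp.duration_mean, 0.25 * bp.duration_mean))
                dur = min(dur, w1 - w0)
                start = rng.uniform(w0, w1 - dur)
                i0 = int(np.searchsorted(t, start))
                n = int(round(dur * fs))
                if n < 2:
                    continue
                freq = rng.uniform(f_lo, f_hi)
                phase = rng.uniform(0, 2 * np.pi)
                tt = np.arange(n) / fs
                packet = (bp.amplitude * _tukey(n)
                          * np.cos(2 * np.pi * freq * tt + phase))
                data[tr, r, i0:i0 + n] += packet[: data.shape[2] - i0]
    return active


def simulate_participant_epochs(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    participant_id: str = "sim",
    return_truth: bool = False,
):
    """Simulate one participant's trials x regions x samples epoch block.

    The returned epochs include ``config.pad`` seconds of real signal
    beyond each epoch edge (see ParcelEpochs.pad). With all burst
    amplitudes at zero, no beta oscillation and no gamma background the
    output is pure 1/f noise.

    When ``return_truth`` is set, also returns a dict with the per-trial
    ground-truth active-region indicators per band, for oracle tests.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    n_samp = config.n_samples
    t = config.times()
    data = _one_over_f_noise(
        rng, (config.n_trials, config.n_regions), n_samp, config.fs, config.noise_sd)

    # beta ERD: ongoing oscillation in motor regions dipping during movement
    if config.beta_amplitude > 0 and config.n_motor_regions > 0:
        env = _dip_envelope(t, config.beta_erd_window, config.beta_erd_depth)
        n_motor = min(config.n_motor_regions, config.n_regions)
        for r in range(n_motor):
            freq = rng.uniform(*BAND_EDGES["beta"])
            phase = rng.uniform(0, 2 * np.pi)
            data[:, r, :] += (config.beta_amplitude * env
                              * np.cos(2 * np.pi * freq * t + phase))

    # ongoing gamma background, suppressed in a per-trial subset of regions
    if config.gamma_background_amplitude > 0:
        supp_env = _dip_envelope(t, config.suppression_window,
                                 config.suppression_depth)
        supp_mean = float(config.n_suppressed_regions_mean.get(group, 0.0))
        supp_mask = np.zeros((config.n_trials, config.n_regions), dtype=bool)
        for tr in range(config.n_trials):
            n_supp = _draw_count(rng, supp_mean, config.n_regions)
            if n_supp:
                supp_mask[tr, rng.choice(config.n_regions, size=n_supp,
                                         replace=False)] = True
        shape = (config.n_trials, config.n_regions, 1)
        freq = rng.uniform(*BAND_EDGES["gamma"], size=shape)
        phase = rng.uniform(0, 2 * np.pi, size=shape)
        env = np.where(supp_mask[:, :, None], supp_env, 1.0)
        data += (config.gamma_background_amplitude * env
                 * np.cos(2 * np.pi * freq * t + phase))

    truth: dict[str, np.ndarray] = {}
    for band_name, per_group in config.burst_params.items():
        bp = per_group.get(group)
        if bp is None or bp.amplitude == 0:
            continue
        truth[band_name] = _add_bursts(
            data, t, config.fs, rng, BAND_EDGES[band_name], bp, config.n_regions)

    epochs = ParcelEpochs(
        participant_id=participant_id, group=group, data=data, fs=config.fs,
        t0_offset=config.epoch_window[0] - config.pad, pad=config.pad)
    if return_truth:
        return epochs, truth
    return epochs


def participant_rngs(config: SimulationConfig) -> list[tuple[str, str, np.random.Generator]]:
    """(participant_id, group, rng) for the whole cohort, derived from the
    master seed via SeedSequence spawn keys (stable under partial
    regeneration: stream k does not depend on how many others are drawn)."""
    out = []
    idx = 0
    for group, n in (("HC", config.n_hc), ("ALS", config.n_als)):
        for j in range(n):
            ss = np.random.SeedSequence(config.seed, spawn_key=(idx,))
            out.append((f"{group.lower()}{j + 1:03d}", group,
                        np.random.default_rng(ss)))
            idx += 1
    return out


def simulate_cohort_epochs(config: SimulationConfig):
    """Yield ParcelEpochs for every participant in the configured cohort."""
    for pid, group, rng in participant_rngs(config):
        yield simulate_participant_epochs(config, group, rng, participant_id=pid)


def simulate_clinical_table(config: SimulationConfig,
                            latent_spread: np.ndarray | None = None,
                            participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Clinical covariate table with a planted spread -> progression link.

    For ALS participants the ALSFRS-R progression rate is generated as
    ``rate = rate_mean + slope * z(latent_spread) + noise`` (clipped so the
    ALSFRS-R score stays in 0..48), the symptom duration is drawn
    log-normally, and the ALSFRS-R score is back-derived and rounded to an
    integer; the progression rate is then recomputed from the rounded
    score so the identity ``rate = (48 - ALSFRS_R) / duration`` holds to
    machine precision.

    latent_spread: one value per ALS participant (e.g. each participant's
    GAS); standardized internally. None plants no association.
    """
    config.validate()
    if not np.isfinite(config.gas_progression_slope):
        raise ValueError("gas_progression_slope must be finite")
    n_hc, n_als = config.n_hc, config.n_als
    if n_hc + n_als == 0:
        raise ValueError("empty cohort")
    if latent_spread is not None:
        latent_spread = np.asarray(latent_spread, dtype=float)
        if latent_spread.shape != (n_als,):
            raise ValueError(
                f"latent_spread must have one value per ALS participant ({n_als})")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(10_000,)))
    if participant_ids is None:
        participant_ids = ([f"hc{j + 1:03d}" for j in range(n_hc)]
                           + [f"als{j + 1:03d}" for j in range(n_als)])
    group = ["HC"] * n_hc + ["ALS"] * n_als

    # demographics roughly matching the target cohort marginals
    age = np.concatenate([
        np.clip(rng.normal(61.8, 16.4, n_hc), 25, 90),
        np.clip(rng.normal(61.0, 12.7, n_als), 25, 90),
    ]).round(1)
    sex = np.concatenate([
        rng.choice(["F", "M"], n_hc, p=[0.515, 0.485]),
        rng.choice(["F", "M"], n_als, p=[0.333, 0.667]),
    ])
    missing_mri = rng.binomial(1, 0.15, n_hc + n_als)

    if latent_spread is not None and n_als > 1 and latent_spread.std() > 0:
        z = (latent_spread - latent_spread.mean()) / latent_spread.std()
    else:
        z = np.zeros(n_als)

    duration = np.clip(rng.lognormal(np.log(24.0), 0.65, n_als), 3.0, 120.0).round(1)
    rate_raw = (config.progression_rate_mean
                + config.gas_progression_slope * z
                + rng.normal(0, config.progression_noise_sd, n_als))
    rate_raw = np.clip(rate_raw, 0.0, 48.0 / duration)
    alsfrs = np.round(48.0 - rate_raw * duration).astype(int)
    alsfrs = np.clip(alsfrs, 0, 48)
    progression_rate = (48.0 - alsfrs) / duration

    ecas_hc = np.clip(rng.normal(118.8, 9.6, n_hc), 0, 136).round(0)
    ecas_als = np.clip(rng.normal(112.6, 9.2, n_als), 0, 136).round(0)
    umn = np.clip(np.round(rng.normal(10.1, 3.8, n_als)), 0, 20).astype(int)
    nfl = rng.lognormal(np.log(70.0), 0.6, n_als).round(1)  # pg/mL, no GAS link
    fine_motor = np.clip(
        np.round(6.4 - config.fine_motor_slope * z + rng.normal(0, 1.2, n_als)),
        0, 8).astype(int)

    df = pd.DataFrame({
        "participant_id": participant_ids,
        "group": group,
        "age": age,
        "sex": sex,
        "missing_mri": missing_mri,
    })
    for col in ("ALSFRS_R", "symptom_duration", "progression_rate", "ECAS",
                "UMN_score", "NfL", "fine_motor_subscore"):
        df[col] = np.nan
    df.loc[df.group == "ALS", "ALSFRS_R"] = alsfrs.astype(float)
    df.loc[df.group == "ALS", "symptom_duration"] = duration
    df.loc[df.group == "ALS", "progression_rate"] = progression_rate
    df.loc[df.group == "HC", "ECAS"] = ecas_hc
    df.loc[df.group == "ALS", "ECAS"] = ecas_als
    df.loc[df.group == "ALS", "UMN_score"] = umn.astype(float)
    df.loc[df.group == "ALS", "NfL"] = nfl
    df.loc[df.group == "ALS", "fine_motor_subscore"] = fine_motor.astype(float)
    return df


def simulate_behavior_table(config: SimulationConfig,
                            participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Behavioral summaries (grip length/strength, reaction time, accuracy).

    Both groups are drawn from identical distributions by default (null
    group difference, as observed behaviorally in the target study); a
    per-metric additive ALS shift is available for power checks.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(20_000,)))
    n = config.n_hc + config.n_als
    group = ["HC"] * config.n_hc + ["ALS"] * config.n_als
    if participant_ids is None:
        participant_ids = ([f"hc{j + 1:03d}" for j in range(config.n_hc)]
                           + [f"als{j + 1:03d}" for j in range(config.n_als)])
    df = pd.DataFrame({"participant_id": participant_ids, "group": group})
    is_als = np.asarray(group) == "ALS"
    for metric, (mu, sd) in config.behavior_means.items():
        x = rng.normal(mu, sd, n)
        x[is_als] += config.behavior_group_shift.get(metric, 0.0)
        if metric == "accuracy":
            x = np.clip(x, 0.0, 1.0)
        else:
            x = np.clip(x, 1e-3, None)
        df[metric] = x
    return df
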