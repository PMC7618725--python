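"""HC-calibrated activation detection and the gamma-activation-spread (GAS) statistic.

The detection rule is deliberately simple: for every region and band,
activation / deactivation cut-offs are placed two (pooled) standard
deviations above / below the mean of the healthy-control group's
trial-averaged power time courses, and every trial x region x band x
100 ms bin is then scored ternary — activated (+1) above the upper
cut-off, deactivated (-1) below the lower one, neither (0) otherwise,
with strict inequalities so exact-threshold values score 0.

Pooling choice: each HC participant contributes their trial-averaged bin
values over the full epoch; the pooled mean and sample SD (ddof=1) over
participants x bins give one threshold pair per region x band. A
degenerate SD of 0 collapses both cut-offs onto the mean and every state
becomes 0 (no error raised).

Spread statistics count regions: the activated count at a band x bin is
the across-trial mean of the number of regions in state +1 (so counts
are real-valued in [0, n_regions]); the deactivated count mirrors -1.
GAS is the mean gamma activated count over the bins whose centers lie in
the tonic grip window (1-3 s post trigger, closed interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import BandPowerBins

__all__ = ["ThresholdTable", "ActivationMap", "SpreadSeries", "GASValue",
           "calibrate_thresholds", "binarize_activation", "spread_timeseries",
           "compute_gas"]


@dataclass
class ThresholdTable:
    """Per region x band activation cut-offs calibrated on the HC group."""

    center: np.ndarray  # regions x bands, pooled HC mean
    sd: np.ndarray      # regions x bands, pooled sample SD (ddof=1)
    band_names: tuple[str, ...]
    sd_multiplier: float = 2.0
    n_pooled: int = 0

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.sd_multiplier * self.sd

    @property
    def lower(self) -> np.ndarray:
        return self.center - self.sd_multiplier * self.sd

    def to_frame(self) -> pd.DataFrame:
        n_regions = self.center.shape[0]
        rows = []
        for r in range(n_regions):
            for bi, band in enumerate(self.band_names):
                rows.append({"region": r, "band": band,
                             "center": self.center[r, bi], "sd": self.sd[r, bi],
                             "upper": self.upper[r, bi], "lower": self.lower[r, bi],
                             "n_pooled": self.n_pooled})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sd_multiplier: float = 2.0) -> "ThresholdTable":
        bands = tuple(pd.unique(df["band"]))
        regions = np.sort(pd.unique(df["region"]))
        center = np.empty((len(regions), len(bands)))
        sd = np.empty_like(center)
        for bi, band in enumerate(bands):
            sub = df[df["band"] == band].sort_values("region")
            center[:, bi] = sub["center"].to_numpy()
            sd[:, bi] = sub["sd"].to_numpy()
            # recover the multiplier the file was written with
            pos = sub["sd"].to_numpy() > 0
            if pos.any():
                sd_multiplier = float(
                    ((sub["upper"].to_numpy() - sub["center"].to_numpy())[pos]
                     / sub["sd"].to_numpy()[pos]).mean())
        return cls(center=center, sd=sd, band_names=bands,
                   sd_multiplier=sd_multiplier,
                   n_pooled=int(df["n_pooled"].iloc[0]) if len(df) else 0)


@dataclass
class ActivationMap:
    """Ternary states, trials x regions x bands x bins, values in {-1, 0, +1}."""

    state: np.ndarray
    band_names: tuple[str, ...]
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        bad = ~np.isin(self.state, (-1, 0, 1))
        if bad.any():
            raise ValueError("activation states must be in {-1, 0, +1}")


@dataclass
class SpreadSeries:
    """Trial-averaged counts of activated / deactivated regions, bands x bins."""

    activated_count: np.ndarray
    deactivated_count: np.ndarray
    band_names: tuple[str, ...]
    bin_edges: np.ndarray
    participant_id: str = ""
    group: str = ""

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def band_index(self, band: str) -> int:
        return self.band_names.index(band)


@dataclass(frozen=True)
class GASValue:
    """Mean activated-region count for one band over the tonic window."""

    gas: float
    window: tuple[float, float]
    band: str


def calibrate_thresholds(hc_bandpower: Sequence[BandPowerBins],
                         sd_multiplier: float = 2.0) -> ThresholdTable:
    """Pool the HC group's trial-averaged bin values and set cut-offs.

    Every HC participant must share the region / band / bin grid. At
    least two participants are required (the pooled sample SD uses
    ddof=1 and single-participant calibration would hide that the
    thresholds hinge on between-subject spread).
    """
    if len(hc_bandpower) < 2:
        raise ValueError("threshold calibration needs at least 2 HC participants")
    ref = hc_bandpower[0]
    for bp in hc_bandpower[1:]:
        if (bp.value.shape[1:] != ref.value.shape[1:]
                or bp.band_names != ref.band_names
                or not np.allclose(bp.bin_edges, ref.bin_edges)):
            raise ValueError("HC band-power grids do not match")
    # participants x regions x bands x bins
    pooled = np.stack([bp.trial_mean() for bp in hc_bandpower], axis=0)
    n_part, n_regions, n_bands, n_bins = pooled.shape
    flat = pooled.transpose(1, 2, 0, 3).reshape(n_regions, n_bands, -1)
    center = flat.mean(axis=2)
    sd = flat.std(axis=2, ddof=1)
    return ThresholdTable(center=center, sd=sd, band_names=ref.band_names,
                          sd_multiplier=sd_multiplier,
                          n_pooled=n_part * n_bins)


def binarize_activation(bandpower: BandPowerBins, thresholds: ThresholdTable,
                        statistic: str = "per_trial") -> ActivationMap:
    """Score every cell ternary against the calibrated cut-offs.

    statistic='per_trial' (default) scores each trial's bin values and
    leaves the trial axis intact; 'trial_mean' scores the trial-averaged
    time course (output has a singleton trial axis), the statistic the
    thresholds themselves are calibrated on.
    Strict inequalities: a value exactly at a cut-off scores 0.
    """
    if bandpower.band_names != thresholds.band_names:
        raise ValueError("band names do not match thresholds")
    if bandpower.value.shape[1] != thresholds.center.shape[0]:
        raise ValueError("region count does not match thresholds")
    if not np.all(np.isfinite(bandpower.value)):
        raise ValueError("non-finite band-power values")
    if statistic == "per_trial":
        v = bandpower.value
    elif statistic == "trial_mean":
        v = bandpower.trial_mean()[None]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    upper = thresholds.upper[None, :, :, None]
    lower = thresholds.lower[None, :, :, None]
    state = np.zeros(v.shape, dtype=np.int8)
    state[v > upper] = 1
    state[v < lower] = -1
    return ActivationMap(state=state, band_names=bandpower.band_names,
                         bin_edges=bandpower.bin_edges)


def spread_timeseries(actmap: ActivationMap, participant_id: str = "",
                      group: str = "") -> SpreadSeries:
    """Region counts per band x bin, averaged over trials."""
    act = (actmap.state == 1).sum(axis=1).mean(axis=0)
    deact = (actmap.state == -1).sum(axis=1).mean(axis=0)
    return SpreadSeries(activated_count=act, deactivated_count=deact,
                        band_names=actmap.band_names, bin_edges=actmap.bin_edges,
                        participant_id=participant_id, group=group)


def compute_gas(spread: SpreadSeries, window: tuple[float, float] = (1.0, 3.0),
                band: str = "gamma") -> GASValue:
    """Mean activated-region count over bins with centers inside `window`.

    Bin membership is decided by the bin center, closed interval (centers
    exactly at an endpoint are included); for the default -1..5 s epoch
    at 100 ms pitch that selects the 20 bins with centers 1.05..2.95 s.
    """
    centers = spread.bin_centers()
    sel = (centers >= window[0] - 1e-12) & (centers <= window[1] + 1e-12)
    if not sel.any():
        raise ValueError("no bins inside the requested window")
    bi = spread.band_index(band)
    return GASValue(gas=float(spread.activated_count[bi, sel].mean()),
                    window=window, band=band)
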