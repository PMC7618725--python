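"""HDF5 container and CSV round-trips for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .activation import SpreadSeries, ThresholdTable
from .simulate import ParcelEpochs
from .spectral import BandPowerBins

__all__ = ["write_epochs", "read_epochs", "write_bandpower", "read_bandpower",
           "write_spreads", "read_spreads", "write_thresholds", "read_thresholds"]


def write_epochs(path: str | Path, epochs_iter: Iterable[ParcelEpochs]) -> None:
    """One HDF5 group per participant: dataset `data` (float32,
    trials x regions x samples) with fs / t0_offset / pad / group attrs."""
    with h5py.File(path, "w") as f:
        for ep in epochs_iter:
            g = f.create_group(ep.participant_id)
            g.create_dataset("data", data=ep.data.astype(np.float32))
            g.attrs["fs"] = ep.fs
            g.attrs["t0_offset"] = ep.t0_offset
            g.attrs["pad"] = ep.pad
            g.attrs["group"] = ep.group
            g.attrs["participant_id"] = ep.participant_id


def read_epochs(path: str | Path) -> list[ParcelEpochs]:
    out = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            g = f[pid]
            out.append(ParcelEpochs(
                participant_id=str(g.attrs["participant_id"]),
                group=str(g.attrs["group"]),
                data=g["data"][()].astype(np.float64),
                fs=float(g.attrs["fs"]),
                t0_offset=float(g.attrs["t0_offset"]),
                pad=float(g.attrs["pad"])))
    return out


def write_bandpower(path: str | Path, items: dict[str, BandPowerBins]) -> None:
    with h5py.File(path, "w") as f:
        for pid, bp in items.items():
            g = f.create_group(pid)
            g.create_dataset("bandpower", data=bp.value.astype(np.float32))
            g.attrs["bin_edges"] = bp.bin_edges
            g.attrs["band_names"] = list(bp.band_names)
            if bp.baseline_window is not None:
                g.attrs["baseline_window"] = list(bp.baseline_window)


def read_bandpower(path: str | Path) -> dict[str, BandPowerBins]:
    out = {}
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            g = f[pid]
            bw = g.attrs.get("baseline_window")
            out[pid] = BandPowerBins(
                value=g["bandpower"][()].astype(np.float64),
                bin_edges=np.asarray(g.attrs["bin_edges"], dtype=float),
                band_names=tuple(str(b) for b in g.attrs["band_names"]),
                baseline_window=tuple(bw) if bw is not None else None)
    return out


def write_spreads(path: str | Path, spreads: Sequence[SpreadSeries]) -> None:
    with h5py.File(path, "w") as f:
        for s in spreads:
            g = f.create_group(s.participant_id)
            g.create_dataset("activated_count", data=s.activated_count)
            g.create_dataset("deactivated_count", data=s.deactivated_count)
            g.attrs["bin_edges"] = s.bin_edges
            g.attrs["band_names"] = list(s.band_names)
            g.attrs["group"] = s.group


def read_spreads(path: str | Path) -> list[SpreadSeries]:
    out = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            g = f[pid]
            out.append(SpreadSeries(
                activated_count=g["activated_count"][()],
                deactivated_count=g["deactivated_count"][()],
                band_names=tuple(str(b) for b in g.attrs["band_names"]),
                bin_edges=np.asarray(g.attrs["bin_edges"], dtype=float),
                participant_id=pid, group=str(g.attrs["group"])))
    return out


def write_thresholds(path: str | Path, thresholds: ThresholdTable) -> None:
    thresholds.to_frame().to_csv(path, index=False)


def read_thresholds(path: str | Path) -> ThresholdTable:
    return ThresholdTable.from_frame(pd.read_csv(path))
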