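"""Schematic 2-D parcel layout for activation maps and videos.

A flat stand-in for a cortical surface: each hemisphere is a disc of
region markers arranged on a sunflower (golden-angle) spiral, left disc
centered at x = -1.2, right at +1.2. Sufficient for the qualitative
"how many regions light up" readout; no anatomy involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParcelLayout", "default_layout"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class ParcelLayout:
    table: pd.DataFrame  # columns: id (1-based), name, x, y, hemisphere

    def __post_init__(self) -> None:
        if self.table["id"].duplicated().any():
            raise ValueError("region ids must be unique")
        if not np.all(np.isfinite(self.table[["x", "y"]].to_numpy())):
            raise ValueError("layout coordinates must be finite")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy()


def default_layout(n_regions: int = 52) -> ParcelLayout:
    half = (n_regions + 1) // 2
    rows = []
    rid = 1
    for hemi, cx in (("L", -1.2), ("R", 1.2)):
        n = half if hemi == "L" else n_regions - half
        k = np.arange(n)
        r = np.sqrt((k + 0.5) / n)
        th = k * _GOLDEN_ANGLE
        for j in range(n):
            rows.append({"id": rid, "name": f"{hemi}{j + 1:02d}",
                         "x": cx + r[j] * np.cos(th[j]),
                         "y": r[j] * np.sin(th[j]),
                         "hemisphere": hemi})
            rid += 1
    return ParcelLayout(pd.DataFrame(rows))
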