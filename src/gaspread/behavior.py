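"""Welch two-sample comparisons of behavioral / demographic summaries.

Provides both a raw-vector form and a summary-statistic form (mean, SD,
n per group) so printed cohort tables can be re-tested directly; the two
are algebraically identical. Two-sided p-values, Bonferroni correction
over a declared family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "WelchResult", "welch_from_summaries",
           "welch_from_vectors", "bonferroni", "compare_behavior",
           "BEHAVIOR_METRICS"]

BEHAVIOR_METRICS = ("grip_length", "grip_strength", "reaction_time", "accuracy")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("sd must be finite and non-negative")

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    p_bonferroni: float = np.nan
    degenerate: bool = False


def welch_from_summaries(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's t-test from (mean, sd, n) summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), df by
    Welch-Satterthwaite, two-sided p. Both SDs zero with equal means is
    degenerate and reported as t=0, p=1 with a flag.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    se2 = va + vb
    if se2 == 0:
        if a.mean == b.mean:
            return WelchResult(t=0.0, df=float(a.n + b.n - 2), p=1.0,
                               degenerate=True)
        return WelchResult(t=np.inf if a.mean > b.mean else -np.inf,
                           df=float(a.n + b.n - 2), p=0.0, degenerate=True)
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def welch_from_vectors(x: np.ndarray, y: np.ndarray) -> WelchResult:
    return welch_from_summaries(GroupSummary.from_vector(x),
                                GroupSummary.from_vector(y))


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, m * p))


def compare_behavior(table: pd.DataFrame,
                     metrics: tuple[str, ...] = BEHAVIOR_METRICS,
                     group_col: str = "group") -> pd.DataFrame:
    """Welch tests ALS vs HC per metric, Bonferroni family = the metrics.

    Returns a tidy frame mirroring a cohort-characteristics table: group
    means/SDs, t, Welch df, raw and corrected p.
    """
    groups = table[group_col].unique()
    if not {"HC", "ALS"} <= set(groups):
        raise ValueError("behavior table must contain both HC and ALS rows")
    rows = []
    m = len(metrics)
    for metric in metrics:
        if metric not in table.columns:
            raise ValueError(f"missing metric column {metric!r}")
        a = GroupSummary.from_vector(table.loc[table[group_col] == "ALS", metric])
        h = GroupSummary.from_vector(table.loc[table[group_col] == "HC", metric])
        res = welch_from_summaries(a, h)
        rows.append({
            "metric": metric,
            "als_mean": a.mean, "als_sd": a.sd, "als_n": a.n,
            "hc_mean": h.mean, "hc_sd": h.sd, "hc_n": h.n,
            "t": res.t, "df": res.df, "p": res.p,
            "p_bonferroni": bonferroni(res.p, m),
        })
    return pd.DataFrame(rows)
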