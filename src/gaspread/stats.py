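"""Permutation GLM inference for spread measures and clinical associations.

Group contrasts and clinical associations are ordinary-least-squares
GLMs with confound regressors (age, sex, missing structural MRI).
Significance comes from non-parametric permutation testing under the
Freedman-Lane scheme: the outcome is residualized on the confounds, the
residual rows are permuted, the reduced-model fit is added back, and the
full model is refit to build the null distribution of the contrast t.
Family-wise error across regions, time bins and bands is controlled with
the permutation distribution of the maximum |t| over the whole tested
family (max-statistic correction).

Permutation p-values use the add-one estimator
p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm), so p >= 1/(1 + n_perm)
always; when the total number of row permutations is small enough the
test switches to exhaustive enumeration and p is the exact fraction.
All tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .activation import GASValue, SpreadSeries

__all__ = ["DesignMatrix", "GLMResult", "build_design", "fit_glm",
           "permutation_test", "group_contrast_spread", "clinical_association"]

#: |t| assigned when the residual variance underflows (perfect fit)
T_CAP = 1e12

#: switch to exhaustive enumeration when n! is at most this
EXHAUSTIVE_LIMIT = 20_000


@dataclass
class DesignMatrix:
    """Design with named columns and a single-coefficient contrast."""

    X: np.ndarray
    columns: tuple[str, ...]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X must be n x p with one name per column")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal column count")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def tested_column(self) -> int:
        nz = np.flatnonzero(self.contrast)
        if nz.size != 1:
            raise ValueError("contrast must select exactly one coefficient")
        return int(nz[0])


def build_design(table: pd.DataFrame, effect: str,
                 confounds: Sequence[str] = ("age", "sex", "missing_mri")) -> DesignMatrix:
    """Intercept + effect column + mean-centered confounds.

    `effect` may be 'group' (ALS=1, HC=0 indicator) or any numeric column
    (e.g. a GAS column). Sex is encoded F=0 / M=1 before centering.
    Confounds that carry no independent information in the sample — a
    constant column (nobody missing an MRI) or one collinear with the
    columns already included (all-male ALS vs all-female HC in a tiny
    cohort) — are dropped rather than producing a rank-deficient design.
    """
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if effect == "group":
        eff = (table["group"].to_numpy() == "ALS").astype(float)
    else:
        eff = table[effect].to_numpy(dtype=float)
    cols.append(eff)
    names.append(effect)
    for c in confounds:
        v = table[c]
        if c == "sex":
            v = v.map({"F": 0.0, "M": 1.0}) if v.dtype == object else v.astype(float)
        v = v.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            continue
        candidate = np.column_stack(cols + [v - v.mean()])
        if np.linalg.matrix_rank(candidate) <= len(cols):
            continue
        cols.append(v - v.mean())
        names.append(c)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X=X, columns=tuple(names), contrast=contrast)


def _guarded_t(eff: np.ndarray, sigma2: np.ndarray, var_c: float,
               scale: float) -> np.ndarray:
    """t = eff / sqrt(sigma2 * var_c), with perfect fits (residual variance
    at rounding level) mapped to 0 when the effect is itself at rounding
    level, else to +/- T_CAP."""
    tiny = np.finfo(float).eps * max(scale, 1.0) * 1e3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(sigma2 * var_c)
    degenerate = sigma2 < tiny ** 2
    t = np.where(degenerate, np.where(np.abs(eff) < tiny, 0.0,
                                      np.sign(eff) * T_CAP), t)
    return np.clip(np.nan_to_num(t, nan=0.0, posinf=T_CAP, neginf=-T_CAP),
                   -T_CAP, T_CAP)


def fit_glm(y: np.ndarray, design: DesignMatrix):
    """OLS betas and contrast t-statistics.

    y is n (one outcome) or n x m (m outcome elements fitted jointly).
    Returns (betas p x m, t m-vector, df). A perfect fit (zero residual
    variance) yields |t| capped at T_CAP with the sign of the effect, or
    t = 0 when the effect itself is zero.
    """
    X = design.X
    n, p = X.shape
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T  # n x m
    if y2.shape[0] != n:
        raise ValueError("outcome length does not match design rows")
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y2
    resid = y2 - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    c = design.contrast
    var_c = float(c @ np.linalg.inv(X.T @ X) @ c)
    eff = c @ beta
    t = _guarded_t(eff, sigma2, var_c, np.abs(y2).max(initial=1.0))
    if np.ndim(y) == 1:
        return beta[:, 0], float(t[0]), df
    return beta, t, df


@dataclass
class GLMResult:
    """Permutation-GLM output for a family of outcome elements."""

    labels: tuple[str, ...]
    beta: np.ndarray
    t: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    family: str
    n_perm: int
    seed: int | None
    df: int
    exhaustive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element": list(self.labels),
            "beta": self.beta,
            "t": self.t,
            "p_uncorrected": self.p_uncorrected,
            "p_fwe": self.p_fwe,
            "family": self.family,
            "n_perm": self.n_perm,
            "seed": self.seed if self.seed is not None else -1,
            "df": self.df,
        })


def _perm_iter(n: int, n_perm: int, rng: np.random.Generator, exhaustive: bool):
    if exhaustive:
        for perm in _all_permutations(range(n)):
            yield np.asarray(perm)
    else:
        for _ in range(n_perm):
            yield rng.permutation(n)


def permutation_test(y: np.ndarray, design: DesignMatrix,
                     n_perm: int = 5000, seed: int | None = 0,
                     labels: Sequence[str] | None = None,
                     family: str = "",
                     scheme: str = "freedman_lane",
                     exhaustive: bool | None = None) -> GLMResult:
    """Freedman-Lane permutation test of the design's single-coefficient
    contrast over one family of outcome elements.

    y: n or n x m. The max-|t| null over all m elements provides the
    family-wise corrected p-values. Switches to exhaustive enumeration
    of all n! row permutations when n! <= EXHAUSTIVE_LIMIT (p then being
    the exact fraction, without the add-one correction).

    scheme='label' permutes the raw outcome rows instead (valid without
    confounds; approximate with them). `exhaustive` forces enumeration on
    or off; the default (None) decides by the EXHAUSTIVE_LIMIT rule.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = design.X
    n = X.shape[0]
    j = design.tested_column
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T
    m = y2.shape[1]
    if labels is None:
        labels = tuple(f"el{i}" for i in range(m))
    beta_full, t_obs, df = fit_glm(y2, design)
    t_obs = np.atleast_1d(t_obs)

    if exhaustive is None:
        exhaustive = math.factorial(n) <= EXHAUSTIVE_LIMIT
    elif exhaustive and math.factorial(n) > EXHAUSTIVE_LIMIT:
        raise ValueError("exhaustive enumeration infeasible for this n")
    rng = np.random.default_rng(seed)
    if scheme == "freedman_lane":
        Z = np.delete(X, j, axis=1)
        pinv_z = np.linalg.pinv(Z)
        fit_z = Z @ (pinv_z @ y2)
        resid_z = y2 - fit_z
    elif scheme == "label":
        fit_z = np.zeros_like(y2)
        resid_z = y2
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    # refit machinery reused across permutations
    pinv = np.linalg.pinv(X)
    a = design.contrast @ pinv                      # n-vector: t numerator weights
    H = X @ pinv
    M = np.eye(n) - H                               # residual maker
    var_c = float(design.contrast @ np.linalg.inv(X.T @ X) @ design.contrast)

    exceed = np.zeros(m)
    exceed_max = np.zeros(m)
    count = 0
    abs_obs = np.abs(t_obs)
    scale = np.abs(y2).max(initial=1.0)
    for perm in _perm_iter(n, n_perm, rng, exhaustive):
        y_star = fit_z + resid_z[perm]
        eff = a @ y_star
        sigma2 = (np.linalg.norm(M @ y_star, axis=0) ** 2) / df
        abs_star = np.abs(_guarded_t(eff, sigma2, var_c, scale))
        exceed += abs_star >= abs_obs
        exceed_max += abs_star.max() >= abs_obs
        count += 1

    if exhaustive:
        p_unc = exceed / count
        p_fwe = exceed_max / count
    else:
        p_unc = (1.0 + exceed) / (1.0 + count)
        p_fwe = (1.0 + exceed_max) / (1.0 + count)
    p_unc = np.minimum(p_unc, 1.0)
    p_fwe = np.minimum(np.maximum(p_fwe, p_unc), 1.0)
    return GLMResult(labels=tuple(labels), beta=beta_full[j], t=t_obs,
                     p_uncorrected=p_unc, p_fwe=p_fwe,
                     family=family or f"{m} elements", n_perm=count, seed=seed,
                     df=df, exhaustive=exhaustive)


def _spread_outcome_matrix(spreads: Sequence[SpreadSeries],
                           gas_window: tuple[float, float] = (1.0, 3.0)):
    """Stack every band x bin activated/deactivated count plus the scalar
    gamma / high-gamma window means into one participants x elements matrix."""
    from .activation import compute_gas

    ref = spreads[0]
    n_bands, n_bins = ref.activated_count.shape
    cols, labels = [], []
    for s in spreads:
        row = [s.activated_count.ravel(), s.deactivated_count.ravel()]
        extra = [compute_gas(s, gas_window, band).gas
                 for band in ("gamma", "high_gamma") if band in s.band_names]
        cols.append(np.concatenate(row + [np.asarray(extra)]))
    centers = ref.bin_centers()
    for kind in ("activated", "deactivated"):
        for b in ref.band_names:
            labels += [f"{kind}:{b}:{c:.2f}s" for c in centers]
    labels += [f"gas:{band}" for band in ("gamma", "high_gamma")
               if band in ref.band_names]
    return np.vstack(cols), tuple(labels)


def group_contrast_spread(spreads: Sequence[SpreadSeries],
                          clinical: pd.DataFrame,
                          n_perm: int = 5000, seed: int | None = 0,
                          gas_window: tuple[float, float] = (1.0, 3.0)) -> GLMResult:
    """ALS-vs-HC permutation contrast over every spread element.

    The FWE family is everything tested together: activated and
    deactivated counts for all bands x bins, plus the scalar gamma and
    high-gamma window means. Confounds: age, sex, missing MRI.
    """
    if "group" not in clinical.columns:
        raise ValueError("clinical table lacks a 'group' column")
    order = {pid: i for i, pid in enumerate(clinical["participant_id"])}
    spreads = sorted(spreads, key=lambda s: order[s.participant_id])
    if [s.participant_id for s in spreads] != list(clinical["participant_id"]):
        raise ValueError("spread collection does not match clinical table rows")
    y, labels = _spread_outcome_matrix(spreads, gas_window)
    design = build_design(clinical, "group")
    return permutation_test(y, design, n_perm=n_perm, seed=seed, labels=labels,
                            family="regions-collapsed spread: bands x bins x "
                                   "{activated,deactivated} + scalar GAS")


CLINICAL_OUTCOMES = ("ALSFRS_R", "progression_rate", "ECAS", "UMN_score",
                     "NfL", "fine_motor_subscore")


def clinical_association(gas: Sequence[GASValue] | np.ndarray,
                         clinical: pd.DataFrame, outcome: str,
                         n_perm: int = 5000, seed: int | None = 0) -> GLMResult:
    """Permutation GLM of one clinical outcome on GAS in the ALS group.

    Model: outcome ~ intercept + GAS + age + sex + missing_mri, ALS rows
    only; the permutation p is for the GAS coefficient. Each outcome is
    its own family (no cross-outcome correction).
    """
    if outcome not in CLINICAL_OUTCOMES:
        raise ValueError(f"unknown clinical outcome {outcome!r}")
    als = clinical[clinical["group"] == "ALS"].reset_index(drop=True)
    gas_vec = np.asarray([g.gas if isinstance(g, GASValue) else float(g)
                          for g in gas], dtype=float)
    if len(gas_vec) != len(als):
        raise ValueError("need one GAS value per ALS participant")
    if len(als) < 10:
        import warnings
        warnings.warn("fewer than 10 ALS participants; association is fragile")
    if np.ptp(gas_vec) == 0:
        raise ValueError("GAS regressor is constant")
    y = als[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome} is constant")
    tbl = als.copy()
    tbl["GAS"] = gas_vec
    design = build_design(tbl, "GAS")
    return permutation_test(y, design, n_perm=n_perm, seed=seed,
                            labels=(outcome,), family=f"clinical:{outcome}")
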