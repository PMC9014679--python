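"""Venous oxygenation (Yv) estimation from TRUST MRI difference signals.

TRUST (T2-Relaxation-Under-Spin-Tagging) labels venous blood and acquires
label/control pairs at several effective echo times (eTEs). The pairwise
difference isolates the venous blood signal, which decays mono-exponentially
with the blood T2:

    S(eTE) = S0 * exp(-eTE / T2)

T2 is then converted to the venous hemoglobin saturation Yv through an
empirical calibration quadratic in (1 - Y) whose coefficients depend on
hematocrit and on the CPMG refocusing interval of the T2 preparation:

    1/T2 [1/s] = a1 + a2 * (1 - Y) + a3 * (1 - Y)^2

The calibration table bundled with the package covers tau_CPMG = 10 ms on an
Hct grid of 0.35-0.50 and is linearly interpolated in Hct.

Default acquisition layout follows a common protocol: eTEs {0, 40, 80, 160}
ms, 3 averages per eTE, a 4-voxel ROI in the occipital superior sagittal
sinus selected as the brightest difference voxels in a user-supplied search
mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    ConfigurationError,
    EstimationError,
    ExtrapolationWarning,
    FitError,
    InputError,
)

__all__ = [
    "TrustSeries",
    "T2Fit",
    "control_label_difference",
    "select_roi",
    "fit_t2",
    "t2_to_yv",
    "yv_to_t2",
    "yv_per_condition",
    "load_calibration",
    "read_trust_tsv",
    "write_trust_tsv",
]

DEFAULT_ETES_MS = (0.0, 40.0, 80.0, 160.0)


@dataclass
class TrustSeries:
    """Difference-signal series of one TRUST acquisition.

    ``signals`` is either a 1-D array (one value per eTE, averages already
    collapsed) or a 2-D array shaped (n_ete, n_avg).
    """

    effective_tes: np.ndarray  # ms
    signals: np.ndarray  # a.u.
    tau_cpmg: float = 10.0  # ms
    t1_blood: float = 1.65  # s, used only if T1-recovery correction is on
    voxel_count: int = 4

    def __post_init__(self) -> None:
        self.effective_tes = np.asarray(self.effective_tes, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        te = self.effective_tes
        if te.ndim != 1 or len(te) < 3:
            raise InputError("need at least 3 effective TEs")
        if np.any(np.diff(te) <= 0):
            raise InputError("effective TEs must be strictly increasing")
        if te[0] != 0:
            raise InputError("first effective TE must be 0")
        if self.signals.shape[0] != len(te):
            raise InputError("signals first axis must match effective TEs")
        if not np.all(np.isfinite(self.signals)):
            raise InputError("signals must be finite")

    @property
    def collapsed(self) -> np.ndarray:
        """Per-eTE mean over averages (identity for 1-D signals)."""
        if self.signals.ndim == 1:
            return self.signals
        return self.signals.mean(axis=1)


@dataclass
class T2Fit:
    """Result of a mono-exponential T2 fit."""

    t2_blood: float  # ms
    s0: float  # a.u.
    r_squared: float
    apparent: bool  # True if no T1-recovery correction was applied


def control_label_difference(control, label) -> np.ndarray:
    """Element-wise control - label, averages collapsed to one value per eTE.

    Inputs are arrays shaped (n_ete,) or (n_ete, n_avg) with matching shapes.
    """
    c = np.asarray(control, dtype=float)
    l = np.asarray(label, dtype=float)
    if c.shape != l.shape:
        raise InputError(f"control shape {c.shape} != label shape {l.shape}")
    diff = c - l
    if diff.ndim == 1:
        return diff
    return diff.mean(axis=1)


def select_roi(image: np.ndarray, mask: np.ndarray, k: int = 4) -> np.ndarray:
    """Indices of the k brightest voxels of ``image`` within ``mask``.

    Returns flat indices into ``image`` (C order), deterministically
    tie-broken by ascending voxel index.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise InputError("image and mask shapes differ")
    if k < 1:
        raise InputError("k must be >= 1")
    candidates = np.flatnonzero(m.ravel())
    if candidates.size == 0:
        raise InputError("mask is empty")
    if k > candidates.size:
        raise InputError(f"k={k} exceeds mask size {candidates.size}")
    vals = img.ravel()[candidates]
    # sort by (-value, index): lexsort uses the last key as primary
    order = np.lexsort((candidates, -vals))
    return np.sort(candidates[order[:k]])


def fit_t2(series: TrustSeries, t1_correction: bool = False) -> T2Fit:
    """Least-squares mono-exponential fit of a TRUST difference series.

    Fits S(eTE) = S0 * exp(-eTE / T2app) on the average-collapsed series.
    With ``t1_correction`` the apparent rate is corrected for longitudinal
    relaxation of the labeled blood during the eTE:
    1/T2_blood = 1/T2app - 1/T1_blood.

    Raises
    ------
    FitError
        If all signals are non-positive, the fitted decay is non-physical
        (negative or absent), or the T1 correction leaves no transverse
        decay.
    """
    s = series.collapsed
    te = series.effective_tes
    if np.all(s <= 0):
        raise FitError("all TRUST difference signals are non-positive")
    if s[0] <= 0:
        raise FitError("mean difference signal at eTE 0 must be positive")

    # Log-linear initial guess from the positive samples.
    pos = s > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[pos], np.log(s[pos]), 1)
        rate0 = max(-slope, 1e-6)
        s0_0 = float(np.exp(intercept))
    else:  # pragma: no cover - needs >=3 eTEs so rarely hit
        rate0, s0_0 = 1.0 / 60.0, float(s.max())

    def model(t, s0, rate):
        return s0 * np.exp(-rate * t)

    try:
        popt, _ = curve_fit(model, te, s, p0=[s0_0, rate0], maxfev=5000)
    except RuntimeError as exc:
        raise FitError(f"T2 fit did not converge: {exc}") from exc
    s0, rate = float(popt[0]), float(popt[1])  # rate in 1/ms

    if rate <= 1e-5:  # T2 > 100 s: no measurable decay
        raise FitError(f"no measurable decay (apparent T2 = {1.0 / max(rate, 1e-300):.3g} ms)")
    if rate < 0 or s0 <= 0:
        raise FitError("non-physical fit (negative decay rate or amplitude)")

    resid = s - model(te, *popt)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    if t1_correction:
        t1_ms = series.t1_blood * 1000.0
        rate_b = rate - 1.0 / t1_ms
        if rate_b <= 0:
            raise FitError(
                f"T1-recovery correction removes all decay (T2app={1 / rate:.1f} ms, "
                f"T1b={t1_ms:.0f} ms)"
            )
        return T2Fit(t2_blood=1.0 / rate_b, s0=s0, r_squared=r2, apparent=False)
    return T2Fit(t2_blood=1.0 / rate, s0=s0, r_squared=r2, apparent=True)


@lru_cache(maxsize=1)
def load_calibration() -> dict:
    """Bundled T2->Yv calibration table (tau_CPMG = 10 ms)."""
    text = resources.files("cmrkit.data").joinpath("trust_calibration_tcpmg10.json").read_text()
    return json.loads(text)


def _coefficients(hct: float) -> tuple[float, float, float]:
    cal = load_calibration()
    grid = np.asarray(cal["hct_grid"])
    if hct < grid[0] or hct > grid[-1]:
        warnings.warn(
            f"Hct {hct} outside calibration grid [{grid[0]}, {grid[-1]}]; "
            "coefficients clamped to the nearest grid edge",
            ExtrapolationWarning,
            stacklevel=3,
        )
        hct = float(np.clip(hct, grid[0], grid[-1]))
    return tuple(
        float(np.interp(hct, grid, np.asarray(cal[key]))) for key in ("a1", "a2", "a3")
    )


def yv_to_t2(yv: float, hct: float, tau_cpmg: float = 10.0) -> float:
    """Forward calibration: blood T2 (ms) for a given venous saturation.

    This is the generative counterpart of :func:`t2_to_yv`, used by the
    synthetic-data module and in round-trip tests.
    """
    _check_tau(tau_cpmg)
    if not 0.0 <= yv <= 1.0:
        raise InputError(f"yv={yv} outside [0, 1]")
    a1, a2, a3 = _coefficients(hct)
    x = 1.0 - yv
    rate_s = a1 + a2 * x + a3 * x * x  # 1/s
    return 1000.0 / rate_s


def t2_to_yv(t2_blood: float, hct: float, tau_cpmg: float = 10.0) -> float:
    """Venous saturation Yv from blood T2 (ms) via the calibration quadratic.

    Solves a3*(1-Y)^2 + a2*(1-Y) + (a1 - 1000/T2) = 0 for the physiologic
    root (1-Y) in [0, 1]. Rates outside the calibrated range trigger an
    :class:`ExtrapolationWarning`; a root outside [0, 1] beyond a small slack
    raises :class:`EstimationError`.
    """
    _check_tau(tau_cpmg)
    if t2_blood <= 0:
        raise InputError("t2_blood must be positive")
    a1, a2, a3 = _coefficients(hct)
    rate = 1000.0 / t2_blood  # 1/s
    lo, hi = a1, a1 + a2 + a3  # rates at Y=1 and Y=0
    if rate < lo or rate > hi:
        warnings.warn(
            f"1/T2 = {rate:.2f} 1/s outside calibrated range [{lo:.2f}, {hi:.2f}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    disc = a2 * a2 - 4.0 * a3 * (a1 - rate)
    if disc < 0:
        if rate < lo:
            # decay slower than the fully oxygenated calibration limit
            # (noise on a high-Yv measurement): clamp to Y = 1, already
            # flagged by the extrapolation warning above
            return 1.0
        raise EstimationError(f"no real calibration root for 1/T2 = {rate:.2f} 1/s")
    x = (-a2 + np.sqrt(disc)) / (2.0 * a3)  # positive branch: x >= 0 for rate >= a1
    if x < -0.05 or x > 1.05:
        raise EstimationError(
            f"calibration root 1-Y = {x:.3f} outside the physiologic range [0, 1]"
        )
    return float(np.clip(1.0 - x, 0.0, 1.0))


def _check_tau(tau_cpmg: float) -> None:
    cal = load_calibration()
    if abs(tau_cpmg - cal["tau_cpmg_ms"]) > 1e-9:
        raise ConfigurationError(
            f"bundled calibration is for tau_CPMG = {cal['tau_cpmg_ms']} ms, "
            f"got {tau_cpmg} ms; supply an alternate table"
        )


def yv_per_condition(fits: Sequence[T2Fit], hct: float, tau_cpmg: float = 10.0) -> float:
    """Average Yv over repeated scans of one breathing condition.

    Each fit is converted to Yv first, then the Yv values are arithmetic
    averaged (repeats are averaged at the Yv level, not the T2 level).
    """
    if len(fits) == 0:
        raise InputError("need at least one T2 fit")
    return float(np.mean([t2_to_yv(f.t2_blood, hct, tau_cpmg) for f in fits]))


# ---------------------------------------------------------------------------
# Tabular I/O


def read_trust_tsv(path, tau_cpmg: float = 10.0, t1_blood: float = 1.65) -> TrustSeries:
    """Read a TRUST series from a TSV with columns ete_ms, average, signal."""
    df = pd.read_csv(path, sep="\t")
    required = {"ete_ms", "average", "signal"}
    if not required.issubset(df.columns):
        raise InputError(f"TRUST TSV must have columns {sorted(required)}")
    etes = np.sort(df["ete_ms"].unique())
    n_avg = df["average"].nunique()
    sig = np.full((len(etes), n_avg), np.nan)
    avg_ids = np.sort(df["average"].unique())
    for i, te in enumerate(etes):
        for j, a in enumerate(avg_ids):
            sel = df[(df["ete_ms"] == te) & (df["average"] == a)]["signal"]
            if len(sel) != 1:
                raise InputError(f"expected one signal for eTE {te}, average {a}")
            sig[i, j] = sel.iloc[0]
    return TrustSeries(effective_tes=etes, signals=sig, tau_cpmg=tau_cpmg, t1_blood=t1_blood)


def write_trust_tsv(series: TrustSeries, path) -> None:
    """Write a TRUST series as a (ete_ms, average, signal) TSV."""
    sig = series.signals if series.signals.ndim == 2 else series.signals[:, None]
    rows = [
        {"ete_ms": te, "average": j, "signal": sig[i, j]}
        for i, te in enumerate(series.effective_tes)
        for j in range(sig.shape[1])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
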