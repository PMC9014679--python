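"""pCASL CBF quantification with the single-compartment kinetic model.

Voxel-wise CBF is obtained from the label/control difference signal dM and
the equilibrium magnetization M0 through the continuous-labeling
single-compartment closed form evaluated at the post-bolus branch
(PLD >= arrival time): the labeled bolus decays with the blood T1 until it
arrives in tissue and with the tissue T1 afterwards,

    Q = 2 * alpha * T1t * exp(-ATT/T1a) * (1 - exp(-tau/T1t))
        * exp(-(PLD - ATT)/T1t)
    CBF [ml/100g/min] = 6000 * lambda * (dM / M0) / Q

with labeling efficiency alpha, label duration tau, post-label delay PLD,
arterial arrival time ATT, tissue T1 ``T1t``, arterial blood T1 ``T1a`` and
blood-tissue water partition coefficient lambda. Slice timing of a 2-D
readout is handled by per-slice PLDs (PLD_i = base PLD + i * slice_dt).

Quantification uses gray-matter tissue parameters for every voxel; the
resulting white-matter underestimation is repaired at the global-averaging
step with the GM/WM quantification-factor ratio (the WM correction factor,
~1.19 for the default parameter set). Global CBF is a tissue-probability
weighted mean over non-excluded voxels with one-pass outlier rejection of
voxels whose |CBF| exceeds mean + 2 SD.

The arterial blood water T1 is condition dependent: hyperoxia (carbogen
breathing) shortens it, so quantification accepts normoxic/hyperoxic T1a
pairs (four literature scenarios are bundled) and a 5% GM arrival-time
reduction for hypercapnic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError, ValidityError

__all__ = [
    "KineticParams",
    "AslDataset",
    "T1Scenario",
    "T1_SCENARIOS",
    "HYPEROXIC_CONDITIONS",
    "HYPERCAPNIC_CONDITIONS",
    "quantification_factor",
    "quantify_cbf_map",
    "wm_correction_factor",
    "wm_correction_map",
    "global_cbf",
    "t1a_sensitivity",
]

#: Conditions in which the hyperoxic arterial blood T1 applies.
HYPEROXIC_CONDITIONS = frozenset({"carbogen"})
#: Conditions in which the GM arrival time is reduced by the hypercapnic factor.
HYPERCAPNIC_CONDITIONS = frozenset({"co2air", "carbogen"})


@dataclass
class KineticParams:
    """Parameters of the single-compartment pCASL kinetic model (times in s)."""

    lambda_blood_tissue: float = 0.9  # ml/g
    alpha: float = 0.85  # labeling efficiency
    t1_blood_normoxic: float = 1.65
    t1_blood_hyperoxic: float = 1.49
    t1_tissue_gm: float = 1.3
    t1_tissue_wm: float = 0.84
    arrival_gm: float = 1.3
    arrival_wm: float = 1.7
    label_duration: float = 1.5
    base_pld: float = 1.7
    # default per-slice PLD increment: (TR - PLD - tau) / n_slices for a
    # 17-slice readout at TR 3.9 s
    slice_dt: float = (3.9 - 1.7 - 1.5) / 17
    hypercapnic_att_factor: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "lambda_blood_tissue",
            "alpha",
            "t1_blood_normoxic",
            "t1_blood_hyperoxic",
            "t1_tissue_gm",
            "t1_tissue_wm",
            "arrival_gm",
            "arrival_wm",
            "label_duration",
            "base_pld",
            "hypercapnic_att_factor",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.slice_dt < 0:
            raise InputError("slice_dt must be non-negative")

    def t1_blood(self, condition: str) -> float:
        return (
            self.t1_blood_hyperoxic
            if condition in HYPEROXIC_CONDITIONS
            else self.t1_blood_normoxic
        )

    def arrival(self, condition: str, tissue: str = "gm") -> float:
        base = self.arrival_gm if tissue == "gm" else self.arrival_wm
        if tissue == "gm" and condition in HYPERCAPNIC_CONDITIONS:
            return base * self.hypercapnic_att_factor
        return base


@dataclass
class T1Scenario:
    """Normoxic/hyperoxic arterial blood water T1 pair (s)."""

    name: str
    t1_normoxic: float
    t1_hyperoxic: float

    def __post_init__(self) -> None:
        if self.t1_normoxic <= 0 or self.t1_hyperoxic <= 0:
            raise InputError("scenario T1 values must be positive")


#: Literature T1a scenarios used for the sensitivity analysis.
T1_SCENARIOS = {
    "I": T1Scenario("I", 1.65, 1.49),
    "II": T1Scenario("II", 1.65, 1.472),
    "III": T1Scenario("III", 1.669, 1.527),
    "IV": T1Scenario("IV", 1.898, 1.743),
}


@dataclass
class AslDataset:
    """One subject-condition pCASL dataset: dM/M0 volumes plus tissue maps."""

    delta_m: np.ndarray
    m0: np.ndarray
    p_gm: np.ndarray
    p_wm: np.ndarray
    exclusion_mask: np.ndarray  # True = excluded (CSF / cerebellum / brainstem)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        shapes = {
            np.shape(a)
            for a in (self.delta_m, self.m0, self.p_gm, self.p_wm, self.exclusion_mask)
        }
        if len(shapes) != 1:
            raise InputError(f"volume shapes differ: {shapes}")
        self.delta_m = np.asarray(self.delta_m, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        self.p_gm = np.asarray(self.p_gm, dtype=float)
        self.p_wm = np.asarray(self.p_wm, dtype=float)
        self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
        for name, p in (("p_gm", self.p_gm), ("p_wm", self.p_wm)):
            if p.min() < 0 or p.max() > 1:
                raise InputError(f"{name} must be within [0, 1]")
        if not (0 <= self.slice_axis < self.delta_m.ndim):
            raise InputError("slice_axis out of range")

    @property
    def n_slices(self) -> int:
        return self.delta_m.shape[self.slice_axis]

    # -- NIfTI I/O ----------------------------------------------------------

    @classmethod
    def from_niftis(cls, delta_m, m0, p_gm, p_wm, exclusion_mask, slice_axis: int = 2):
        def arr(p):
            return np.asarray(nib.load(str(p)).dataobj, dtype=float)

        return cls(
            delta_m=arr(delta_m),
            m0=arr(m0),
            p_gm=arr(p_gm),
            p_wm=arr(p_wm),
            exclusion_mask=arr(exclusion_mask) > 0.5,
            slice_axis=slice_axis,
        )

    def to_niftis(self, directory, prefix: str = "asl") -> dict:
        """Write the volumes as .nii.gz files; returns the path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        volumes = {
            "deltam": self.delta_m,
            "m0": self.m0,
            "pgm": self.p_gm,
            "pwm": self.p_wm,
            "exclude": self.exclusion_mask.astype(np.uint8),
        }
        for key, vol in volumes.items():
            path = directory / f"{prefix}_{key}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), np.eye(4)), path)
            out[key] = path
        return out


def quantification_factor(
    params: KineticParams,
    t1_tissue: float,
    arrival_time: float,
    pld: float,
    t1_blood: Optional[float] = None,
) -> float:
    """Dimensionless kinetic scale Q relating dM/M0 to CBF (includes 2*alpha).

    Valid on the post-bolus branch only (PLD >= arrival time).
    """
    if t1_blood is None:
        t1_blood = params.t1_blood_normoxic
    if pld < arrival_time:
        raise ValidityError(
            f"PLD {pld:.3f} s < arrival time {arrival_time:.3f} s: outside the "
            "post-bolus closed-form branch"
        )
    return (
        2.0
        * params.alpha
        * t1_tissue
        * np.exp(-arrival_time / t1_blood)
        * (1.0 - np.exp(-params.label_duration / t1_tissue))
        * np.exp(-(pld - arrival_time) / t1_tissue)
    )


def _slice_plds(params: KineticParams, n_slices: int) -> np.ndarray:
    return params.base_pld + np.arange(n_slices) * params.slice_dt


def _along_axis(values: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = len(values)
    return values.reshape(shape)


def quantify_cbf_map(
    data: AslDataset,
    params: KineticParams,
    condition: str,
    t1_blood: Optional[float] = None,
    slice_timing: bool = True,
    m0_threshold: float = 1e-6,
) -> np.ndarray:
    """Voxel-wise CBF map (ml/100g/min) for one breathing condition.

    GM tissue T1 and arrival time are used for all voxels (the WM bias is
    repaired later at the global-averaging step). ``condition`` selects the
    blood T1 (hyperoxic for carbogen) and the hypercapnic arrival-time
    reduction; pass ``t1_blood`` to override (e.g. for a T1a scenario).
    Voxels with M0 <= ``m0_threshold`` are set to NaN.
    """
    m0 = data.m0
    if not np.any(m0 > m0_threshold):
        raise InputError("all-zero (or sub-threshold) M0 volume")
    if t1_blood is None:
        t1_blood = params.t1_blood(condition)
    att = params.arrival(condition, "gm")

    if slice_timing:
        plds = _slice_plds(params, data.n_slices)
    else:
        plds = np.full(data.n_slices, params.base_pld)
    q = np.array(
        [
            quantification_factor(params, params.t1_tissue_gm, att, pld, t1_blood)
            for pld in plds
        ]
    )
    q_vol = _along_axis(q, data.delta_m.ndim, data.slice_axis)

    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = 6000.0 * params.lambda_blood_tissue * data.delta_m / (m0 * q_vol)
    cbf = np.where(m0 > m0_threshold, cbf, np.nan)
    return cbf


def wm_correction_factor(
    params: KineticParams,
    pld: Optional[float] = None,
    t1_blood: Optional[float] = None,
    condition: str = "roomair1",
) -> float:
    """GM/WM quantification-factor ratio Q(GM)/Q(WM) at a single PLD.

    Quantifying WM voxels with GM kinetics underestimates WM CBF by this
    factor (~1.19 for the defaults); multiplying WM CBF by it restores the
    WM value. alpha and lambda cancel in the ratio. Defaults to the base PLD
    and the condition-appropriate blood T1 / arrival times.
    """
    if pld is None:
        pld = params.base_pld
    if t1_blood is None:
        t1_blood = params.t1_blood(condition)
    q_gm = quantification_factor(
        params, params.t1_tissue_gm, params.arrival(condition, "gm"), pld, t1_blood
    )
    q_wm = quantification_factor(
        params, params.t1_tissue_wm, params.arrival(condition, "wm"), pld, t1_blood
    )
    return float(q_gm / q_wm)


def wm_correction_map(
    data: AslDataset,
    params: KineticParams,
    condition: str = "roomair1",
    t1_blood: Optional[float] = None,
    slice_timing: bool = True,
) -> np.ndarray:
    """Per-voxel WM correction factors matching the slice-specific PLDs.

    The GM/WM factor is PLD dependent, so when quantification uses
    slice-specific PLDs the correction must too; this broadcasts the
    per-slice factors to a full volume for use in :func:`global_cbf`.
    """
    if slice_timing:
        plds = _slice_plds(params, data.n_slices)
    else:
        plds = np.full(data.n_slices, params.base_pld)
    factors = np.array(
        [wm_correction_factor(params, pld, t1_blood, condition) for pld in plds]
    )
    vol = _along_axis(factors, data.delta_m.ndim, data.slice_axis)
    return np.broadcast_to(vol, data.delta_m.shape).copy()


def global_cbf(
    cbf: np.ndarray,
    data: AslDataset,
    wm_factor,
    symmetric: bool = False,
) -> float:
    """Tissue-probability weighted global CBF with one-pass outlier rejection.

    global = sum(pGM*CBF + pWM*CBF*wm_factor) / sum(pGM + pWM) over voxels
    that are not excluded, have tissue (pGM + pWM > 0) and are finite. Voxels
    with |CBF| > mean + 2 SD of the included voxel distribution are then
    removed once and the weighted mean recomputed. With ``symmetric=True``
    the rejection criterion is |CBF - mean| > 2 SD instead.

    ``wm_factor`` may be a scalar or a volume (see :func:`wm_correction_map`).
    """
    cbf = np.asarray(cbf, dtype=float)
    if cbf.shape != data.p_gm.shape:
        raise InputError("CBF map shape does not match the dataset")
    wf = np.broadcast_to(np.asarray(wm_factor, dtype=float), cbf.shape)

    include = (~data.exclusion_mask) & np.isfinite(cbf) & ((data.p_gm + data.p_wm) > 0)
    if not np.any(include):
        raise InputError("no voxels remain after exclusion masking")

    def weighted_mean(sel: np.ndarray) -> float:
        num = np.sum(data.p_gm[sel] * cbf[sel] + data.p_wm[sel] * cbf[sel] * wf[sel])
        den = np.sum(data.p_gm[sel] + data.p_wm[sel])
        return float(num / den)

    vals = cbf[include]
    mean, sd = float(vals.mean()), float(vals.std())
    if symmetric:
        keep_vals = np.abs(vals - mean) <= 2.0 * sd
    else:
        keep_vals = np.abs(vals) <= mean + 2.0 * sd
    keep = include.copy()
    keep[include] = keep_vals
    if not np.any(keep):
        raise InputError("outlier rejection removed every voxel")
    return weighted_mean(keep)


def t1a_sensitivity(
    params: KineticParams,
    scenarios: Optional[Sequence[T1Scenario]] = None,
    perturbations: Sequence[float] = (-0.05, 0.0, 0.05),
    arrival_time: Optional[float] = None,
) -> pd.DataFrame:
    """Percent change in quantified CBF (and CMRO2) under blood-T1 perturbation.

    For a fixed acquisition, quantified CBF scales as exp(+ATT / T1a), so
    quantifying with a perturbed T1a' = T1a * (1 + delta) changes CBF (and,
    by linear propagation through CMRO2 = CBF * (O2a - O2v), CMRO2) by

        100 * (exp(ATT * (1/T1a' - 1/T1a)) - 1)  [%].

    Returns a table with one row per (scenario, basis, perturbation), where
    basis is the normoxic or hyperoxic T1 of the scenario.
    """
    if scenarios is None:
        scenarios = list(T1_SCENARIOS.values())
    if arrival_time is None:
        arrival_time = params.arrival_gm
    for d in perturbations:
        if not -0.5 < d < 0.5:
            raise InputError(f"perturbation {d} outside (-0.5, 0.5)")

    rows = []
    for sc in scenarios:
        for basis, t1 in (("normoxic", sc.t1_normoxic), ("hyperoxic", sc.t1_hyperoxic)):
            for d in perturbations:
                t1p = t1 * (1.0 + d)
                change = np.exp(arrival_time * (1.0 / t1p - 1.0 / t1)) - 1.0
                rows.append(
                    {
                        "scenario": sc.name,
                        "basis": basis,
                        "t1_s": t1,
                        "perturbation": d,
                        "cbf_change_pct": 100.0 * change,
                        "cmro2_change_pct": 100.0 * change,
                    }
                )
    return pd.DataFrame(rows)
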