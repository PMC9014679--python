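"""Assembly of blood-gas, Yv and CBF estimates into OEF/CMRO2 results.

Per subject and breathing condition the pipeline combines

* Yv from the TRUST T2 fit(s),
* global CBF from the pCASL quantification,
* the blood-gas state (measured Ya and pEtCO2 plus gas assumptions)

into the oxygen extraction fraction and the cerebral metabolic rate of O2:

    OEF   = ([O2]a - [O2]v) / [O2]a
    CMRO2 = CBF * ([O2]a - [O2]v) / 100      [umol/100g/min]

with contents in umol O2 / 100 ml blood and CBF in ml/100g/min (the /100
converts per-100-ml content to per-ml so the units resolve).

Changes are computed per subject against the PRECEDING room-air block
(CO2-in-air vs room-air 1, carbogen vs room-air 2), as percent of the
baseline, and group statistics average the per-subject percent changes
(mean of percents, not percent of means) before a two-sided paired t-test.

Plasma-dissolved O2 can be selectively ignored ("plasma modes") to probe its
role: during carbogen breathing the arterial plasma term is large (pO2 = 460
mmHg) while the venous one stays negligible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .asl import global_cbf, quantify_cbf_map, wm_correction_map
from .blood_gas import (
    BloodGas,
    OxygenContent,
    alveolar_to_arterial_po2,
    invert_saturation,
    oxygen_content,
    venous_pco2,
)
from .config import CONDITION_PAIRS, CONDITIONS, StudyConfig
from .errors import DomainError, InputError
from .trust import fit_t2, yv_per_condition

__all__ = [
    "SubjectConditionRecord",
    "compute_oef",
    "compute_cmro2",
    "build_blood_gas",
    "subject_deltas",
    "group_summary",
    "run_pipeline",
    "PipelineResult",
]


@dataclass
class SubjectConditionRecord:
    """Fully assembled result for one subject in one breathing condition."""

    subject_id: str
    condition: str
    p_et_co2: float  # mmHg
    y_a: float  # fraction
    yv: float  # fraction
    cbf: float  # ml/100g/min
    blood_gas: BloodGas
    oef: float  # fraction
    cmro2: float  # umol/100g/min


def _apply_mode(o2a: OxygenContent, o2v: OxygenContent, mode: str):
    """Zero the plasma terms selected by the plasma mode before the ratio."""
    pa = o2a.plasma_dissolved
    pv = o2v.plasma_dissolved
    if mode == "ignore_venous_plasma":
        pv = 0.0
    elif mode == "ignore_all_plasma":
        pa = 0.0
        pv = 0.0
    elif mode != "full":
        raise InputError(f"unknown plasma mode {mode!r}")
    return o2a.hb_bound + pa, o2v.hb_bound + pv


def compute_oef(o2a: OxygenContent, o2v: OxygenContent, mode: str = "full") -> float:
    """Oxygen extraction fraction ([O2]a - [O2]v) / [O2]a.

    Clipped to [-0.05, 1]; values outside that band are flagged with a
    warning before clipping.
    """
    a, v = _apply_mode(o2a, o2v, mode)
    if a <= 0:
        raise DomainError("arterial O2 content must be positive")
    oef = (a - v) / a
    if oef < -0.05 or oef > 1.0:
        warnings.warn(f"OEF {oef:.3f} outside [-0.05, 1]; clipping", stacklevel=2)
    return float(np.clip(oef, -0.05, 1.0))


def compute_cmro2(
    cbf: float, o2a: OxygenContent, o2v: OxygenContent, mode: str = "full"
) -> float:
    """CMRO2 = CBF * ([O2]a - [O2]v) / 100 in umol/100g/min."""
    if cbf < 0:
        raise DomainError("cbf must be non-negative")
    a, v = _apply_mode(o2a, o2v, mode)
    if v > a:
        warnings.warn(
            f"negative arteriovenous O2 difference ({a - v:.1f} umol/100 ml)",
            stacklevel=2,
        )
    return float(cbf * (a - v) / 100.0)


def build_blood_gas(
    condition: str,
    p_et_co2: float,
    y_a: float,
    yv: float,
    hct: float,
    age: float,
    config: StudyConfig,
) -> BloodGas:
    """Blood-gas state for one subject-condition under the configured gas model.

    Normoxic conditions (room-air, CO2 in air) derive arterial pO2 from the
    assumed alveolar pO2 via the age-dependent A-a gradient; the carbogen
    condition assumes the arterial pO2 directly. Venous pO2 is obtained by
    inverting the saturation curve at the measured Yv with venous pCO2 =
    pEtCO2 + offset.
    """
    model = config.saturation(hct)
    if yv > 0.995:
        warnings.warn(
            f"venous saturation {yv:.3f} above the physiologic ceiling; "
            "capped at 0.995 for the blood-gas state",
            stacklevel=2,
        )
        yv = 0.995
    p_v_co2 = venous_pco2(p_et_co2, config.venous_pco2_offset)
    if condition == "carbogen":
        p_a_o2 = config.p_a_o2_carbogen
        p_A_o2 = float("nan")
    else:
        p_A_o2 = config.p_A_o2_normoxia
        p_a_o2 = alveolar_to_arterial_po2(p_A_o2, age, gradient=config.aa_gradient(age))
    p_v_o2 = invert_saturation(yv, p_v_co2, model)
    return BloodGas(
        y_a=y_a,
        y_v=yv,
        p_a_o2=p_a_o2,
        p_v_o2=p_v_o2,
        p_et_co2=p_et_co2,
        p_v_co2=p_v_co2,
        p_A_o2=p_A_o2,
        hct=hct,
        age=age,
    )


def contents_from_blood_gas(bg: BloodGas) -> tuple[OxygenContent, OxygenContent]:
    """Arterial and venous O2 contents for an assembled blood-gas state."""
    o2a = oxygen_content(bg.y_a, bg.p_a_o2, bg.hct)
    o2v = oxygen_content(bg.y_v, bg.p_v_o2, bg.hct)
    return o2a, o2v


def subject_deltas(
    baseline: SubjectConditionRecord, stimulus: SubjectConditionRecord
) -> dict:
    """Absolute and percent changes of a hypercapnic record vs its room-air pair.

    Percent changes are fractional (100 * delta / baseline), computed per
    subject BEFORE any group averaging.
    """
    if baseline.subject_id != stimulus.subject_id:
        raise InputError("records belong to different subjects")
    out = {
        "subject_id": baseline.subject_id,
        "condition": stimulus.condition,
        "baseline": baseline.condition,
        "d_p_et_co2": stimulus.p_et_co2 - baseline.p_et_co2,
        "d_cbf_abs": stimulus.cbf - baseline.cbf,
    }
    for name in ("cbf", "yv", "oef", "cmro2"):
        base = getattr(baseline, name)
        if base == 0:
            raise DomainError(f"zero baseline {name} for subject {baseline.subject_id}")
        out[f"d_{name}_pct"] = 100.0 * (getattr(stimulus, name) - base) / base
    return out


def group_summary(
    records: list[SubjectConditionRecord], normality: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-level mean +/- SD table and paired t-tests vs preceding room-air.

    Returns ``(condition_table, delta_table)``. The delta table contains the
    group mean/SD of the per-subject changes plus the two-sided paired t
    statistic and p-value; pairs with zero-variance differences are flagged
    as degenerate (t/p = NaN). Subjects missing either member of a pair are
    listed and dropped from that pair.
    """
    by = {}
    for r in records:
        by.setdefault(r.condition, {})[r.subject_id] = r

    cond_rows = []
    for cond in CONDITIONS:
        if cond not in by:
            continue
        rs = list(by[cond].values())
        if len(rs) < 2:
            raise InputError(f"need >= 2 subjects per condition, {cond} has {len(rs)}")
        row = {"condition": cond, "n": len(rs)}
        for name, scale in (
            ("p_et_co2", 1.0),
            ("cbf", 1.0),
            ("yv", 100.0),
            ("oef", 1.0),
            ("cmro2", 1.0),
        ):
            vals = np.array([getattr(r, name) for r in rs]) * scale
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=1)
        if normality:
            cm = np.array([r.cmro2 for r in rs])
            row["cmro2_shapiro_p"] = float(stats.shapiro(cm).pvalue)
        cond_rows.append(row)

    delta_rows = []
    for cond, base in CONDITION_PAIRS.items():
        if cond not in by or base not in by:
            continue
        shared = sorted(set(by[cond]) & set(by[base]))
        missing = sorted(set(by[cond]) ^ set(by[base]))
        if missing:
            warnings.warn(
                f"subjects {missing} missing one of ({base}, {cond}); "
                "dropped from the paired comparison",
                stacklevel=2,
            )
        if len(shared) < 2:
            raise InputError(f"fewer than 2 complete pairs for {cond} vs {base}")
        deltas = [subject_deltas(by[base][s], by[cond][s]) for s in shared]
        ddf = pd.DataFrame(deltas)
        row = {"condition": cond, "baseline": base, "n_pairs": len(shared)}
        for col in ("d_p_et_co2", "d_cbf_abs", "d_cbf_pct", "d_yv_pct", "d_oef_pct", "d_cmro2_pct"):
            row[f"{col}_mean"] = ddf[col].mean()
            row[f"{col}_sd"] = ddf[col].std(ddof=1)
        for name in ("cbf", "yv", "oef", "cmro2"):
            pre = np.array([getattr(by[base][s], name) for s in shared])
            post = np.array([getattr(by[cond][s], name) for s in shared])
            diff = post - pre
            if np.allclose(diff.std(ddof=1), 0.0):
                # zero-variance differences: the paired t is undefined
                t, p, degenerate = np.nan, np.nan, True
            else:
                res = stats.ttest_rel(post, pre)
                t, p, degenerate = float(res.statistic), float(res.pvalue), False
            row[f"{name}_t"] = t
            row[f"{name}_p"] = p
            row[f"{name}_degenerate"] = degenerate
        delta_rows.append(row)

    return pd.DataFrame(cond_rows), pd.DataFrame(delta_rows)


@dataclass
class PipelineResult:
    per_subject: pd.DataFrame
    deltas: pd.DataFrame
    condition_table: pd.DataFrame
    delta_table: pd.DataFrame
    records: list
    provenance: dict


def _process_condition(subject, cond, config: StudyConfig) -> SubjectConditionRecord:
    cd = subject.conditions[cond]
    fits = [fit_t2(s, config.t1_recovery_correction) for s in cd.trust]
    yv = yv_per_condition(fits, subject.hct)

    params = config.kinetic
    cbf_map = quantify_cbf_map(cd.asl, params, cond)
    wm_map = wm_correction_map(cd.asl, params, cond)
    cbf = global_cbf(cbf_map, cd.asl, wm_map, symmetric=config.outlier_symmetric)

    bg = build_blood_gas(cond, cd.p_et_co2, cd.y_a, yv, subject.hct, subject.age, config)
    o2a, o2v = contents_from_blood_gas(bg)
    oef = compute_oef(o2a, o2v, config.plasma_mode)
    cmro2 = compute_cmro2(cbf, o2a, o2v, config.plasma_mode)
    return SubjectConditionRecord(
        subject_id=subject.subject_id,
        condition=cond,
        p_et_co2=cd.p_et_co2,
        y_a=cd.y_a,
        yv=yv,
        cbf=cbf,
        blood_gas=bg,
        oef=oef,
        cmro2=cmro2,
    )


def run_pipeline(
    bundle, config: Optional[StudyConfig] = None, out_dir=None
) -> PipelineResult:
    """Run the full per-subject analysis on a study bundle.

    ``bundle`` is a :class:`cmrkit.synth.StudyBundle` (or anything exposing
    ``subjects`` with the same shape). Subjects missing a condition are
    warned about and dropped from the affected paired statistics. Output is
    deterministic given the bundle and configuration; with ``out_dir`` set,
    per-subject and group TSV tables plus a JSON provenance block are
    written there.
    """
    if config is None:
        config = StudyConfig()

    records: list[SubjectConditionRecord] = []
    for subject in bundle.subjects:
        for cond in CONDITIONS:
            if cond not in subject.conditions:
                warnings.warn(
                    f"subject {subject.subject_id} missing condition {cond}",
                    stacklevel=2,
                )
                continue
            records.append(_process_condition(subject, cond, config))

    per_subject = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "condition": r.condition,
                "p_et_co2_mmhg": r.p_et_co2,
                "y_a_pct": 100.0 * r.y_a,
                "yv_pct": 100.0 * r.yv,
                "cbf_ml_100g_min": r.cbf,
                "p_a_o2_mmhg": r.blood_gas.p_a_o2,
                "p_v_o2_mmhg": r.blood_gas.p_v_o2,
                "oef": r.oef,
                "cmro2_umol_100g_min": r.cmro2,
            }
            for r in records
        ]
    )

    by = {}
    for r in records:
        by.setdefault(r.subject_id, {})[r.condition] = r
    delta_rows = []
    for sid in sorted(by):
        for cond, base in CONDITION_PAIRS.items():
            if cond in by[sid] and base in by[sid]:
                delta_rows.append(subject_deltas(by[sid][base], by[sid][cond]))
    deltas = pd.DataFrame(delta_rows)

    condition_table, delta_table = group_summary(records)

    provenance = {
        "package": "cmrkit",
        "version": __version__,
        "numpy": np.__version__,
        "config": config.to_dict(),
        "n_subjects": len(bundle.subjects),
    }

    result = PipelineResult(
        per_subject=per_subject,
        deltas=deltas,
        condition_table=condition_table,
        delta_table=delta_table,
        records=records,
        provenance=provenance,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.6g")
        per_subject.to_csv(out / "per_subject.tsv", **kw)
        deltas.to_csv(out / "deltas.tsv", **kw)
        condition_table.to_csv(out / "group_conditions.tsv", **kw)
        delta_table.to_csv(out / "group_deltas.tsv", **kw)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    return result
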