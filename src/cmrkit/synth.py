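"""Synthetic cohorts, TRUST series and ASL phantoms with known ground truth.

The generator emulates a 10-subject gas-challenge study (7 M / 3 F, age ~29)
with four sequential breathing conditions. Subject physiology is drawn from
normal distributions whose defaults are the study-scale group statistics:
baseline CBF 54.9 +/- 8.2 ml/100g/min, baseline Yv 67.3 +/- 3.6 %, baseline
pEtCO2 45.0 +/- 3.6 mmHg, pEtCO2 increases of 4.2 +/- 1.7 (CO2 in air) and
4.5 +/- 2.2 mmHg (carbogen), CBF-CO2 reactivity slopes of 1.7 +/- 1.5 and
2.8 +/- 3.2 ml/100g/min/mmHg, and CMRO2 changes of -13.4 +/- 13.0 %
(CO2 in air) and -2.0 +/- 27.0 % (carbogen). Draws are truncated to
physiologic ranges by resampling.

The manifest is forward-consistent: the true venous saturation of each
subject-condition is obtained by inverting CMRO2 = CBF * ([O2]a - [O2]v)/100
for Yv under the same blood-gas model the analysis pipeline uses, so a
noiseless bundle round-trips exactly through :func:`cmrkit.pipeline.run_pipeline`.

Imaging data are generated with the forward models of the quantification
modules: TRUST difference signals decay mono-exponentially with the T2 given
by the bundled calibration at (Yv, Hct) plus Gaussian noise per average;
phantom ASL volumes obey the slice-aware single-compartment kinetic model,
with WM voxels generated under WM kinetic parameters so that GM-parameter
quantification underestimates them (the bias the WM correction factor
repairs). Noise on difference images is Gaussian; all randomness flows from
one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .asl import AslDataset, KineticParams, quantification_factor
from .blood_gas import (
    alveolar_to_arterial_po2,
    hb_saturation,
    oxygen_content,
    venous_pco2,
)
from .config import CONDITIONS, StudyConfig
from .errors import ConfigurationError, InputError
from .pipeline import build_blood_gas
from .trust import DEFAULT_ETES_MS, TrustSeries, read_trust_tsv, write_trust_tsv, yv_to_t2

__all__ = [
    "CohortEffects",
    "PhantomGeometry",
    "SyntheticTruth",
    "StudyBundle",
    "SubjectData",
    "ConditionData",
    "generate_cohort",
    "simulate_trust",
    "simulate_asl",
    "make_phantom",
    "generate_bundle",
    "save_bundle",
    "load_bundle",
]


@dataclass
class CohortEffects:
    """Population means/SDs the cohort generator draws from (study defaults)."""

    age_mean: float = 29.4
    age_sd: float = 3.4
    male_fraction: float = 0.7

    cbf_mean: float = 54.9  # ml/100g/min, room-air 1
    cbf_sd: float = 8.2
    yv_mean: float = 0.673  # fraction, room-air 1
    yv_sd: float = 0.036
    petco2_mean: float = 45.0  # mmHg, room-air 1
    petco2_sd: float = 3.6
    petco2_roomair2_shift: float = -1.3  # mmHg, room-air 2 relative to room-air 1
    petco2_roomair2_jitter: float = 1.0

    dpetco2_co2air: tuple = (4.2, 1.7)  # mmHg
    dpetco2_carbogen: tuple = (4.5, 2.2)
    cvr_co2air: tuple = (1.7, 1.5)  # ml/100g/min per mmHg
    cvr_carbogen: tuple = (2.8, 3.2)
    dcmro2_co2air: tuple = (-13.4, 13.0)  # percent vs preceding room-air
    dcmro2_carbogen: tuple = (-2.0, 27.0)
    roomair2_cbf_shift: tuple = (-2.6, 3.0)  # ml/100g/min
    roomair2_cmro2_jitter: float = 0.05  # fractional SD around room-air 1

    # measured arterial saturation (pulse oximetry) per condition
    ya: dict = field(
        default_factory=lambda: {
            "roomair1": (0.982, 0.006),
            "co2air": (0.985, 0.006),
            "roomair2": (0.984, 0.004),
            "carbogen": (0.989, 0.004),
        }
    )

    # imaging noise (a.u.)
    trust_s0: float = 100.0
    trust_noise_sd: float = 2.0
    trust_n_avg: int = 3
    asl_m0: float = 1000.0
    asl_deltam_noise_sd: float = 1.0
    asl_m0_noise_sd: float = 10.0
    wm_flow_ratio: float = 0.4  # WM/GM perfusion ratio in the phantom

    # truncation bounds (resampling)
    age_bounds: tuple = (18.0, 60.0)
    cbf_bounds: tuple = (30.0, 90.0)
    yv_bounds: tuple = (0.50, 0.85)
    petco2_bounds: tuple = (30.0, 55.0)
    dpetco2_bounds: tuple = (0.5, 12.0)
    dcmro2_bounds: tuple = (-60.0, 80.0)
    cond_cbf_bounds: tuple = (25.0, 110.0)


@dataclass
class PhantomGeometry:
    """Ellipsoidal brain phantom: GM shell, WM core, CSF/cerebellum exclusion."""

    p_gm: np.ndarray
    p_wm: np.ndarray
    exclusion_mask: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if np.any(self.p_gm + self.p_wm > 1.0 + 1e-9):
            raise InputError("pGM + pWM must be <= 1 everywhere")
        include = (~self.exclusion_mask) & ((self.p_gm + self.p_wm) > 0)
        if not np.any(include):
            raise InputError("phantom has an empty inclusion set")

    @property
    def shape(self):
        return self.p_gm.shape


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: one row per subject-condition plus generator meta."""

    records: pd.DataFrame  # subject_id, sex, age, hct, condition, ...
    seed: int
    n: int

    def subject_rows(self, subject_id: str) -> pd.DataFrame:
        return self.records[self.records["subject_id"] == subject_id]


@dataclass
class ConditionData:
    trust: list  # list of TrustSeries (1 repeat room-air, 2 hypercapnic)
    asl: AslDataset
    p_et_co2: float
    y_a: float


@dataclass
class SubjectData:
    subject_id: str
    sex: str
    age: float
    hct: float
    conditions: dict  # condition name -> ConditionData


@dataclass
class StudyBundle:
    subjects: list
    truth: SyntheticTruth
    config: StudyConfig


def _truncated_normal(rng, mean, sd, bounds, max_tries=1000):
    lo, hi = bounds
    if sd == 0:
        if not lo <= mean <= hi:
            raise ConfigurationError(f"mean {mean} outside bounds {bounds} with sd=0")
        return float(mean)
    if lo >= hi:
        raise ConfigurationError(f"infeasible truncation bounds {bounds}")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ConfigurationError(
        f"could not draw N({mean}, {sd}) within {bounds} in {max_tries} tries"
    )


def _solve_yv(cmro2, cbf, o2a_total, p_v_co2, hct, config: StudyConfig) -> float:
    """Invert CMRO2 = CBF*([O2]a - [O2]v)/100 for the venous saturation.

    Parametrized by the venous pO2 (on which both the saturation and the
    plasma term are monotone increasing), which needs a single bracketed
    root find instead of nesting a curve inversion inside each evaluation.
    """
    model = config.saturation(hct)

    def g(p_v_o2):
        yv = hb_saturation(p_v_o2, p_v_co2, model)
        o2v = oxygen_content(yv, p_v_o2, hct)
        return cbf * (o2a_total - o2v.total) / 100.0 - cmro2

    lo, hi = 5.0, 250.0
    if g(lo) < 0 or g(hi) > 0:
        raise ConfigurationError(
            f"CMRO2 {cmro2:.1f} infeasible for CBF {cbf:.1f} at Hct {hct}"
        )
    p_root = float(brentq(g, lo, hi, xtol=1e-10))
    return float(hb_saturation(p_root, p_v_co2, model))


def generate_cohort(
    n: int = 10,
    seed: int = 0,
    effects: Optional[CohortEffects] = None,
    config: Optional[StudyConfig] = None,
) -> SyntheticTruth:
    """Draw a cohort's ground-truth physiology for all four conditions.

    Subject parameters come from the configured normal distributions
    (defaults above), truncated to physiologic ranges by resampling.
    Condition-wise true Yv is computed by inverting the CMRO2 equation given
    the drawn true CMRO2 and CBF, so truth is forward-consistent with the
    analysis model. Reproducible from ``seed``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    eff = effects or CohortEffects()
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)

    n_male = int(round(eff.male_fraction * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)

    rows = []
    for i in range(n):
        sid = f"sub-{i + 1:02d}"
        sex = str(sexes[i])
        age = _truncated_normal(rng, eff.age_mean, eff.age_sd, eff.age_bounds)
        hct = cfg.hct_for_sex(sex)

        # draw measured quantities per condition
        petco2 = {"roomair1": _truncated_normal(rng, eff.petco2_mean, eff.petco2_sd, eff.petco2_bounds)}
        petco2["co2air"] = petco2["roomair1"] + _truncated_normal(
            rng, *eff.dpetco2_co2air, eff.dpetco2_bounds
        )
        petco2["roomair2"] = _truncated_normal(
            rng,
            petco2["roomair1"] + eff.petco2_roomair2_shift,
            eff.petco2_roomair2_jitter,
            eff.petco2_bounds,
        )
        petco2["carbogen"] = petco2["roomair2"] + _truncated_normal(
            rng, *eff.dpetco2_carbogen, eff.dpetco2_bounds
        )
        ya = {c: _truncated_normal(rng, *eff.ya[c], (0.9, 0.999)) for c in CONDITIONS}

        def arterial_po2(cond):
            if cond == "carbogen":
                return cfg.p_a_o2_carbogen
            return alveolar_to_arterial_po2(
                cfg.p_A_o2_normoxia, age, gradient=cfg.aa_gradient(age)
            )

        def solve(cond, cmro2_val, cbf_val):
            o2a = oxygen_content(ya[cond], arterial_po2(cond), hct)
            p_v_co2 = venous_pco2(petco2[cond], cfg.venous_pco2_offset)
            return _solve_yv(cmro2_val, cbf_val, o2a.total, p_v_co2, hct, cfg)

        # room-air 1: draw (CBF, Yv); CMRO2 follows from the gas assumptions
        cbf = {"roomair1": _truncated_normal(rng, eff.cbf_mean, eff.cbf_sd, eff.cbf_bounds)}
        yv = {"roomair1": _truncated_normal(rng, eff.yv_mean, eff.yv_sd, eff.yv_bounds)}
        bg1 = build_blood_gas(
            "roomair1", petco2["roomair1"], ya["roomair1"], yv["roomair1"], hct, age, cfg
        )
        o2a1 = oxygen_content(bg1.y_a, bg1.p_a_o2, hct)
        o2v1 = oxygen_content(bg1.y_v, bg1.p_v_o2, hct)
        cmro2 = {"roomair1": cbf["roomair1"] * (o2a1.total - o2v1.total) / 100.0}

        # remaining conditions: draw effects, redrawing the rare combinations
        # whose (CBF, CMRO2) pair admits no physiologic venous saturation
        dcmro2 = {"roomair1": 0.0, "roomair2": 0.0}
        for _ in range(200):
            try:
                cbf["roomair2"] = _truncated_normal(
                    rng,
                    cbf["roomair1"] + eff.roomair2_cbf_shift[0],
                    eff.roomair2_cbf_shift[1],
                    eff.cbf_bounds,
                )
                cmro2["roomair2"] = cmro2["roomair1"] * (
                    1.0 + rng.normal(0.0, eff.roomair2_cmro2_jitter)
                )
                yv["roomair2"] = solve("roomair2", cmro2["roomair2"], cbf["roomair2"])
                break
            except ConfigurationError:
                continue
        else:  # pragma: no cover
            raise ConfigurationError("could not draw a feasible room-air 2 state")

        for cond, base, cvr, dcm in (
            ("co2air", "roomair1", eff.cvr_co2air, eff.dcmro2_co2air),
            ("carbogen", "roomair2", eff.cvr_carbogen, eff.dcmro2_carbogen),
        ):
            dpet = petco2[cond] - petco2[base]
            for _ in range(200):
                try:
                    cbf_c = float(
                        np.clip(cbf[base] + rng.normal(*cvr) * dpet, *eff.cond_cbf_bounds)
                    )
                    d = _truncated_normal(rng, *dcm, eff.dcmro2_bounds)
                    cmro2_c = cmro2[base] * (1.0 + d / 100.0)
                    yv[cond] = solve(cond, cmro2_c, cbf_c)
                    cbf[cond], cmro2[cond], dcmro2[cond] = cbf_c, cmro2_c, d
                    break
                except ConfigurationError:
                    continue
            else:  # pragma: no cover
                raise ConfigurationError(f"could not draw a feasible {cond} state")

        for cond in CONDITIONS:
            rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "age": age,
                    "hct": hct,
                    "condition": cond,
                    "p_et_co2": petco2[cond],
                    "y_a": ya[cond],
                    "cbf_true": cbf[cond],
                    "yv_true": yv[cond],
                    "cmro2_true": cmro2[cond],
                    "dcmro2_true_pct": dcmro2[cond],
                }
            )
    return SyntheticTruth(records=pd.DataFrame(rows), seed=seed, n=n)


def simulate_trust(
    yv: float,
    hct: float,
    rng: np.random.Generator,
    noise_sd: float = 2.0,
    s0: float = 100.0,
    n_avg: int = 3,
    effective_tes=DEFAULT_ETES_MS,
    t1_blood: float = 1.65,
) -> TrustSeries:
    """Forward-simulate one TRUST acquisition for a subject-condition.

    The decay constant is the calibration T2 at (Yv, Hct); Gaussian noise of
    ``noise_sd`` is added independently per average.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    te = np.asarray(effective_tes, dtype=float)
    t2 = yv_to_t2(yv, hct)
    clean = s0 * np.exp(-te / t2)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(len(te), n_avg))
    else:
        noise = np.zeros((len(te), n_avg))
    return TrustSeries(effective_tes=te, signals=clean[:, None] + noise, t1_blood=t1_blood)


def make_phantom(shape=(32, 32, 17), slice_axis: int = 2) -> PhantomGeometry:
    """Default ellipsoidal phantom: GM shell, WM core, CSF + caudal exclusion.

    Tissue probability maps are binary (pure GM shell, pure WM core); a small
    central ellipsoid emulates ventricular CSF (no tissue, excluded) and the
    two most caudal slices of the brain are flagged as excluded
    cerebellum/brainstem territory while still containing tissue.
    """
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2,
        np.arange(ny) - (ny - 1) / 2,
        np.arange(nz) - (nz - 1) / 2,
        indexing="ij",
    )

    def ellipsoid(rx, ry, rz):
        return (x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0

    brain = ellipsoid(13.0, 13.0, 7.5)
    core = ellipsoid(7.0, 7.0, 4.5)
    csf = ellipsoid(2.5, 2.5, 1.8)

    p_wm = (core & ~csf).astype(float)
    p_gm = (brain & ~core).astype(float)

    exclusion = csf.copy()
    caudal = z <= (-(nz - 1) / 2 + 1)  # two most caudal slices
    exclusion |= brain & caudal

    geom = PhantomGeometry(
        p_gm=p_gm, p_wm=p_wm, exclusion_mask=exclusion, slice_axis=slice_axis
    )
    if slice_axis != 2:
        raise InputError("default phantom is built on slice axis 2")
    return geom


def simulate_asl(
    cbf_global: float,
    geometry: PhantomGeometry,
    params: KineticParams,
    condition: str,
    rng: np.random.Generator,
    deltam_noise_sd: float = 1.0,
    m0_noise_sd: float = 10.0,
    m0_value: float = 1000.0,
    wm_flow_ratio: float = 0.4,
    t1_blood: Optional[float] = None,
) -> AslDataset:
    """Forward-simulate a pCASL dataset whose weighted global CBF is ``cbf_global``.

    GM voxels carry a GM flow, WM voxels ``wm_flow_ratio`` times less, chosen
    so the tissue-weighted global over non-excluded voxels equals the target.
    dM follows the slice-aware kinetic model with tissue-appropriate
    parameters (WM voxels with WM tissue T1 and arrival time, so that
    GM-parameter quantification underestimates them). M0 is uniform; Gaussian
    noise is added to both volumes.
    """
    if deltam_noise_sd < 0 or m0_noise_sd < 0:
        raise ConfigurationError("noise SDs must be non-negative")
    if t1_blood is None:
        t1_blood = params.t1_blood(condition)

    p_gm, p_wm = geometry.p_gm, geometry.p_wm
    include = (~geometry.exclusion_mask) & ((p_gm + p_wm) > 0)
    w_gm = float(p_gm[include].sum())
    w_wm = float(p_wm[include].sum())
    cbf_gm = cbf_global * (w_gm + w_wm) / (w_gm + wm_flow_ratio * w_wm)
    cbf_wm = wm_flow_ratio * cbf_gm

    nz = geometry.shape[geometry.slice_axis]
    plds = params.base_pld + np.arange(nz) * params.slice_dt
    att_gm = params.arrival(condition, "gm")
    att_wm = params.arrival(condition, "wm")
    q_gm = np.array(
        [quantification_factor(params, params.t1_tissue_gm, att_gm, p, t1_blood) for p in plds]
    )
    q_wm = np.array(
        [quantification_factor(params, params.t1_tissue_wm, att_wm, p, t1_blood) for p in plds]
    )
    sh = [1] * p_gm.ndim
    sh[geometry.slice_axis] = nz
    q_gm = q_gm.reshape(sh)
    q_wm = q_wm.reshape(sh)

    scale = m0_value / (6000.0 * params.lambda_blood_tissue)
    delta_m = scale * (p_gm * q_gm * cbf_gm + p_wm * q_wm * cbf_wm)
    if deltam_noise_sd > 0:
        delta_m = delta_m + rng.normal(0.0, deltam_noise_sd, size=delta_m.shape)
    m0 = np.full(geometry.shape, m0_value)
    if m0_noise_sd > 0:
        m0 = m0 + rng.normal(0.0, m0_noise_sd, size=m0.shape)
        m0 = np.maximum(m0, 1.0)

    return AslDataset(
        delta_m=delta_m,
        m0=m0,
        p_gm=p_gm,
        p_wm=p_wm,
        exclusion_mask=geometry.exclusion_mask,
        slice_axis=geometry.slice_axis,
    )


def generate_bundle(
    n: int = 10,
    seed: int = 0,
    effects: Optional[CohortEffects] = None,
    config: Optional[StudyConfig] = None,
    noiseless: bool = False,
    phantom_shape=(32, 32, 17),
) -> StudyBundle:
    """Generate a full in-memory study bundle (cohort truth + imaging data).

    With ``noiseless=True`` all imaging noise is switched off, in which case
    the analysis pipeline recovers the manifest truth exactly (up to the
    stated numerical tolerances). Hypercapnic conditions get two TRUST
    repeats, room-air conditions one, mirroring the acquisition scheme.
    """
    eff = effects or CohortEffects()
    cfg = config or StudyConfig()
    truth = generate_cohort(n, seed, eff, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    geometry = make_phantom(phantom_shape)

    trust_sd = 0.0 if noiseless else eff.trust_noise_sd
    dm_sd = 0.0 if noiseless else eff.asl_deltam_noise_sd
    m0_sd = 0.0 if noiseless else eff.asl_m0_noise_sd

    subjects = []
    for sid, srows in truth.records.groupby("subject_id", sort=True):
        first = srows.iloc[0]
        conditions = {}
        for cond in CONDITIONS:
            row = srows[srows["condition"] == cond].iloc[0]
            n_rep = 2 if cond in ("co2air", "carbogen") else 1
            trust = [
                simulate_trust(
                    row["yv_true"],
                    first["hct"],
                    rng,
                    noise_sd=trust_sd,
                    s0=eff.trust_s0,
                    n_avg=eff.trust_n_avg,
                    t1_blood=cfg.kinetic.t1_blood(cond),
                )
                for _ in range(n_rep)
            ]
            asl = simulate_asl(
                row["cbf_true"],
                geometry,
                cfg.kinetic,
                cond,
                rng,
                deltam_noise_sd=dm_sd,
                m0_noise_sd=m0_sd,
                m0_value=eff.asl_m0,
                wm_flow_ratio=eff.wm_flow_ratio,
            )
            conditions[cond] = ConditionData(
                trust=trust, asl=asl, p_et_co2=row["p_et_co2"], y_a=row["y_a"]
            )
        subjects.append(
            SubjectData(
                subject_id=str(sid),
                sex=first["sex"],
                age=float(first["age"]),
                hct=float(first["hct"]),
                conditions=conditions,
            )
        )
    return StudyBundle(subjects=subjects, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Bundle disk format: NIfTI volumes + TSV tables + JSON manifest


def save_bundle(bundle: StudyBundle, directory) -> Path:
    """Write a bundle to disk (NIfTI volumes, TRUST/physio TSVs, manifest JSON)."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)

    physio = []
    for subj in bundle.subjects:
        sdir = root / "subjects" / subj.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        for cond, cd in subj.conditions.items():
            for rep, series in enumerate(cd.trust):
                write_trust_tsv(series, sdir / f"trust_{cond}_rep{rep}.tsv")
            cd.asl.to_niftis(sdir, prefix=f"asl_{cond}")
            physio.append(
                {
                    "subject_id": subj.subject_id,
                    "condition": cond,
                    "p_et_co2_mmhg": cd.p_et_co2,
                    "y_a_pct": 100.0 * cd.y_a,
                    "n_trust_repeats": len(cd.trust),
                }
            )
    pd.DataFrame(physio).to_csv(root / "physio.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = {
        "seed": bundle.truth.seed,
        "n": bundle.truth.n,
        "config": bundle.config.to_dict(),
        "subjects": [
            {"subject_id": s.subject_id, "sex": s.sex, "age": s.age, "hct": s.hct}
            for s in bundle.subjects
        ],
        "truth": bundle.truth.records.to_dict(orient="records"),
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return root


def load_bundle(directory) -> StudyBundle:
    """Read a bundle written by :func:`save_bundle`."""
    root = Path(directory)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = StudyConfig.from_dict(manifest["config"])
    physio = pd.read_csv(root / "physio.tsv", sep="\t")

    subjects = []
    for meta in manifest["subjects"]:
        sid = meta["subject_id"]
        sdir = root / "subjects" / sid
        conditions = {}
        for cond in CONDITIONS:
            sel = physio[(physio["subject_id"] == sid) & (physio["condition"] == cond)]
            if sel.empty:
                continue
            row = sel.iloc[0]
            trust = [
                read_trust_tsv(
                    sdir / f"trust_{cond}_rep{r}.tsv",
                    t1_blood=cfg.kinetic.t1_blood(cond),
                )
                for r in range(int(row["n_trust_repeats"]))
            ]
            asl = AslDataset.from_niftis(
                sdir / f"asl_{cond}_deltam.nii.gz",
                sdir / f"asl_{cond}_m0.nii.gz",
                sdir / f"asl_{cond}_pgm.nii.gz",
                sdir / f"asl_{cond}_pwm.nii.gz",
                sdir / f"asl_{cond}_exclude.nii.gz",
            )
            conditions[cond] = ConditionData(
                trust=trust,
                asl=asl,
                p_et_co2=float(row["p_et_co2_mmhg"]),
                y_a=float(row["y_a_pct"]) / 100.0,
            )
        subjects.append(
            SubjectData(
                subject_id=sid,
                sex=meta["sex"],
                age=meta["age"],
                hct=meta["hct"],
                conditions=conditions,
            )
        )
    truth = SyntheticTruth(
        records=pd.DataFrame(manifest["truth"]), seed=manifest["seed"], n=manifest["n"]
    )
    return StudyBundle(subjects=subjects, truth=truth, config=cfg)
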