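"""Hemoglobin O2 dissociation curves and blood oxygen content arithmetic.

This module provides the blood-gas building blocks used to turn measured
hemoglobin saturations (arterial ``Ya`` from pulse oximetry, venous ``Yv``
from TRUST MRI) into total blood oxygen content, which is the quantity that
enters OEF and CMRO2:

    [O2] = Y * Ch(Hct) + pO2 * Cd

where ``Ch`` is the hemoglobin O2 carrying capacity (912 umol O2 / 100 ml
blood at Hct = 0.45, scaled linearly with hematocrit) and ``Cd`` = 0.138
umol O2 / 100 ml blood / mmHg is the plasma O2 solubility.

Two saturation curve models are shipped:

``severinghaus``
    The classic one-parameter curve Y = 1 / (23400 / (pO2^3 + 150 pO2) + 1),
    which depends on pO2 only.

``bohr_shifted``
    The same curve with the pO2 axis rescaled by a CO2-dependent half
    saturation pressure, log10 P50 = log10 P50_ref + b * (pCO2 - pCO2_ref).
    Raising pCO2 right-shifts the curve (the Bohr effect: CO2 lowers the
    affinity of hemoglobin for O2), which matters for hypercapnic breathing
    conditions where venous pCO2 is elevated.

A third ``plugin`` kind lets a caller register a full physiological blood-gas
model (e.g. the NSR Physiome SHbO2CO2 equation set) as a drop-in callable
without this package vendoring those equations.

Units are mmHg for pressures, fractions (0-1) for saturations and hematocrit,
and umol O2 / 100 ml blood for contents, throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "SaturationModel",
    "BloodGas",
    "OxygenContent",
    "hb_saturation",
    "invert_saturation",
    "hb_capacity",
    "oxygen_content",
    "alveolar_to_arterial_po2",
    "venous_pco2",
    "HB_CAPACITY_REFERENCE",
    "HB_CAPACITY_REFERENCE_HCT",
    "PLASMA_SOLUBILITY",
]

#: Hemoglobin O2 carrying capacity at the reference hematocrit, umol/100 ml.
HB_CAPACITY_REFERENCE = 912.0
#: Hematocrit at which :data:`HB_CAPACITY_REFERENCE` applies.
HB_CAPACITY_REFERENCE_HCT = 0.45
#: Plasma O2 solubility Cd, umol O2 / 100 ml blood / mmHg.
PLASMA_SOLUBILITY = 0.138

# Saturation-model plugin callables have signature (p_o2, p_co2, model) -> Y.
SaturationPlugin = Callable[[float, float, "SaturationModel"], float]


@dataclass
class SaturationModel:
    """Configuration of the hemoglobin O2 saturation curve.

    Parameters
    ----------
    kind
        One of ``severinghaus``, ``bohr_shifted`` or ``plugin``.
    reference_p50
        Half-saturation pO2 (mmHg) of the reference curve at
        ``reference_pco2``. Only used by the ``bohr_shifted`` kind.
    bohr_coefficient
        d log10(P50) / d pCO2 in 1/mmHg. Positive values right-shift the
        curve for pCO2 above the reference.
    reference_pco2
        pCO2 (mmHg) at which no Bohr shift is applied.
    hct
        Hematocrit fraction, forwarded to plugin models that need it.
    plugin
        Callable implementing a full dissociation model; required when
        ``kind == "plugin"``.
    """

    kind: str = "severinghaus"
    reference_p50: float = 26.9
    bohr_coefficient: float = 0.0013
    reference_pco2: float = 40.0
    hct: float = 0.45
    plugin: Optional[SaturationPlugin] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("severinghaus", "bohr_shifted", "plugin"):
            raise ConfigurationError(f"unknown saturation model kind {self.kind!r}")
        if self.reference_p50 <= 0:
            raise ConfigurationError("reference_p50 must be positive")
        if not 0.0 <= self.hct <= 0.6:
            raise ConfigurationError(f"hct {self.hct} outside [0, 0.6]")


@dataclass
class OxygenContent:
    """Blood O2 content split into hemoglobin-bound and plasma-dissolved parts.

    All fields are in umol O2 per 100 ml blood; ``total`` is their sum.
    """

    hb_bound: float
    plasma_dissolved: float

    @property
    def total(self) -> float:
        return self.hb_bound + self.plasma_dissolved


@dataclass
class BloodGas:
    """Arterial and venous blood-gas state for one subject-condition.

    Saturations are fractions; pressures are mmHg. ``p_A_o2`` is the alveolar
    O2 pressure used to derive the arterial one for normoxic conditions (it is
    NaN for the carbogen condition where arterial pO2 is assumed directly).
    """

    y_a: float
    y_v: float
    p_a_o2: float
    p_v_o2: float
    p_et_co2: float
    p_v_co2: float
    p_A_o2: float
    hct: float
    age: float

    def __post_init__(self) -> None:
        for name in ("p_a_o2", "p_v_o2", "p_et_co2", "p_v_co2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if not 0 <= self.y_v <= 1 or not 0 <= self.y_a <= 1:
            raise DomainError("saturations must be fractions in [0, 1]")


def _severinghaus_curve(p_o2):
    """Y(pO2) for the reference curve; defined as exactly 0 at pO2 = 0."""
    p = np.asarray(p_o2, dtype=float)
    out = np.zeros_like(p)
    nz = p > 0
    pn = p[nz]
    out[nz] = 1.0 / (23400.0 / (pn**3 + 150.0 * pn) + 1.0)
    return out


def hb_saturation(p_o2, p_co2: float = 40.0, model: Optional[SaturationModel] = None):
    """Hemoglobin O2 saturation Y in [0, 1] at the given pO2 (and pCO2).

    Accepts scalars or arrays of pO2. ``p_co2`` is ignored by the plain
    ``severinghaus`` kind; for ``bohr_shifted`` it sets the P50 via the
    configured Bohr coefficient.

    Raises
    ------
    DomainError
        If any pO2 is negative.
    ConfigurationError
        If ``kind == "plugin"`` but no plugin callable is registered.
    """
    if model is None:
        model = SaturationModel()
    p = np.asarray(p_o2, dtype=float)
    if np.any(p < 0):
        raise DomainError("p_o2 must be non-negative")

    if model.kind == "severinghaus":
        y = _severinghaus_curve(p)
    elif model.kind == "bohr_shifted":
        # Rescale the pO2 axis by P50(pCO2)/P50_ref before applying the
        # reference curve: effective pO2 = pO2 * P50_ref / P50(pCO2).
        shift = 10.0 ** (model.bohr_coefficient * (p_co2 - model.reference_pco2))
        y = _severinghaus_curve(p / shift)
    else:  # plugin
        if model.plugin is None:
            raise ConfigurationError(
                "saturation model kind 'plugin' requires a registered plugin callable"
            )
        y = np.asarray(model.plugin(p, p_co2, model), dtype=float)

    if np.ndim(p_o2) == 0:
        return float(y)
    return y


def invert_saturation(
    y: float, p_co2: float = 40.0, model: Optional[SaturationModel] = None
) -> float:
    """pO2 (mmHg) at which the saturation curve attains ``y``.

    Solved by bracketed root finding on [0, 5000] mmHg; the result satisfies
    ``|hb_saturation(pO2) - y| < 1e-6``.

    Raises
    ------
    DomainError
        If ``y`` is not strictly inside (0, 1).
    NumericalError
        If the root finder fails or the achieved saturation tolerance is
        not met (with diagnostics in the message).
    """
    if not 0.0 < y < 1.0:
        raise DomainError(f"saturation y={y} must be strictly inside (0, 1)")
    if model is None:
        model = SaturationModel()

    def f(p: float) -> float:
        return hb_saturation(p, p_co2, model) - y

    hi = 5000.0
    if f(hi) < 0:
        raise NumericalError(
            f"saturation {y} not reachable below {hi} mmHg (curve saturates lower)"
        )
    try:
        p_root = brentq(f, 0.0, hi, xtol=1e-9, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - brentq is robust on this bracket
        raise NumericalError(f"saturation inversion failed for y={y}: {exc}") from exc
    resid = abs(f(p_root))
    if resid > 1e-6:
        raise NumericalError(
            f"saturation inversion residual {resid:.2e} exceeds 1e-6 at pO2={p_root}"
        )
    return float(p_root)


def hb_capacity(hct: float) -> float:
    """Hemoglobin O2 carrying capacity Ch (umol/100 ml) at hematocrit ``hct``.

    Scales linearly through zero: Ch = 912 * Hct / 0.45. ``hct = 0`` returns 0
    (no hemoglobin); negative or supra-physiologic (> 0.6) values raise.
    """
    if hct < 0 or hct > 0.6:
        raise DomainError(f"hct {hct} outside [0, 0.6]")
    return HB_CAPACITY_REFERENCE * hct / HB_CAPACITY_REFERENCE_HCT


def oxygen_content(y: float, p_o2: float, hct: float) -> OxygenContent:
    """Total blood O2 content from saturation, pO2 and hematocrit.

    hb_bound = Y * Ch(Hct); plasma_dissolved = pO2 * Cd.
    """
    if not np.isfinite(y) or not np.isfinite(p_o2):
        raise DomainError("y and p_o2 must be finite")
    if y < 0 or y > 1:
        raise DomainError(f"saturation y={y} outside [0, 1]")
    if p_o2 < 0:
        raise DomainError("p_o2 must be non-negative")
    return OxygenContent(
        hb_bound=y * hb_capacity(hct),
        plasma_dissolved=p_o2 * PLASMA_SOLUBILITY,
    )


def alveolar_to_arterial_po2(
    p_A_o2: float, age: float, gradient: Optional[float] = None
) -> float:
    """Convert alveolar to arterial pO2 via the alveolar-arterial gradient.

    The default age-dependent gradient is the standard clinical approximation
    AaDO2(age) = 2.5 + 0.21 * age (mmHg); pass ``gradient`` to override it
    with an explicit value in mmHg.
    """
    if p_A_o2 <= 0:
        raise DomainError("p_A_o2 must be positive")
    if gradient is None:
        if age <= 0:
            raise DomainError("age must be positive for the default gradient formula")
        gradient = 2.5 + 0.21 * age
    if gradient >= p_A_o2:
        raise DomainError(
            f"A-a gradient {gradient:.1f} mmHg >= alveolar pO2 {p_A_o2:.1f} mmHg"
        )
    return p_A_o2 - gradient


def venous_pco2(p_et_co2: float, offset: float = 5.0) -> float:
    """Venous pCO2 estimated as end-tidal pCO2 plus a fixed offset (default +5)."""
    if p_et_co2 <= 0:
        raise DomainError("p_et_co2 must be positive")
    return p_et_co2 + offset
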