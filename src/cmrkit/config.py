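"""Study configuration: gas assumptions, model choices, kinetic parameters.

The defaults describe a hypercapnic gas-challenge study at 3 T with four
sequential breathing conditions: room-air, 5% CO2 in air (hypercapnic
normoxic), room-air again, and carbogen (5% CO2 / 95% O2, hypercapnic
hyperoxic). Each hypercapnic condition is referenced to its preceding
room-air block.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .asl import T1_SCENARIOS, KineticParams
from .blood_gas import SaturationModel
from .errors import ConfigurationError

__all__ = [
    "StudyConfig",
    "CONDITIONS",
    "CONDITION_PAIRS",
]

#: Breathing conditions in acquisition order.
CONDITIONS = ("roomair1", "co2air", "roomair2", "carbogen")
#: Hypercapnic condition -> its preceding room-air reference.
CONDITION_PAIRS = {"co2air": "roomair1", "carbogen": "roomair2"}

_PLASMA_MODES = ("full", "ignore_venous_plasma", "ignore_all_plasma")


@dataclass
class StudyConfig:
    """All tunable assumptions of the CMRO2/OEF pipeline."""

    # hematology / demographics
    hct_male: float = 0.42
    hct_female: float = 0.40
    age_default: float = 29.4  # years, used when a subject age is missing

    # gas assumptions
    p_A_o2_normoxia: float = 104.0  # mmHg alveolar O2, room-air and CO2-in-air
    p_a_o2_carbogen: float = 460.0  # mmHg arterial O2 assumed for carbogen
    venous_pco2_offset: float = 5.0  # mmHg above measured pEtCO2

    # alveolar-arterial gradient: AaDO2 = intercept + slope * age (mmHg),
    # or a fixed override in mmHg
    aa_gradient_intercept: float = 2.5
    aa_gradient_slope: float = 0.21
    aa_gradient_override: Optional[float] = None

    # saturation curve
    saturation_model: str = "bohr_shifted"
    reference_p50: float = 26.9
    bohr_coefficient: float = 0.0013
    reference_pco2: float = 40.0

    # TRUST
    trust_roi_k: int = 4
    t1_recovery_correction: bool = False

    # ASL
    t1_scenario: str = "I"
    outlier_symmetric: bool = False
    kinetic: KineticParams = field(default_factory=KineticParams)

    # CMRO2 assembly
    plasma_mode: str = "full"

    seed: int = 0

    def __post_init__(self) -> None:
        if self.plasma_mode not in _PLASMA_MODES:
            raise ConfigurationError(
                f"plasma_mode must be one of {_PLASMA_MODES}, got {self.plasma_mode!r}"
            )
        if self.t1_scenario not in T1_SCENARIOS:
            raise ConfigurationError(
                f"t1_scenario must be one of {sorted(T1_SCENARIOS)}, got {self.t1_scenario!r}"
            )
        # apply the scenario's T1a pair to the kinetic parameters
        sc = T1_SCENARIOS[self.t1_scenario]
        self.kinetic.t1_blood_normoxic = sc.t1_normoxic
        self.kinetic.t1_blood_hyperoxic = sc.t1_hyperoxic

    # -- derived helpers ----------------------------------------------------

    def hct_for_sex(self, sex: str) -> float:
        s = sex.strip().upper()[:1]
        if s == "M":
            return self.hct_male
        if s == "F":
            return self.hct_female
        raise ConfigurationError(f"sex must be 'M' or 'F', got {sex!r}")

    def saturation(self, hct: Optional[float] = None) -> SaturationModel:
        return SaturationModel(
            kind=self.saturation_model,
            reference_p50=self.reference_p50,
            bohr_coefficient=self.bohr_coefficient,
            reference_pco2=self.reference_pco2,
            hct=self.hct_male if hct is None else hct,
        )

    def aa_gradient(self, age: float) -> float:
        if self.aa_gradient_override is not None:
            return self.aa_gradient_override
        return self.aa_gradient_intercept + self.aa_gradient_slope * age

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        kin = d.pop("kinetic", None)
        cfg = cls(**d) if kin is None else cls(kinetic=KineticParams(**kin), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
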