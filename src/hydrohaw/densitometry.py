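"""Deterministic physics and physiology of hydrostatic densitometry.

Implements the full equation chain for two-component body-composition
assessment by hydrostatic weighing, with or without head submersion:

* pure-water density from temperature (Kell 1975 polynomial),
* residual lung volume predicted from stature and age (Quanjer),
* Archimedean head volume from the drop in apparent immersed weight when
  the head goes under (MWDH / DW),
* the Buskirk body-density formula for full submersion and its two
  head-above-water variants (head-volume-corrected, and direct regression
  of true density on "uncorrected density"),
* anthropometric head-volume prediction from head girth, face girth and
  body mass,
* the Brozek two-component fat-percent conversion.

Unit conventions (enforced, never silently converted inline): masses in
kg, volumes in L, densities in g/mL, girths/diameters in cm; stature is
stored in cm and converted to m only inside residual-volume prediction
via :func:`cm_to_m`.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Sex",
    "DensityMethod",
    "Anthropometrics",
    "WaterConditions",
    "ImmersionWeights",
    "LungAndGasVolumes",
    "BodyComposition",
    "PlausibilityWarning",
    "NegativeBodyFatWarning",
    "cm_to_m",
    "water_density",
    "predict_residual_volume",
    "head_volume_from_immersion",
    "body_density_hbw",
    "uncorrected_density",
    "predict_head_volume",
    "body_density_haw_hv",
    "body_density_haw_ud",
    "body_density_to_immersed_mass",
    "brozek_bf_percent",
    "HV_COEFFICIENTS",
    "UD_TO_DB_COEFFICIENTS",
    "RV_COEFFICIENTS",
    "DEFAULT_GI_GAS_L",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class DensityMethod(str, enum.Enum):
    """Which immersed weight enters the density calculation."""

    HBW = "HBW"          # head below water (criterion)
    HAW_HV = "HAW_HV"    # head above water, corrected with predicted head volume
    HAW_UD = "HAW_UD"    # head above water, density regressed on uncorrected density


class PlausibilityWarning(UserWarning):
    """Measurement outside the observed calibration range (flag, not error)."""


class NegativeBodyFatWarning(UserWarning):
    """Body density above the lean two-component limit; BF% is negative."""


CM_PER_M = 100.0


def cm_to_m(value_cm: float) -> float:
    """Centralised cm → m conversion (the only place stature changes units)."""
    return value_cm / CM_PER_M


#: GI gas allowance subtracted alongside residual volume in the Buskirk formula (L).
DEFAULT_GI_GAS_L = 0.1

#: Head-volume prediction coefficients per sex: (head girth, face girth, mass), intercept.
HV_COEFFICIENTS = {
    Sex.MALE: ((0.1294, 0.0299, 0.0055), -5.7506),
    Sex.FEMALE: ((0.1314, 0.0504, 0.0094), -7.3181),
}

#: Direct regression of true body density on uncorrected density: (slope, intercept).
UD_TO_DB_COEFFICIENTS = {
    Sex.MALE: (0.5840, 0.4105),
    Sex.FEMALE: (0.5821, 0.4008),
}

#: Quanjer residual-volume prediction: (height coefficient L/m, age coefficient L/y, intercept L).
RV_COEFFICIENTS = {
    Sex.MALE: (1.31, 0.022, -1.232),
    Sex.FEMALE: (1.812, 0.016, -2.003),
}

# Brozek two-component conversion constants: BF% = 100*(4.57/DB - 4.142)
_BROZEK_A = 4.57
_BROZEK_B = 4.142

# Observed measurement ranges (pooled derivation + validation groups) used for
# plausibility flagging.  A value outside its window warns but never errors.
PLAUSIBLE_RANGES = {
    Sex.MALE: {
        "age_y": (18.0, 36.0),
        "height_cm": (161.0, 210.0),
        "mass_kg": (62.5, 118.2),
        "head_girth_cm": (55.0, 62.0),
        "face_girth_cm": (61.0, 72.0),
        "head_length_cm": (17.0, 21.5),
        "head_width_cm": (14.0, 17.0),
        "face_length_cm": (23.0, 26.5),
    },
    Sex.FEMALE: {
        "age_y": (18.0, 26.0),
        "height_cm": (144.0, 185.0),
        "mass_kg": (41.0, 96.6),
        "head_girth_cm": (51.5, 60.0),
        "face_girth_cm": (54.5, 64.0),
        "head_length_cm": (16.0, 20.0),
        "head_width_cm": (13.5, 16.0),
        "face_length_cm": (21.5, 25.5),
    },
}

#: Plausibility window for computed body densities (g/mL).
DB_PLAUSIBLE = (0.90, 1.20)


@dataclass
class Anthropometrics:
    """A subject's physical measurements.

    Girth/diameter fields are the head-volume predictors; the three
    diameters are optional because they were only taken in the
    derivation cohort.
    """

    sex: Sex
    age_y: float
    height_cm: float
    mass_kg: float
    head_girth_cm: float
    face_girth_cm: float
    head_length_cm: Optional[float] = None
    head_width_cm: Optional[float] = None
    face_length_cm: Optional[float] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        required = {
            "age_y": self.age_y,
            "height_cm": self.height_cm,
            "mass_kg": self.mass_kg,
            "head_girth_cm": self.head_girth_cm,
            "face_girth_cm": self.face_girth_cm,
        }
        for name, value in required.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name in ("head_length_cm", "head_width_cm", "face_length_cm"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for flag in self.plausibility_flags():
            warnings.warn(flag, PlausibilityWarning, stacklevel=3)

    def plausibility_flags(self) -> list[str]:
        """Human-readable flags for measurements outside the observed ranges."""
        flags = []
        for name, (lo, hi) in PLAUSIBLE_RANGES[self.sex].items():
            value = getattr(self, name)
            if value is not None and not lo <= value <= hi:
                flags.append(
                    f"{name}={value:g} outside observed {self.sex.value} "
                    f"range [{lo:g}, {hi:g}]"
                )
        return flags


@dataclass(frozen=True)
class WaterConditions:
    """Water temperature and the density used to convert mass to volume."""

    temperature_c: float
    density: float = None  # type: ignore[assignment]  # derived when omitted

    def __post_init__(self) -> None:
        if self.density is None:
            object.__setattr__(self, "density", water_density(self.temperature_c))
        if not 0.0 <= self.temperature_c <= 40.0:
            raise ValueError(f"temperature {self.temperature_c} °C outside [0, 40]")
        if not 0.98 < self.density <= 1.00005:
            raise ValueError(f"water density {self.density} g/mL implausible")


@dataclass(frozen=True)
class ImmersionWeights:
    """Apparent masses in water with the head above / below the surface."""

    mw_haw_kg: float
    mw_hbw_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mw_hbw_kg is not None and not self.mw_hbw_kg < self.mw_haw_kg:
            raise ValueError(
                "head immersion must reduce apparent weight: "
                f"MW_HBW={self.mw_hbw_kg} >= MW_HAW={self.mw_haw_kg}"
            )

    @property
    def mwdh_kg(self) -> Optional[float]:
        """Mass of water displaced by the head (None without MW_HBW)."""
        if self.mw_hbw_kg is None:
            return None
        return self.mw_haw_kg - self.mw_hbw_kg


@dataclass(frozen=True)
class LungAndGasVolumes:
    """Residual lung volume and the fixed gastrointestinal-gas allowance."""

    rv_l: float
    gi_gas_l: float = DEFAULT_GI_GAS_L

    def __post_init__(self) -> None:
        if not self.rv_l > 0:
            raise ValueError(f"residual volume must be positive, got {self.rv_l}")
        if self.gi_gas_l < 0:
            raise ValueError(f"GI gas allowance must be >= 0, got {self.gi_gas_l}")


@dataclass
class BodyComposition:
    """Result of a body-composition calculation with its audit trail."""

    db: float
    bf_percent: float
    method: DensityMethod
    hv_imm_l: Optional[float] = None
    hv_pred_l: Optional[float] = None
    ud: Optional[float] = None
    rv_l: Optional[float] = None
    water: Optional[WaterConditions] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.method = DensityMethod(self.method)
        lo, hi = DB_PLAUSIBLE
        if not lo < self.db < hi:
            self.flags.append(f"body density {self.db:.4f} outside plausible ({lo}, {hi})")
        if self.bf_percent < 0:
            self.flags.append("negative fat percent (density above lean limit)")
        # internal consistency between stored density and fat percent
        expected = brozek_bf_percent(self.db, _warn=False)
        if not math.isclose(expected, self.bf_percent, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"BF% {self.bf_percent} inconsistent with density {self.db} "
                f"(Brozek gives {expected})"
            )


# Kell (1975) pure-water density polynomial, g/mL, valid 0–150 °C; agrees with
# CRC handbook tables to 1e-5 g/mL over the 0–40 °C domain used here.
_KELL_NUM = (999.83952, 16.945176, -7.9870401e-3, -46.170461e-6,
             105.56302e-9, -280.54253e-12)
_KELL_DEN = 16.879850e-3


def water_density(temperature_c: float) -> float:
    """Density of pure water (g/mL) at ``temperature_c`` on [0, 40] °C."""
    t = temperature_c
    if not 0.0 <= t <= 40.0:
        raise ValueError(f"temperature {t} °C outside supported domain [0, 40]")
    num = sum(c * t**i for i, c in enumerate(_KELL_NUM))
    return num / (1.0 + _KELL_DEN * t) / 1000.0


def predict_residual_volume(sex: Sex, height_m: float, age_y: float) -> float:
    """Residual lung volume (L) predicted from stature (m!) and age (years).

    The regression is stature-in-meters; a height above 3 is rejected as an
    almost certain cm/m mix-up.
    """
    sex = Sex(sex)
    if height_m > 3.0:
        raise ValueError(
            f"height {height_m} looks like centimeters; this equation takes meters"
        )
    if not 1.2 <= height_m <= 2.3:
        raise ValueError(f"height {height_m} m outside supported range [1.2, 2.3]")
    b_h, b_a, b0 = RV_COEFFICIENTS[sex]
    rv = b_h * height_m + b_a * age_y + b0
    if not rv > 0:
        raise ValueError(
            f"predicted residual volume {rv:.4f} L is non-positive; "
            "inputs outside the equation's validity"
        )
    return rv


def head_volume_from_immersion(mw_haw_kg: float, mw_hbw_kg: float, dw: float) -> float:
    """Archimedean head volume (L): displaced water mass over water density."""
    if not mw_hbw_kg < mw_haw_kg:
        raise ValueError(
            "head immersion must reduce apparent weight: "
            f"MW_HBW={mw_hbw_kg} >= MW_HAW={mw_haw_kg}"
        )
    return (mw_haw_kg - mw_hbw_kg) / dw


def _buskirk_density(ma_kg: float, immersed_kg: float, dw: float, rv_l: float,
                     gi_gas_l: float, head_correction_l: float = 0.0) -> float:
    """Shared core of the Buskirk density formula and its head-above variants."""
    if not immersed_kg < ma_kg:
        raise ValueError(f"immersed mass {immersed_kg} must be below dry mass {ma_kg}")
    denom = (ma_kg - immersed_kg) / dw + head_correction_l - rv_l - gi_gas_l
    if not denom > 0:
        raise ValueError(
            f"non-positive body volume ({denom:.4f} L); inputs are inconsistent"
        )
    return ma_kg / denom


def body_density_hbw(ma_kg: float, mw_hbw_kg: float, dw: float, rv_l: float,
                     gi_gas_l: float = DEFAULT_GI_GAS_L) -> float:
    """Criterion body density (g/mL) from full submersion at residual volume."""
    return _buskirk_density(ma_kg, mw_hbw_kg, dw, rv_l, gi_gas_l)


def uncorrected_density(ma_kg: float, mw_haw_kg: float, dw: float, rv_l: float,
                        gi_gas_l: float = DEFAULT_GI_GAS_L) -> float:
    """The Buskirk formula evaluated with the head-above-water weight.

    Deliberately omits the head's displaced volume, so it systematically
    exceeds the true density; used only as the predictor of the direct
    regression (see :func:`body_density_haw_ud`).
    """
    return _buskirk_density(ma_kg, mw_haw_kg, dw, rv_l, gi_gas_l)


def predict_head_volume(sex: Sex, head_girth_cm: float, face_girth_cm: float,
                        mass_kg: float) -> float:
    """Head volume (L) predicted from head girth, face girth and body mass."""
    sex = Sex(sex)
    ranges = PLAUSIBLE_RANGES[sex]
    for name, value in (("head_girth_cm", head_girth_cm),
                        ("face_girth_cm", face_girth_cm),
                        ("mass_kg", mass_kg)):
        lo, hi = ranges[name]
        if not lo <= value <= hi:
            warnings.warn(
                f"{name}={value:g} outside observed {sex.value} range [{lo:g}, {hi:g}]",
                PlausibilityWarning,
                stacklevel=2,
            )
    (b_hg, b_fg, b_ma), b0 = HV_COEFFICIENTS[sex]
    hv = b_hg * head_girth_cm + b_fg * face_girth_cm + b_ma * mass_kg + b0
    if not hv > 0:
        raise ValueError(f"predicted head volume {hv:.4f} L is non-positive")
    return hv


def body_density_haw_hv(ma_kg: float, mw_haw_kg: float, dw: float, hv_pred_l: float,
                        rv_l: float, gi_gas_l: float = DEFAULT_GI_GAS_L) -> float:
    """Body density (g/mL) from head-above-water weighing, head volume added back."""
    return _buskirk_density(ma_kg, mw_haw_kg, dw, rv_l, gi_gas_l,
                            head_correction_l=hv_pred_l)


def body_density_haw_ud(sex: Sex, ud: float) -> float:
    """Body density (g/mL) from the direct regression on uncorrected density."""
    sex = Sex(sex)
    if not ud > 0:
        raise ValueError(f"uncorrected density must be positive, got {ud}")
    slope, intercept = UD_TO_DB_COEFFICIENTS[sex]
    return slope * ud + intercept


def body_density_to_immersed_mass(ma_kg: float, db: float, dw: float, rv_l: float,
                                  gi_gas_l: float = DEFAULT_GI_GAS_L,
                                  head_correction_l: float = 0.0) -> float:
    """Invert the Buskirk formula for the apparent immersed mass (kg).

    With ``head_correction_l`` = 0 this inverts the full-submersion form;
    with a predicted head volume it inverts the head-above-water form.
    """
    if not db > 0:
        raise ValueError(f"density must be positive, got {db}")
    return ma_kg - dw * (ma_kg / db - head_correction_l + rv_l + gi_gas_l)


def brozek_bf_percent(db: float, _warn: bool = True) -> float:
    """Brozek two-component fat percent from body density.

    Negative values (density above the lean limit 4.57/4.142 g/mL) are
    returned unmodified with a warning — clipping would distort group means.
    """
    if not db > 0:
        raise ValueError(f"density must be positive, got {db}")
    bf = 100.0 * (_BROZEK_A / db - _BROZEK_B)
    if bf < 0 and _warn:
        warnings.warn(
            f"negative fat percent ({bf:.2f}%) at density {db:.4f} g/mL",
            NegativeBodyFatWarning,
            stacklevel=2,
        )
    return bf
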