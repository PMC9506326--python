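"""Synthetic study cohorts with the statistical structure the analysis assumes.

The study data are emulated, not downloaded: anthropometrics are drawn
from a single-factor Gaussian model whose marginal means, SDs, ranges
and predictor–MWDH correlations default to the published derivation
(Exp) and validation (Val) group summaries, body densities are drawn
from the published group moments, immersed weights are solved exactly
from the Buskirk formula, and each weighing trial is rendered as a
sampled two-plateau weight trace with phase-specific Gaussian noise.

Head volume can be generated two ways (``hv_mode``):

* ``"equation"`` (default) — head volume is the published prediction
  equation evaluated on the drawn predictors plus Gaussian noise
  (``hv_noise_sd``); the generator then owns the true coefficients, so
  derivation code can be tested for parameter recovery.  Displaced mass
  is HV·DW.
* ``"factor"`` — displaced mass is the latent factor itself (faithful
  to the published marginal moments and correlations); head volume is
  MWDH/DW, with no closed-form true equation.

The factor model implies corr(Vi, Vj) = ri·rj between predictors — the
published tables give only predictor–MWDH correlations, so the full
predictor covariance is a modelling assumption, stated openly here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .densitometry import (
    DEFAULT_GI_GAS_L,
    HV_COEFFICIENTS,
    Anthropometrics,
    Sex,
    body_density_to_immersed_mass,
    brozek_bf_percent,
    cm_to_m,
    predict_residual_volume,
    water_density,
)
from .traces import DEFAULT_SAMPLE_RATE, WeightTrace

__all__ = [
    "VariableCalibration",
    "TraceConfig",
    "CohortConfig",
    "SyntheticSubject",
    "StudyTruth",
    "table1_calibration",
    "db_moments",
    "trace_noise_sd",
    "generate_cohort",
    "generate_traces",
    "make_study",
    "cohort_to_frame",
    "write_cohort_csv",
    "write_traces_csv",
]


@dataclass(frozen=True)
class VariableCalibration:
    """Marginal mean/SD, admissible range, and correlation with MWDH."""

    mean: float
    sd: float
    min: float
    max: float
    r_mwdh: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("calibration SD must be positive")
        if not -1.0 <= self.r_mwdh <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


# Published group summaries (mean, SD, min, max, r with MWDH).  Head
# diameters were not taken in the validation groups; their Val
# calibrations reuse the Exp moments.
_C = VariableCalibration
_TABLE1 = {
    (Sex.MALE, "exp"): {
        "age_y":          _C(21.6, 3.3, 18.0, 36.0, 0.10),
        "height_cm":      _C(182.0, 10.0, 166.0, 210.0, 0.22),
        "mass_kg":        _C(83.3, 10.6, 64.7, 116.8, 0.37),
        "head_girth_cm":  _C(57.7, 1.7, 55.0, 62.0, 0.72),
        "face_girth_cm":  _C(65.4, 2.0, 61.0, 72.0, 0.63),
        "head_length_cm": _C(19.6, 0.9, 17.0, 21.5, 0.50),
        "head_width_cm":  _C(15.3, 0.6, 14.0, 17.0, 0.39),
        "face_length_cm": _C(25.2, 0.8, 23.0, 26.5, 0.45),
        "mwdh_kg":        _C(4.11, 0.38, 2.94, 5.11, 1.00),
    },
    (Sex.MALE, "val"): {
        "age_y":          _C(22.1, 3.2, 19.0, 35.0, -0.18),
        "height_cm":      _C(177.0, 8.0, 161.0, 189.0, 0.49),
        "mass_kg":        _C(81.8, 13.5, 62.5, 118.2, 0.48),
        "head_girth_cm":  _C(58.1, 1.5, 55.5, 61.0, 0.77),
        "face_girth_cm":  _C(66.3, 2.0, 63.5, 71.0, 0.83),
        "head_length_cm": _C(19.6, 0.9, 17.0, 21.5, 0.50),
        "head_width_cm":  _C(15.3, 0.6, 14.0, 17.0, 0.39),
        "face_length_cm": _C(25.2, 0.8, 23.0, 26.5, 0.45),
        "mwdh_kg":        _C(4.27, 0.38, 3.43, 5.38, 1.00),
    },
    (Sex.FEMALE, "exp"): {
        "age_y":          _C(20.4, 1.2, 19.0, 23.0, 0.05),
        "height_cm":      _C(168.0, 8.0, 152.0, 185.0, 0.49),
        "mass_kg":        _C(65.2, 10.8, 41.0, 96.6, 0.65),
        "head_girth_cm":  _C(55.5, 1.4, 51.5, 58.5, 0.79),
        "face_girth_cm":  _C(61.0, 1.9, 54.5, 64.0, 0.75),
        "head_length_cm": _C(18.9, 0.7, 16.0, 20.0, 0.53),
        "head_width_cm":  _C(14.6, 0.5, 13.5, 16.0, 0.36),
        "face_length_cm": _C(23.7, 0.9, 21.5, 25.5, 0.48),
        "mwdh_kg":        _C(3.64, 0.39, 2.47, 4.66, 1.00),
    },
    (Sex.FEMALE, "val"): {
        "age_y":          _C(20.5, 1.6, 18.0, 26.0, 0.07),
        "height_cm":      _C(166.0, 7.0, 144.0, 175.0, 0.05),
        "mass_kg":        _C(65.9, 8.2, 51.6, 79.8, -0.05),
        "head_girth_cm":  _C(55.6, 1.7, 53.0, 60.0, 0.58),
        "face_girth_cm":  _C(61.8, 1.7, 57.0, 64.0, 0.48),
        "head_length_cm": _C(18.9, 0.7, 16.0, 20.0, 0.53),
        "head_width_cm":  _C(14.6, 0.5, 13.5, 16.0, 0.36),
        "face_length_cm": _C(23.7, 0.9, 21.5, 25.5, 0.48),
        "mwdh_kg":        _C(3.65, 0.39, 3.08, 5.35, 1.00),
    },
}

# Criterion body-density group moments (g/mL).
_DB_MOMENTS = {
    (Sex.MALE, "exp"): (1.0727, 0.0102),
    (Sex.MALE, "val"): (1.0662, 0.0187),
    (Sex.FEMALE, "exp"): (1.0528, 0.0134),
    (Sex.FEMALE, "val"): (1.0475, 0.0157),
}

# Within-window weight-sample SDs (kg) by phase (head above / head below).
_TRACE_NOISE = {
    Sex.MALE: {"haw": 0.311, "hbw": 0.396},
    Sex.FEMALE: {"haw": 0.223, "hbw": 0.300},
}


def table1_calibration(sex: Sex, group: str = "exp") -> dict[str, VariableCalibration]:
    """Published calibration for a sex/group (copy; safe to mutate)."""
    return dict(_TABLE1[(Sex(sex), group)])


def db_moments(sex: Sex, group: str = "exp") -> tuple[float, float]:
    return _DB_MOMENTS[(Sex(sex), group)]


def trace_noise_sd(sex: Sex) -> dict[str, float]:
    return dict(_TRACE_NOISE[Sex(sex)])


@dataclass(frozen=True)
class TraceConfig:
    """Shape and noise of the rendered weighing trace."""

    sample_rate: float = DEFAULT_SAMPLE_RATE
    haw_plateau_s: float = 4.0
    transition_s: float = 1.0
    hbw_plateau_s: float = 4.0
    surface_s: float = 1.0
    haw_noise_sd: float = 0.311
    hbw_noise_sd: float = 0.396
    trial_jitter_sd: float = 0.05   # per-trial wobble of plateau means (kg)
    trials_per_subject: int = 3


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one cohort reproducibly."""

    sex: Sex
    n: int
    seed: int
    group: str = "exp"
    calibration: Optional[dict[str, VariableCalibration]] = None
    hv_mode: str = "equation"            # "equation" | "factor"
    hv_coefficients: Optional[tuple[tuple[float, float, float], float]] = None
    hv_noise_sd: float = 0.25            # L, scatter about the true HV equation
    db_mean: Optional[float] = None
    db_sd: Optional[float] = None
    db_mass_r: float = 0.0               # optional density–mass correlation hook
    water_temp_c: float = 35.0
    trace: Optional[TraceConfig] = None
    max_redraws: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.n < 3:
            raise ValueError("cohort size must be at least 3")
        if self.hv_mode not in ("equation", "factor"):
            raise ValueError(f"unknown hv_mode {self.hv_mode!r}")
        if self.hv_noise_sd < 0:
            raise ValueError("hv_noise_sd must be >= 0")
        if self.calibration is None:
            object.__setattr__(self, "calibration", table1_calibration(self.sex, self.group))
        if self.db_mean is None or self.db_sd is None:
            mean, sd = db_moments(self.sex, self.group)
            object.__setattr__(self, "db_mean", self.db_mean or mean)
            object.__setattr__(self, "db_sd", self.db_sd or sd)
        if self.trace is None:
            noise = trace_noise_sd(self.sex)
            object.__setattr__(self, "trace", TraceConfig(
                haw_noise_sd=noise["haw"], hbw_noise_sd=noise["hbw"]))
        if self.hv_coefficients is None:
            coeffs, intercept = HV_COEFFICIENTS[self.sex]
            object.__setattr__(self, "hv_coefficients", (coeffs, intercept))


@dataclass
class SyntheticSubject:
    """Ground-truth record: measurements, latent truth, implied weights."""

    anthropometrics: Anthropometrics
    true_hv_l: float
    true_db: float
    true_bf_percent: float
    rv_l: float
    mw_hbw_kg: float
    mw_haw_kg: float
    dw: float
    traces: list[WeightTrace] = field(default_factory=list)


@dataclass
class StudyTruth:
    """What the generator knows that the analysis must recover."""

    hv_terms: tuple[str, str, str]
    hv_coefficients: tuple[float, float, float]
    hv_intercept: float
    hv_noise_sd: float
    water_temp_c: float
    dw: float


_ANTHRO_VARS = ("age_y", "height_cm", "mass_kg", "head_girth_cm", "face_girth_cm",
                "head_length_cm", "head_width_cm", "face_length_cm")


def _draw_subject(cfg: CohortConfig, rng: np.random.Generator, dw: float,
                  subject_id: str) -> SyntheticSubject:
    cal = cfg.calibration
    mwdh_cal = cal["mwdh_kg"]
    for _ in range(cfg.max_redraws):
        z = rng.standard_normal()
        values = {}
        for name in _ANTHRO_VARS:
            c = cal[name]
            eps = rng.standard_normal()
            values[name] = c.mean + c.sd * (c.r_mwdh * z
                                            + np.sqrt(1 - c.r_mwdh**2) * eps)
        mwdh = mwdh_cal.mean + mwdh_cal.sd * z
        in_range = all(cal[n].min <= values[n] <= cal[n].max for n in _ANTHRO_VARS)
        if not (in_range and mwdh_cal.min <= mwdh <= mwdh_cal.max):
            continue
        if cfg.hv_mode == "equation":
            (b_hg, b_fg, b_ma), b0 = cfg.hv_coefficients
            true_hv = (b_hg * values["head_girth_cm"] + b_fg * values["face_girth_cm"]
                       + b_ma * values["mass_kg"] + b0
                       + cfg.hv_noise_sd * rng.standard_normal())
            mwdh = true_hv * dw
        else:
            true_hv = mwdh / dw
        if true_hv <= 0:
            continue
        # density: independent of the factor by default; the db_mass_r hook
        # reuses the subject's standardized mass to induce a correlation
        eps_db = rng.standard_normal()
        z_mass = (values["mass_kg"] - cal["mass_kg"].mean) / cal["mass_kg"].sd
        true_db = cfg.db_mean + cfg.db_sd * (cfg.db_mass_r * z_mass
                                             + np.sqrt(1 - cfg.db_mass_r**2) * eps_db)
        rv = predict_residual_volume(cfg.sex, cm_to_m(values["height_cm"]),
                                     values["age_y"])
        mw_hbw = body_density_to_immersed_mass(values["mass_kg"], true_db, dw, rv,
                                               DEFAULT_GI_GAS_L)
        if mw_hbw <= 0:
            continue
        mw_haw = mw_hbw + mwdh
        if mw_haw >= values["mass_kg"]:
            continue
        anthro = Anthropometrics(sex=cfg.sex, subject_id=subject_id, **values)
        return SyntheticSubject(
            anthropometrics=anthro,
            true_hv_l=float(true_hv),
            true_db=float(true_db),
            true_bf_percent=brozek_bf_percent(float(true_db), _warn=False),
            rv_l=float(rv),
            mw_hbw_kg=float(mw_hbw),
            mw_haw_kg=float(mw_haw),
            dw=dw,
        )
    raise RuntimeError(
        f"could not draw a feasible subject in {cfg.max_redraws} attempts"
    )


def generate_cohort(config: CohortConfig, with_traces: bool = False
                    ) -> list[SyntheticSubject]:
    """Draw a cohort; a pure function of (config, seed).

    Per-subject child RNG streams are spawned from the root seed, so
    enlarging the cohort never reshuffles earlier subjects.
    """
    dw = water_density(config.water_temp_c)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n)
    subjects = []
    import warnings as _warnings

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # plausibility flags are expected noise here
            subj = _draw_subject(config, rng, dw, subject_id=f"{config.sex.value[0]}{i:04d}")
        if with_traces:
            subj.traces = generate_traces(subj, config.trace, rng)
        subjects.append(subj)
    return subjects


def generate_traces(subject: SyntheticSubject, trace_config: TraceConfig,
                    rng: np.random.Generator) -> list[WeightTrace]:
    """Render weighing trials as piecewise plateau/ramp traces with noise."""
    tc = trace_config
    rate = tc.sample_rate
    n_haw = int(round(tc.haw_plateau_s * rate))
    n_tr = int(round(tc.transition_s * rate))
    n_hbw = int(round(tc.hbw_plateau_s * rate))
    n_up = int(round(tc.surface_s * rate))
    traces = []
    for trial in range(tc.trials_per_subject):
        haw_level = subject.mw_haw_kg + tc.trial_jitter_sd * rng.standard_normal()
        hbw_level = subject.mw_hbw_kg + tc.trial_jitter_sd * rng.standard_normal()
        haw = haw_level + tc.haw_noise_sd * rng.standard_normal(n_haw)
        down = np.linspace(haw_level, hbw_level, n_tr, endpoint=False)
        hbw = hbw_level + tc.hbw_noise_sd * rng.standard_normal(n_hbw)
        up = np.linspace(hbw_level, haw_level, n_up, endpoint=False)
        samples = np.concatenate((haw, down, hbw, up))
        traces.append(WeightTrace(samples=samples, sample_rate=rate,
                                  subject_id=subject.anthropometrics.subject_id,
                                  trial_id=f"t{trial}"))
    return traces


def make_study(exp_config: CohortConfig, val_config: CohortConfig,
               with_traces: bool = False
               ) -> tuple[list[SyntheticSubject], list[SyntheticSubject], StudyTruth]:
    """Derivation and validation cohorts from one calibration, plus the truth."""
    if exp_config.sex != val_config.sex:
        raise ValueError("derivation and validation cohorts must share a sex")
    if exp_config.seed == val_config.seed:
        raise ValueError("derivation and validation cohorts need disjoint seeds")
    exp = generate_cohort(exp_config, with_traces=with_traces)
    val = generate_cohort(val_config, with_traces=with_traces)
    (coeffs, intercept) = exp_config.hv_coefficients
    truth = StudyTruth(
        hv_terms=("head_girth_cm", "face_girth_cm", "mass_kg"),
        hv_coefficients=coeffs,
        hv_intercept=intercept,
        hv_noise_sd=exp_config.hv_noise_sd,
        water_temp_c=exp_config.water_temp_c,
        dw=water_density(exp_config.water_temp_c),
    )
    return exp, val, truth


def cohort_to_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Flatten a cohort to the pipeline's per-subject table."""
    rows = []
    for s in subjects:
        a = s.anthropometrics
        rows.append({
            "subject_id": a.subject_id,
            "sex": a.sex.value,
            "age_y": a.age_y,
            "height_cm": a.height_cm,
            "mass_kg": a.mass_kg,
            "head_girth_cm": a.head_girth_cm,
            "face_girth_cm": a.face_girth_cm,
            "head_length_cm": a.head_length_cm,
            "head_width_cm": a.head_width_cm,
            "face_length_cm": a.face_length_cm,
            "mw_haw_kg": s.mw_haw_kg,
            "mw_hbw_kg": s.mw_hbw_kg,
            "true_hv_l": s.true_hv_l,
            "true_db": s.true_db,
            "true_bf_percent": s.true_bf_percent,
            "rv_l": s.rv_l,
            "dw": s.dw,
        })
    return pd.DataFrame(rows)


def write_cohort_csv(subjects: list[SyntheticSubject], path: str | Path) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False)


def write_traces_csv(subjects: list[SyntheticSubject], path: str | Path) -> None:
    """Long-format trace CSV (subject_id, trial_id, t_s, weight_kg)."""
    frames = []
    for s in subjects:
        for tr in s.traces:
            t = np.arange(len(tr)) / tr.sample_rate
            frames.append(pd.DataFrame({
                "subject_id": tr.subject_id,
                "trial_id": tr.trial_id,
                "t_s": t,
                "weight_kg": tr.samples,
            }))
    if not frames:
        raise ValueError("no traces to write; generate the cohort with traces")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ground_truth_json(truth: StudyTruth, path: str | Path) -> None:
    payload = {
        "hv_terms": list(truth.hv_terms),
        "hv_coefficients": list(truth.hv_coefficients),
        "hv_intercept": truth.hv_intercept,
        "hv_noise_sd": truth.hv_noise_sd,
        "water_temp_c": truth.water_temp_c,
        "dw": truth.dw,
        "note": "factor-model predictor covariance corr(Vi,Vj)=ri*rj is assumed",
    }
    Path(path).write_text(json.dumps(payload, indent=2))
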