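"""Orchestration: single-subject calculation and the derive-then-validate study.

``compute_subject`` chains the equation stack for one person and one
method (full submersion; head above water with predicted head volume;
head above water via the uncorrected-density regression), retaining
every intermediate value for audit.

``run_study`` replicates the study design on per-sex derivation and
validation tables: prediction equations are fitted on the derivation
group only, frozen, applied to the validation group, and certified with
the full agreement suite (CCC, Bland–Altman, paired t, TOST with the
published bounds: ±0.2 L head volume, ±2 percentage points body fat),
plus the head-above vs head-below weight-fluctuation comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import densitometry as dens
from .agreement import (
    BlandAltmanResult,
    CccResult,
    EquivalenceSpec,
    TostResult,
    bland_altman,
    lin_ccc,
    normality_test,
    paired_t,
    see_vs_criterion,
    tost_paired,
)
from .densitometry import (
    Anthropometrics,
    BodyComposition,
    DensityMethod,
    ImmersionWeights,
    Sex,
    WaterConditions,
)
from .regression import RegressionModel, cross_validate, fit_ud_model, select_hv_model
from .traces import SessionResult

logger = logging.getLogger(__name__)

__all__ = [
    "MethodComparison",
    "SexReport",
    "StudyReport",
    "ReconstructedRow",
    "published_hv_model",
    "published_ud_model",
    "compute_subject",
    "prepare_subject_table",
    "run_study",
    "reconstruct_equivalence_row",
]

HV_EQUIVALENCE = EquivalenceSpec.symmetric(0.2)   # L
BF_EQUIVALENCE = EquivalenceSpec.symmetric(2.0)   # percentage points of body fat


def published_hv_model(sex: Sex) -> RegressionModel:
    """The shipped head-volume prediction equation as a RegressionModel."""
    sex = Sex(sex)
    (coeffs, intercept) = dens.HV_COEFFICIENTS[sex]
    return RegressionModel(
        response="hv_imm_l",
        terms=["head_girth_cm", "face_girth_cm", "mass_kg"],
        coefficients=np.asarray(coeffs, float),
        intercept=intercept,
        n=44 if sex is Sex.MALE else 46,
        r_squared=float("nan"),
        see=0.2596 if sex is Sex.MALE else 0.2091,
        sex=sex.value,
    )


def published_ud_model(sex: Sex) -> RegressionModel:
    """The shipped uncorrected-density regression as a RegressionModel."""
    sex = Sex(sex)
    slope, intercept = dens.UD_TO_DB_COEFFICIENTS[sex]
    return RegressionModel(
        response="db_hbw",
        terms=["ud"],
        coefficients=np.asarray([slope], float),
        intercept=intercept,
        n=44 if sex is Sex.MALE else 46,
        r_squared=float("nan"),
        see=0.0,
        sex=sex.value,
    )


def compute_subject(anthro: Anthropometrics,
                    weights: ImmersionWeights | SessionResult,
                    water: WaterConditions | float,
                    method: DensityMethod = DensityMethod.HBW,
                    hv_model: Optional[RegressionModel] = None,
                    ud_model: Optional[RegressionModel] = None,
                    rv_override: Optional[float] = None,
                    gi_gas_l: float = dens.DEFAULT_GI_GAS_L,
                    hv_pred_override: Optional[float] = None) -> BodyComposition:
    """Full body-composition calculation for one subject and one method."""
    method = DensityMethod(method)
    if isinstance(water, (int, float)):
        water = WaterConditions(temperature_c=float(water))
    if isinstance(weights, SessionResult):
        if not weights.qc_pass:
            raise ValueError(
                f"session failed QC: {'; '.join(weights.qc_reasons)}"
            )
        weights = ImmersionWeights(mw_haw_kg=weights.mw_haw_kg,
                                   mw_hbw_kg=weights.mw_hbw_kg)
    if rv_override is not None:
        rv = rv_override
    else:
        rv = dens.predict_residual_volume(anthro.sex,
                                          dens.cm_to_m(anthro.height_cm),
                                          anthro.age_y)
    dw = water.density
    hv_imm = None
    if weights.mw_hbw_kg is not None:
        hv_imm = dens.head_volume_from_immersion(weights.mw_haw_kg,
                                                 weights.mw_hbw_kg, dw)

    if method is DensityMethod.HBW:
        if weights.mw_hbw_kg is None:
            raise ValueError("method HBW requires MW_HBW (head-below-water weight)")
        db = dens.body_density_hbw(anthro.mass_kg, weights.mw_hbw_kg, dw, rv, gi_gas_l)
        hv_pred = None
        ud = None
    elif method is DensityMethod.HAW_HV:
        if hv_pred_override is not None:
            hv_pred = hv_pred_override
        elif hv_model is not None:
            hv_pred = float(hv_model.predict(pd.DataFrame([{
                "head_girth_cm": anthro.head_girth_cm,
                "face_girth_cm": anthro.face_girth_cm,
                "mass_kg": anthro.mass_kg,
                "head_length_cm": anthro.head_length_cm,
                "head_width_cm": anthro.head_width_cm,
                "face_length_cm": anthro.face_length_cm,
                "height_cm": anthro.height_cm,
            }]))[0])
        else:
            hv_pred = dens.predict_head_volume(anthro.sex, anthro.head_girth_cm,
                                               anthro.face_girth_cm, anthro.mass_kg)
        db = dens.body_density_haw_hv(anthro.mass_kg, weights.mw_haw_kg, dw,
                                      hv_pred, rv, gi_gas_l)
        ud = None
    else:  # HAW_UD
        ud = dens.uncorrected_density(anthro.mass_kg, weights.mw_haw_kg, dw,
                                      rv, gi_gas_l)
        if ud_model is not None:
            db = float(ud_model.predict(pd.DataFrame({"ud": [ud]}))[0])
        else:
            db = dens.body_density_haw_ud(anthro.sex, ud)
        hv_pred = None

    bf = dens.brozek_bf_percent(db, _warn=False)
    result = BodyComposition(db=db, bf_percent=bf, method=method,
                             hv_imm_l=hv_imm, hv_pred_l=hv_pred, ud=ud,
                             rv_l=rv, water=water)
    for flag in result.flags:
        logger.warning("subject %s: %s", anthro.subject_id, flag)
    return result


@dataclass
class MethodComparison:
    """Agreement of one predicted quantity against its criterion."""

    name: str
    n: int
    criterion_mean: float
    criterion_sd: float
    predicted_mean: float
    predicted_sd: float
    ccc: CccResult
    see_regression: float
    rmse: float
    bland_altman: BlandAltmanResult
    t: float
    t_p: float
    shapiro_w: float
    shapiro_p: float
    tost: TostResult


@dataclass
class SexReport:
    """Everything the study produces for one sex."""

    sex: str
    n_exp: int
    n_val: int
    hv_model: RegressionModel
    ud_model: RegressionModel
    hv_exp_see: float
    comparisons: dict[str, MethodComparison]
    fluctuation: Optional[dict] = None
    excluded: list[dict] = field(default_factory=list)


@dataclass
class StudyReport:
    """Per-sex study results plus reproducibility metadata."""

    per_sex: dict[str, SexReport]
    meta: dict = field(default_factory=dict)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if hasattr(obj, "__dataclass_fields__"):
                return asdict(obj)
            return str(obj)

        payload = json.dumps({"meta": self.meta,
                              "per_sex": {k: asdict(v) for k, v in self.per_sex.items()}},
                             default=default, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def equivalence_table(self) -> pd.DataFrame:
        """Flat frame mirroring the published equivalence-table layout."""
        rows = []
        for sex, rep in self.per_sex.items():
            for name, comp in rep.comparisons.items():
                t = comp.tost
                rows.append({
                    "sex": sex,
                    "comparison": name,
                    "n": comp.n,
                    "bound_lower": HV_EQUIVALENCE.lower if name == "hv" else BF_EQUIVALENCE.lower,
                    "bound_upper": HV_EQUIVALENCE.upper if name == "hv" else BF_EQUIVALENCE.upper,
                    "ci90_lower": round(t.ci90[0], 3),
                    "ci90_upper": round(t.ci90[1], 3),
                    "equivalent": "Yes" if t.equivalent else "No",
                    "power": round(t.power, 2) if np.isfinite(t.power) else np.nan,
                    "min_n": t.min_n,
                    "t": round(comp.t, 2),
                    "p": round(comp.t_p, 3),
                })
        return pd.DataFrame(rows)


def prepare_subject_table(df: pd.DataFrame, gi_gas_l: float = dens.DEFAULT_GI_GAS_L
                          ) -> pd.DataFrame:
    """Add derived per-subject quantities needed by derivation and validation.

    Expects columns: sex, age_y, height_cm, mass_kg, head_girth_cm,
    face_girth_cm, mw_haw_kg, mw_hbw_kg, and either ``dw`` or
    ``water_temp_c``.  Adds rv_l, hv_imm_l, db_hbw, bf_hbw, ud.
    """
    out = df.copy()
    if "dw" not in out.columns:
        if "water_temp_c" not in out.columns:
            raise ValueError("need a dw or water_temp_c column")
        out["dw"] = [dens.water_density(t) for t in out["water_temp_c"]]
    if "rv_l" not in out.columns:
        out["rv_l"] = [
            dens.predict_residual_volume(Sex(r.sex), dens.cm_to_m(r.height_cm), r.age_y)
            for r in out.itertuples()
        ]
    out["hv_imm_l"] = (out["mw_haw_kg"] - out["mw_hbw_kg"]) / out["dw"]
    out["db_hbw"] = [
        dens.body_density_hbw(r.mass_kg, r.mw_hbw_kg, r.dw, r.rv_l, gi_gas_l)
        for r in out.itertuples()
    ]
    out["bf_hbw"] = [dens.brozek_bf_percent(d, _warn=False) for d in out["db_hbw"]]
    out["ud"] = [
        dens.uncorrected_density(r.mass_kg, r.mw_haw_kg, r.dw, r.rv_l, gi_gas_l)
        for r in out.itertuples()
    ]
    return out


def _compare(name: str, criterion: np.ndarray, predicted: np.ndarray,
             spec: EquivalenceSpec) -> MethodComparison:
    ccc = lin_ccc(criterion, predicted)
    see = see_vs_criterion(criterion, predicted)
    ba = bland_altman(criterion, predicted)
    d = predicted - criterion
    t, _, p = paired_t(d)
    w, p_norm = normality_test(d)
    tost = tost_paired(d, spec=spec)
    return MethodComparison(
        name=name, n=len(d),
        criterion_mean=float(np.mean(criterion)), criterion_sd=float(np.std(criterion, ddof=1)),
        predicted_mean=float(np.mean(predicted)), predicted_sd=float(np.std(predicted, ddof=1)),
        ccc=ccc, see_regression=see.see_regression, rmse=see.rmse,
        bland_altman=ba, t=t, t_p=p, shapiro_w=w, shapiro_p=p_norm, tost=tost,
    )


def run_study(exp_df: pd.DataFrame, val_df: pd.DataFrame,
              hv_spec: EquivalenceSpec = HV_EQUIVALENCE,
              bf_spec: EquivalenceSpec = BF_EQUIVALENCE,
              max_terms: int = 3,
              hv_candidates: Optional[list[str]] = None,
              seed: Optional[int] = None) -> StudyReport:
    """Derive equations on the derivation table, validate on the held-out table.

    Both tables must carry a ``sex`` column and either QC-passed session
    weights or direct immersed weights; rows flagged ``qc_pass == False``
    are excluded with logged reasons.
    """
    from .regression import DEFAULT_HV_CANDIDATES

    candidates = hv_candidates or list(DEFAULT_HV_CANDIDATES)
    per_sex: dict[str, SexReport] = {}
    for sex in sorted(set(exp_df["sex"]) | set(val_df["sex"])):
        exp = exp_df[exp_df["sex"] == sex].copy()
        val = val_df[val_df["sex"] == sex].copy()
        excluded = []
        for label, frame in (("exp", exp), ("val", val)):
            if "qc_pass" in frame.columns:
                bad = frame[~frame["qc_pass"].astype(bool)]
                for r in bad.itertuples():
                    reason = getattr(r, "qc_reasons", "failed QC")
                    excluded.append({"group": label, "subject_id": r.subject_id,
                                     "reason": reason})
                    logger.info("excluding %s subject %s: %s", label, r.subject_id, reason)
                frame.drop(bad.index, inplace=True)
        if len(exp) < 10 or len(val) < 3:
            logger.warning("skipping sex %s: too few subjects (exp %d, val %d)",
                           sex, len(exp), len(val))
            continue
        exp = prepare_subject_table(exp)
        val = prepare_subject_table(val)

        usable = [c for c in candidates
                  if c.replace("_sq", "") in exp.columns
                  and exp[c.replace("_sq", "")].notna().all()]
        hv_model = select_hv_model(exp, "hv_imm_l", usable, max_terms=max_terms, sex=sex)
        ud_model = fit_ud_model(exp, "db_hbw", "ud", sex=sex)

        # frozen-coefficient predictions in the validation group
        val["hv_pred_l"] = hv_model.predict(val)
        val["db_haw_hv"] = [
            dens.body_density_haw_hv(r.mass_kg, r.mw_haw_kg, r.dw, r.hv_pred_l, r.rv_l)
            for r in val.itertuples()
        ]
        val["db_haw_ud"] = ud_model.predict(val)
        val["bf_haw_hv"] = [dens.brozek_bf_percent(d, _warn=False) for d in val["db_haw_hv"]]
        val["bf_haw_ud"] = [dens.brozek_bf_percent(d, _warn=False) for d in val["db_haw_ud"]]

        comparisons = {
            "hv": _compare("hv", val["hv_imm_l"].to_numpy(),
                           val["hv_pred_l"].to_numpy(), hv_spec),
            "bf_haw_hv": _compare("bf_haw_hv", val["bf_hbw"].to_numpy(),
                                  val["bf_haw_hv"].to_numpy(), bf_spec),
            "bf_haw_ud": _compare("bf_haw_ud", val["bf_hbw"].to_numpy(),
                                  val["bf_haw_ud"].to_numpy(), bf_spec),
        }

        fluct = None
        if {"haw_window_sd_kg", "hbw_window_sd_kg"} <= set(val.columns):
            ok = val[["haw_window_sd_kg", "hbw_window_sd_kg"]].dropna()
            if len(ok) >= 3:
                t, df_, p = paired_t(ok["haw_window_sd_kg"].to_numpy(),
                                     ok["hbw_window_sd_kg"].to_numpy())
                fluct = {
                    "mean_haw_sd_kg": float(ok["haw_window_sd_kg"].mean()),
                    "mean_hbw_sd_kg": float(ok["hbw_window_sd_kg"].mean()),
                    "t": t, "df": df_, "p": p, "n": len(ok),
                }

        per_sex[sex] = SexReport(
            sex=sex, n_exp=len(exp), n_val=len(val),
            hv_model=hv_model, ud_model=ud_model, hv_exp_see=hv_model.see,
            comparisons=comparisons, fluctuation=fluct, excluded=excluded,
        )
    meta = {"seed": seed,
            "hv_bounds_l": [hv_spec.lower, hv_spec.upper],
            "bf_bounds_pct": [bf_spec.lower, bf_spec.upper]}
    return StudyReport(per_sex=per_sex, meta=meta)


@dataclass(frozen=True)
class ReconstructedRow:
    """Summary row reconstructed from a printed 90% CI."""

    mean_diff: float
    sd_diff: float
    t: float
    equivalent: bool


def reconstruct_equivalence_row(n: int, ci90: tuple[float, float],
                          bounds: tuple[float, float],
                          alpha: float = 0.05) -> ReconstructedRow:
    """Invert a printed 90% CI back to (mean, sd, t) and the TOST decision.

    mean = CI midpoint; sd = halfwidth / t_{1−α, n−1} · √n; decision by
    strict containment of the CI in the bounds.  Anchors the package
    against a published summary table when raw data are unavailable.
    """
    lo, hi = ci90
    if not np.isfinite([lo, hi]).all() or not lo < hi:
        raise ValueError(f"degenerate confidence interval ({lo}, {hi})")
    if n < 3:
        raise ValueError("need n >= 3")
    mean = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    tc = float(stats.t.ppf(1 - alpha, n - 1))
    sd = half / tc * np.sqrt(n)
    t = mean / (sd / np.sqrt(n))
    equivalent = bounds[0] < lo and hi < bounds[1]
    return ReconstructedRow(mean_diff=mean, sd_diff=float(sd), t=float(t),
                     equivalent=equivalent)


def save_agreement_plots(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Optional Bland–Altman summary plots (cosmetic; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sex, rep in report.per_sex.items():
        fig, axes = plt.subplots(1, len(rep.comparisons), figsize=(4 * len(rep.comparisons), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (name, comp) in zip(axes, rep.comparisons.items()):
            ba = comp.bland_altman
            ax.axhline(ba.bias, ls=":", color="k")
            for limit in ba.loa:
                ax.axhline(limit, ls="--", color="gray")
            ax.set_title(f"{sex} {name}: bias {ba.bias:.2f}")
            ax.set_xlabel("pairwise mean")
            ax.set_ylabel("predicted − criterion")
        fig.tight_layout()
        path = out_dir / f"bland_altman_{sex}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
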