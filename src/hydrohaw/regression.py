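"""Derivation and cross-validation of the prediction equations.

Best-subset ordinary least squares for head-volume prediction (head and
face girths, diameters, body mass, and their squares as candidates,
selected by smallest SEE), the simple regression of criterion body
density on uncorrected density, and frozen-coefficient validation in a
held-out group.

Two SEE conventions are computed and always reported side by side:

* derivation SEE — residual standard error sqrt(RSS / (n - k - 1)) of the
  fitted model;
* validation SEE — the standard error of estimate from regressing the
  criterion on the frozen prediction in the validation group,
  sqrt(RSS / (n - 2)), the convention usual in body-composition
  cross-validation; the plain RMSE of (prediction - criterion) is
  reported alongside for transparency.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RankDeficiencyError",
    "RegressionModel",
    "CrossValidation",
    "DEFAULT_HV_CANDIDATES",
    "build_design",
    "fit_ols",
    "select_hv_model",
    "fit_ud_model",
    "cross_validate",
    "residual_diagnostics",
]

#: Candidate head-volume predictor terms; *_sq are raw (uncentered) squares.
DEFAULT_HV_CANDIDATES = (
    "head_girth_cm", "head_girth_cm_sq",
    "face_girth_cm", "face_girth_cm_sq",
    "head_length_cm", "head_width_cm", "face_length_cm",
    "mass_kg",
)

_SQUARE_SUFFIX = "_sq"


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""

    def __init__(self, terms: Sequence[str]):
        self.terms = list(terms)
        super().__init__(f"collinear design columns: {self.terms}")


@dataclass
class RegressionModel:
    """A fitted (or published) linear prediction equation."""

    response: str
    terms: list[str]
    coefficients: np.ndarray
    intercept: float
    n: int
    r_squared: float
    see: float
    sex: Optional[str] = None
    residual_df: Optional[int] = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise ValueError("one coefficient per term required")
        if self.see < 0:
            raise ValueError("SEE cannot be negative")

    def predict(self, data: pd.DataFrame | dict) -> np.ndarray:
        X = build_design(pd.DataFrame(data), self.terms)
        return X.to_numpy() @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "n": self.n,
            "r_squared": self.r_squared,
            "see": self.see,
            "sex": self.sex,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, payload: dict) -> "RegressionModel":
        return cls(
            response=payload["response"],
            terms=list(payload["terms"]),
            coefficients=np.asarray(payload["coefficients"], float),
            intercept=float(payload["intercept"]),
            n=int(payload.get("n", 0)),
            r_squared=float(payload.get("r_squared", np.nan)),
            see=float(payload.get("see", 0.0)),
            sex=payload.get("sex"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CrossValidation:
    """Frozen-coefficient performance in a held-out group."""

    predictions: np.ndarray
    see_regression: float   # criterion-on-prediction convention, sqrt(RSS/(n-2))
    rmse: float             # sqrt(mean squared prediction error)
    bias: float             # mean(prediction - criterion)
    n: int


def build_design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Assemble predictor columns, deriving ``*_sq`` squares on the fly."""
    cols = {}
    for term in terms:
        if term in df.columns:
            cols[term] = df[term].to_numpy(dtype=float)
        elif term.endswith(_SQUARE_SUFFIX) and term[: -len(_SQUARE_SUFFIX)] in df.columns:
            base = term[: -len(_SQUARE_SUFFIX)]
            cols[term] = df[base].to_numpy(dtype=float) ** 2
        else:
            raise KeyError(f"term {term!r} not derivable from columns {list(df.columns)}")
    return pd.DataFrame(cols, index=df.index)


def _collinear_terms(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns implicated in rank deficiency, via pivoted QR."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    labels = ["intercept"] + list(names)
    return [labels[p] for p in piv[rank:]]


def fit_ols(df: pd.DataFrame, response: str, terms: Sequence[str],
            sex: Optional[str] = None) -> RegressionModel:
    """Ordinary least squares with intercept; SEE = sqrt(RSS / (n - k - 1))."""
    terms = list(terms)
    Xdf = build_design(df, terms)
    y = df[response].to_numpy(dtype=float)
    n, k = len(y), len(terms)
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} terms plus intercept")
    X = sm.add_constant(Xdf.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(_collinear_terms(X, terms))
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    see = float(np.sqrt(rss / (n - k - 1)))
    return RegressionModel(
        response=response,
        terms=terms,
        coefficients=np.asarray(fit.params[1:], float),
        intercept=float(fit.params[0]),
        n=n,
        r_squared=float(fit.rsquared),
        see=see,
        sex=sex,
        residual_df=n - k - 1,
    )


def select_hv_model(df: pd.DataFrame, response: str = "hv_imm_l",
                    candidates: Sequence[str] = DEFAULT_HV_CANDIDATES,
                    max_terms: int = 3, sex: Optional[str] = None) -> RegressionModel:
    """Exhaustive best-subset search, smallest SEE wins.

    Every non-empty subset of ``candidates`` up to ``max_terms`` terms is
    fitted; ties go to fewer terms, then lexicographic term order (the
    enumeration visits subsets in that order and keeps the first strict
    improvement).
    """
    candidates = [c for c in candidates
                  if c in df.columns
                  or (c.endswith(_SQUARE_SUFFIX) and c[: -len(_SQUARE_SUFFIX)] in df.columns)]
    if not candidates:
        raise ValueError("no candidate terms available in the data")
    best: Optional[RegressionModel] = None
    for size in range(1, max_terms + 1):
        for subset in itertools.combinations(sorted(candidates), size):
            model = fit_ols(df, response, list(subset), sex=sex)
            if best is None or model.see < best.see:
                best = model
    assert best is not None
    return best


def fit_ud_model(df: pd.DataFrame, response: str = "db_hbw",
                 predictor: str = "ud", sex: Optional[str] = None) -> RegressionModel:
    """Simple OLS of criterion body density on uncorrected density."""
    if len(df) < 10:
        raise ValueError(f"need n >= 10 for the density regression, got {len(df)}")
    return fit_ols(df, response, [predictor], sex=sex)


def cross_validate(model: RegressionModel, df: pd.DataFrame,
                   response: Optional[str] = None) -> CrossValidation:
    """Apply frozen coefficients to a validation group.

    ``see_regression`` refits nothing of the prediction equation: it is the
    residual scatter of a simple criterion-on-prediction regression,
    sqrt(RSS / (n - 2)).  A constant prediction offset therefore vanishes
    from ``see_regression`` but shows up fully in ``rmse`` and ``bias``.
    """
    response = response or model.response
    y = df[response].to_numpy(dtype=float)
    yhat = model.predict(df)
    n = len(y)
    diff = yhat - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    if n >= 3 and np.std(yhat) > 0:
        slope, intercept = np.polyfit(yhat, y, 1)
        resid = y - (slope * yhat + intercept)
        see_reg = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    else:
        see_reg = float("nan") if n < 3 else 0.0
    if rmse == 0.0:
        see_reg = 0.0
    return CrossValidation(predictions=yhat, see_regression=see_reg,
                           rmse=rmse, bias=bias, n=n)


def residual_diagnostics(model: RegressionModel, df: pd.DataFrame) -> dict:
    """Shapiro–Wilk on residuals plus a squared-residual-on-fitted slope test.

    Reported for inspection; nothing is auto-rejected.
    """
    y = df[model.response].to_numpy(dtype=float)
    fitted = model.predict(df)
    resid = y - fitted
    w, p_norm = stats.shapiro(resid)
    X = sm.add_constant(fitted)
    het = sm.OLS(resid**2, X).fit()
    return {
        "shapiro_w": float(w),
        "shapiro_p": float(p_norm),
        "het_slope": float(het.params[1]),
        "het_slope_p": float(het.pvalues[1]),
    }
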