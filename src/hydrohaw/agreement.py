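"""Agreement and equivalence statistics for method-comparison studies.

The suite used to certify the head-above-water equations against the
full-submersion criterion: Pearson correlation and SEE, Lin's
concordance correlation coefficient with its precision/accuracy
decomposition and McBride interpretation categories, Bland–Altman bias
and limits of agreement with a proportional-bias slope test, classical
paired t-tests, Shapiro–Wilk normality, and paired TOST equivalence
with post hoc power and minimum sample size.

Sign convention, used consistently throughout the package: differences
are predicted − criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .regression import CrossValidation, RegressionModel, cross_validate

__all__ = [
    "EquivalenceSpec",
    "TostResult",
    "CccResult",
    "BlandAltmanResult",
    "lin_ccc",
    "bland_altman",
    "paired_t",
    "tost_paired",
    "tost_power",
    "tost_min_n",
    "normality_test",
    "see_vs_criterion",
]


@dataclass(frozen=True)
class EquivalenceSpec:
    """Equivalence bounds (response units) and one-sided alpha."""

    lower: float
    upper: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")

    @classmethod
    def symmetric(cls, halfwidth: float, alpha: float = 0.05) -> "EquivalenceSpec":
        if not halfwidth > 0:
            raise ValueError("halfwidth must be positive")
        return cls(-halfwidth, halfwidth, alpha)


@dataclass
class TostResult:
    """Paired two-one-sided-tests equivalence outcome."""

    mean_diff: float
    sd_diff: float
    n: int
    ci90: tuple[float, float]
    equivalent: bool
    t_lower: float
    t_upper: float
    p_tost: float
    power: float
    min_n: Optional[int]
    degenerate: bool = False


@dataclass
class CccResult:
    """Lin's concordance with precision/accuracy decomposition."""

    ccc: float
    rho: float
    cb: float
    category: str


@dataclass
class BlandAltmanResult:
    """Mean bias, 95% limits of agreement, and proportional-bias test."""

    bias: float
    sd_diff: float
    loa: tuple[float, float]
    slope: float
    slope_p: float
    slope_ci: tuple[float, float]
    n: int


# McBride interpretation of CCC magnitude; edges inclusive on the lower
# side (exactly 0.90 -> moderate, 0.95 -> moderate, 0.99 -> substantial).
def _mcbride_category(ccc: float) -> str:
    if ccc < 0.90:
        return "poor"
    if ccc <= 0.95:
        return "moderate"
    if ccc <= 0.99:
        return "substantial"
    return "almost perfect"


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> CccResult:
    """Lin's concordance correlation coefficient (original n-denominator form).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2) with population moments,
    decomposed as CCC = ρ · Cb (precision times accuracy).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = float(np.var(x))   # population (n) denominators per Lin 1989
    sy2 = float(np.var(y))
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("zero variance in one of the paired vectors")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    ccc = 2.0 * sxy / (sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2)
    rho = sxy / np.sqrt(sx2 * sy2)
    cb = ccc / rho
    return CccResult(ccc=float(ccc), rho=float(rho), cb=float(cb),
                     category=_mcbride_category(float(ccc)))


def bland_altman(criterion: Sequence[float], predicted: Sequence[float]
                 ) -> BlandAltmanResult:
    """Bland–Altman agreement of predicted against criterion.

    Differences are predicted − criterion; LoA = bias ± 1.96·SD (n−1 SD);
    proportional bias is the OLS slope of the difference on the pairwise
    mean, with a two-sided t-test of zero slope.
    """
    x = np.asarray(criterion, float)
    y = np.asarray(predicted, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 pairs of equal length")
    d = y - x
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    mc = m - m.mean()
    ssx = float(np.sum(mc**2))
    if ssx == 0.0:
        slope, slope_p, ci = 0.0, 1.0, (0.0, 0.0)
    else:
        slope = float(np.sum(mc * d) / ssx)
        intercept = bias - slope * float(m.mean())
        resid = d - (slope * m + intercept)
        df = len(d) - 2
        if df > 0 and float(np.sum(resid**2)) > 0:
            se = float(np.sqrt(np.sum(resid**2) / df / ssx))
            t = slope / se
            slope_p = float(2 * stats.t.sf(abs(t), df))
            tc = float(stats.t.ppf(0.975, df))
            ci = (slope - tc * se, slope + tc * se)
        else:
            slope_p = 0.0 if slope != 0 else 1.0
            ci = (slope, slope)
    return BlandAltmanResult(bias=bias, sd_diff=sd, loa=loa, slope=slope,
                             slope_p=slope_p, slope_ci=ci, n=len(d))


def _diff_summary(x, y, mean_diff, sd_diff, n):
    """Resolve (x, y) pairs or an explicit summary to (mean, sd, n)."""
    if x is not None:
        x = np.asarray(x, float)
        d = x if y is None else x - np.asarray(y, float)
        return float(d.mean()), float(d.std(ddof=1)), len(d)
    if mean_diff is None or sd_diff is None or n is None:
        raise ValueError("supply paired data or (mean_diff, sd_diff, n)")
    return float(mean_diff), float(sd_diff), int(n)


def paired_t(x: Optional[Sequence[float]] = None,
             y: Optional[Sequence[float]] = None, *,
             mean_diff: Optional[float] = None,
             sd_diff: Optional[float] = None,
             n: Optional[int] = None) -> tuple[float, int, float]:
    """Classical two-sided paired t-test.

    Accepts paired vectors (x, y), a vector of differences (x alone), or
    the summary form (mean_diff, sd_diff, n).  Returns (t, df, p).
    """
    m, s, k = _diff_summary(x, y, mean_diff, sd_diff, n)
    if k < 2:
        raise ValueError("need at least 2 pairs")
    if s <= 0:
        raise ValueError("zero-variance differences; t undefined")
    t = m / (s / np.sqrt(k))
    df = k - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p


def tost_paired(x: Optional[Sequence[float]] = None,
                y: Optional[Sequence[float]] = None, *,
                mean_diff: Optional[float] = None,
                sd_diff: Optional[float] = None,
                n: Optional[int] = None,
                spec: EquivalenceSpec,
                power_at_zero: bool = False) -> TostResult:
    """Paired TOST: equivalent iff the 90% CI lies strictly inside the bounds.

    The (1 − 2α) CI is mean ± t_{1−α, n−1}·sd/√n.  Post hoc power (and
    the minimum n for 0.80 power) take the observed mean difference and
    SD as the truth unless ``power_at_zero`` forces a zero true
    difference.  A zero SD collapses the CI to the mean (degenerate but
    decidable).
    """
    m, s, k = _diff_summary(x, y, mean_diff, sd_diff, n)
    if k < 3:
        raise ValueError("need at least 3 pairs")
    if s < 0:
        raise ValueError("negative SD")
    if s == 0.0:
        inside = spec.lower < m < spec.upper
        return TostResult(mean_diff=m, sd_diff=0.0, n=k, ci90=(m, m),
                          equivalent=inside, t_lower=np.inf if inside else -np.inf,
                          t_upper=-np.inf if inside else np.inf,
                          p_tost=0.0 if inside else 1.0,
                          power=1.0 if inside else 0.0, min_n=3 if inside else None,
                          degenerate=True)
    df = k - 1
    se = s / np.sqrt(k)
    tc = float(stats.t.ppf(1 - spec.alpha, df))
    ci = (m - tc * se, m + tc * se)
    t_lower = (m - spec.lower) / se   # H0: diff <= lower, reject for large t
    t_upper = (m - spec.upper) / se   # H0: diff >= upper, reject for small t
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p_tost = max(p_lower, p_upper)
    equivalent = spec.lower < ci[0] and ci[1] < spec.upper
    truth = 0.0 if power_at_zero else m
    if spec.lower < truth < spec.upper:
        power = tost_power(k, s, spec, true_diff=truth)
        min_n = tost_min_n(s, spec, true_diff=truth)
    else:
        power, min_n = float("nan"), None
    return TostResult(mean_diff=m, sd_diff=s, n=k, ci90=ci, equivalent=equivalent,
                      t_lower=float(t_lower), t_upper=float(t_upper),
                      p_tost=float(p_tost), power=power, min_n=min_n)


def tost_power(n: int, sd: float, spec: EquivalenceSpec,
               true_diff: float = 0.0, _grid: int = 4001) -> float:
    """Exact power of the paired TOST at a given true difference.

    Both one-sided tests reject iff
    lower + t_c·s/√n < d̄ < upper − t_c·s/√n, an event whose probability
    is integrated over the sampling distribution of the sample SD
    (s = σ·sqrt(χ²_{n−1}/(n−1)), independent of d̄ ~ N(δ, σ/√n)).  This
    is the joint noncentral-t formulation, evaluated by quadrature.
    """
    if not sd > 0:
        raise ValueError("sd must be positive")
    if n < 3:
        raise ValueError("need n >= 3")
    if not spec.lower < true_diff < spec.upper:
        raise ValueError(
            f"true difference {true_diff} at or outside bounds "
            f"({spec.lower}, {spec.upper}); power unattainable"
        )
    df = n - 1
    tc = float(stats.t.ppf(1 - spec.alpha, df))
    se = sd / np.sqrt(n)
    # integrate over u = CDF of chi2_df: s_obs = sd*sqrt(q/df), q = chi2 quantile
    u = (np.arange(_grid) + 0.5) / _grid
    q = stats.chi2.ppf(u, df)
    s_obs = sd * np.sqrt(q / df)
    halfgap_hi = (spec.upper - tc * s_obs / np.sqrt(n) - true_diff) / se
    halfgap_lo = (spec.lower + tc * s_obs / np.sqrt(n) - true_diff) / se
    prob = stats.norm.cdf(halfgap_hi) - stats.norm.cdf(halfgap_lo)
    return float(np.mean(np.maximum(prob, 0.0)))


def tost_min_n(sd: float, spec: EquivalenceSpec, true_diff: float = 0.0,
               target_power: float = 0.80, max_n: int = 1_000_000) -> int:
    """Smallest n >= 3 reaching ``target_power`` for the paired TOST."""
    for n in range(3, max_n + 1):
        if tost_power(n, sd, spec, true_diff, _grid=801) >= target_power:
            # confirm on the fine grid to avoid quadrature flip-flop
            if tost_power(n, sd, spec, true_diff) >= target_power:
                return n
    raise ValueError(f"target power {target_power} not reached by n={max_n}")


def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston approximation, 3 <= n <= 5000)."""
    v = np.asarray(values, float)
    if not 3 <= len(v) <= 5000:
        raise ValueError(f"Shapiro–Wilk supports 3 <= n <= 5000, got {len(v)}")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def see_vs_criterion(criterion: Sequence[float], predicted: Sequence[float]
                     ) -> CrossValidation:
    """Both SEE conventions (regression SEE and RMSE) as a labeled result."""
    import pandas as pd

    df = pd.DataFrame({"criterion": np.asarray(criterion, float),
                       "pred": np.asarray(predicted, float)})
    # identity "model" carrying the prediction through cross_validate
    model = RegressionModel(response="criterion", terms=["pred"],
                            coefficients=np.array([1.0]), intercept=0.0,
                            n=len(df), r_squared=float("nan"), see=0.0)
    return cross_validate(model, df)
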