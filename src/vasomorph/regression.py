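"""Linear tapering models of a vascular bed.

Within the 10-50 um caliber window, lumen diameter and wall thickness of
terminal arteries taper approximately linearly with external diameter.  The
bed is therefore summarized by the pair of regressions

    ID  = a * ED + b        (lumen taper)
    WTh = c * ED + d        (wall taper)

fitted to the 5-um interval means (each bin contributes one unweighted
point).  Outlying bins -- vessel subpopulations branching at different
hydrodynamic points -- are detected with the ROUT procedure (robust fit,
then FDR-controlled residual test) before the final ordinary least squares
pass.  An exponential alternative ``A*exp(k*ED)`` is available for wider
caliber ranges, with AICc-based model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TaperFit",
    "LineFit",
    "fit_taper",
    "fit_line_rout",
    "rout_outliers",
    "compare_fits",
    "FitComparison",
    "fit_exponential",
    "ExponentialComparison",
]


# ---------------------------------------------------------------------------
# core line fitting


@dataclass(frozen=True)
class LineFit:
    """One straight line ``y = slope * x + intercept`` with diagnostics."""

    slope: float
    intercept: float
    r2: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    n: int
    ssr: float
    x: np.ndarray
    y: np.ndarray
    removed: list[int] = field(default_factory=list)  # indices into the input

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept

    def se_predict(self, x) -> np.ndarray:
        """Standard error of the fitted line at x (coefficient uncertainty)."""
        x = np.asarray(x, float)
        c = self.cov
        var = c[0, 0] + 2 * x * c[0, 1] + x**2 * c[1, 1]
        return np.sqrt(np.maximum(var, 0.0))

    @property
    def sigma(self) -> float:
        dof = max(self.n - 2, 1)
        return math.sqrt(self.ssr / dof)

    def equation(self, lhs: str = "y", rhs: str = "x") -> str:
        return f"{lhs} = {self.slope:.4f}·{rhs} {'+' if self.intercept >= 0 else '-'} {abs(self.intercept):.4f}"


def _ols(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> LineFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if w is None:
        w = np.ones_like(x)
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ y, rcond=None)
    resid = y - X @ beta
    ssr = float(np.sum(w * resid**2))
    dof = max(len(x) - 2, 1)
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(XtW @ X)
    ybar = np.average(y, weights=w)
    sst = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return LineFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(r2),
        cov=cov,
        n=len(x),
        ssr=ssr,
        x=x,
        y=y,
    )


def _robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tukey-biweight robust straight line (IRLS), used as the ROUT base fit."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(50):
        resid = y - X @ beta
        s = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if s <= 0:
            break
        u = resid / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < 2:
            break
        XtW = X.T * w
        new = np.linalg.solve(XtW @ X, XtW @ y)
        if np.allclose(new, beta, rtol=1e-10, atol=1e-12):
            beta = new
            break
        beta = new
    return float(beta[0]), float(beta[1])


def rout_outliers(x: np.ndarray, y: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Indices of outliers under the ROUT procedure at FDR level ``q``.

    A robust line is fitted first; the robust standard deviation of the
    residuals (RSDR) is estimated from the 68.27th percentile of their
    absolute values with a small-sample correction, residuals are converted
    to t scores and tested with a Benjamini-Hochberg step-up at ``q``.
    ``q`` -> 0 flags nothing, recovering the plain robust fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4 or q <= 0:
        return np.array([], dtype=int)
    b0, b1 = _robust_line(x, y)
    resid = y - (b0 + b1 * x)
    # externally studentized: the point under test is excluded from its own
    # scale estimate, otherwise a single large outlier inflates the RSDR
    # enough to mask itself at small n
    absr = np.abs(resid)
    t = np.empty(n)
    for i in range(n):
        others = np.delete(absr, i)
        # variance-consistent de-bias of the percentile scale estimate:
        # residuals shrink by roughly sqrt((m - k)/m) under an m-point,
        # k-parameter fit
        m = n - 1
        rsdr = np.percentile(others, 68.27) * math.sqrt(m / max(m - 2, 1))
        t[i] = absr[i] / rsdr if rsdr > 0 else np.inf
    p = 2 * stats.t.sf(t, df=max(n - 2, 1))
    order = np.argsort(p)
    thresh = q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    if not passed.any():
        return np.array([], dtype=int)
    k = np.max(np.nonzero(passed)[0])
    return np.sort(order[: k + 1])


def fit_line_rout(
    x, y, robust: bool = True, rout_q: float = 0.01, w: np.ndarray | None = None
) -> LineFit:
    """ROUT-cleaned least squares: robust fit, outlier removal, then OLS."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    removed: list[int] = []
    keep = np.ones(len(x), bool)
    if robust:
        out = rout_outliers(x, y, q=rout_q)
        removed = [int(i) for i in out]
        keep[out] = False
        if keep.sum() < 2:
            raise ValueError("all points removed as outliers")
    fit = _ols(x[keep], y[keep], None if w is None else np.asarray(w, float)[keep])
    return replace(fit, removed=removed)


# ---------------------------------------------------------------------------
# taper fits


@dataclass
class TaperFit:
    """The pair of linear tapering regressions of one organ/group bed."""

    organ: str
    group: str
    id_fit: LineFit
    wth_fit: LineFit
    ed_range: tuple[float, float]
    n_bins: int
    removed_outliers: list[dict] = field(default_factory=list)
    #: caliber positions of the fitted points and their vessel counts --
    #: retained so the bed's accumulated-frequency structure can be matched
    #: across groups (complex-profile correspondence)
    caliber_points: np.ndarray | None = None
    caliber_counts: np.ndarray | None = None

    # convenience accessors matching the field's usual notation
    @property
    def id_slope(self) -> float:
        return self.id_fit.slope

    @property
    def id_intercept(self) -> float:
        return self.id_fit.intercept

    @property
    def wth_slope(self) -> float:
        return self.wth_fit.slope

    @property
    def wth_intercept(self) -> float:
        return self.wth_fit.intercept

    @property
    def r2_id(self) -> float:
        return self.id_fit.r2

    @property
    def r2_wth(self) -> float:
        return self.wth_fit.r2

    def predict_id(self, ed) -> np.ndarray:
        return self.id_fit.predict(ed)

    def predict_wth(self, ed) -> np.ndarray:
        return self.wth_fit.predict(ed)

    def warnings(self) -> list[str]:
        w = []
        if not (0.0 < self.id_slope < 1.0):
            w.append(
                f"id_slope {self.id_slope:.3f} outside (0, 1): not a physical tapering bed"
            )
        grid = np.linspace(*self.ed_range, 64)
        if np.any(self.predict_id(grid) >= grid):
            w.append("predicted ID >= ED somewhere on the fitted range")
        return w

    def as_dict(self) -> dict:
        return {
            "organ": self.organ,
            "group": self.group,
            "id_slope": self.id_slope,
            "id_intercept": self.id_intercept,
            "id_se_slope": float(np.sqrt(self.id_fit.cov[1, 1])),
            "id_se_intercept": float(np.sqrt(self.id_fit.cov[0, 0])),
            "r2_id": self.r2_id,
            "wth_slope": self.wth_slope,
            "wth_intercept": self.wth_intercept,
            "wth_se_slope": float(np.sqrt(self.wth_fit.cov[1, 1])),
            "wth_se_intercept": float(np.sqrt(self.wth_fit.cov[0, 0])),
            "r2_wth": self.r2_wth,
            "n_bins": self.n_bins,
            "ed_range": list(self.ed_range),
            "removed_outliers": self.removed_outliers,
            "equation_id": self.id_fit.equation("ID", "ED"),
            "equation_wth": self.wth_fit.equation("WTh", "ED"),
        }


def fit_taper(
    intervals: pd.DataFrame,
    organ: str = "",
    group: str = "",
    robust: bool = True,
    rout_q: float = 0.01,
    weight_by_n: bool = False,
) -> TaperFit:
    """Fit ``ID ~ ED`` and ``WTh ~ ED`` to interval means.

    Each bin contributes one point at its mean ED (unweighted by default,
    matching the mean-per-interval protocol; ``weight_by_n`` weights bins by
    their vessel counts instead).  With ``robust`` the ROUT procedure removes
    outlying bins at FDR level ``rout_q`` before the final OLS pass.
    """
    if len(intervals) < 4:
        raise ValueError(f"need >= 4 bins to fit a taper, got {len(intervals)}")
    x = intervals["mean_ED"].to_numpy(float)
    w = intervals["n"].to_numpy(float) if weight_by_n else None
    id_fit = fit_line_rout(x, intervals["mean_ID"].to_numpy(float), robust, rout_q, w)
    wth_fit = fit_line_rout(x, intervals["mean_WTh"].to_numpy(float), robust, rout_q, w)
    removed = [
        {"dimension": "ID", "bin_index": i, "mean_ED": float(x[i])} for i in id_fit.removed
    ] + [
        {"dimension": "WTh", "bin_index": i, "mean_ED": float(x[i])} for i in wth_fit.removed
    ]
    lo = float(intervals["bin_low"].min()) if "bin_low" in intervals else float(x.min())
    hi = float(intervals["bin_high"].max()) if "bin_high" in intervals else float(x.max())
    return TaperFit(
        organ=organ,
        group=group,
        id_fit=id_fit,
        wth_fit=wth_fit,
        ed_range=(lo, hi),
        n_bins=len(intervals),
        removed_outliers=removed,
        caliber_points=x.copy(),
        caliber_counts=intervals["n"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# slope / intercept comparison (two-line ANCOVA)


@dataclass
class FitComparison:
    """ANCOVA comparison of two regression lines."""

    f_slope: float
    p_slope: float
    slopes_differ: bool
    f_intercept: float | None
    p_intercept: float | None
    intercepts_differ: bool | None
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        if self.slopes_differ:
            return "slopes differ"
        if self.intercepts_differ:
            return "common slope, intercepts differ"
        return "not different"


def _ancova(x1, y1, x2, y2, alpha=0.05) -> FitComparison:
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])
    n = len(x)

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    ones = np.ones(n)
    ssr_full, k_full = ssr(np.column_stack([ones, x, g, g * x]))  # separate lines
    ssr_slope, k_slope = ssr(np.column_stack([ones, x, g]))  # common slope
    ssr_single, k_single = ssr(np.column_stack([ones, x]))  # one line

    df_full = n - k_full
    if df_full <= 0:
        raise ValueError("not enough points for ANCOVA")
    num = (ssr_slope - ssr_full) / (k_full - k_slope)
    den = ssr_full / df_full
    if den <= 0:
        # identical data fit exactly: no evidence of difference
        f_slope, p_slope = 0.0, 1.0
    else:
        f_slope = num / den
        p_slope = float(stats.f.sf(f_slope, k_full - k_slope, df_full))
    slopes_differ = p_slope < alpha

    f_int = p_int = None
    int_differ = None
    if not slopes_differ:
        df_slope = n - k_slope
        den2 = ssr_slope / df_slope
        if den2 <= 0:
            f_int, p_int = 0.0, 1.0
        else:
            f_int = (ssr_single - ssr_slope) / (k_slope - k_single) / den2
            p_int = float(stats.f.sf(f_int, k_slope - k_single, df_slope))
        int_differ = p_int < alpha
    return FitComparison(
        f_slope=float(f_slope),
        p_slope=float(p_slope),
        slopes_differ=bool(slopes_differ),
        f_intercept=None if f_int is None else float(f_int),
        p_intercept=p_int,
        intercepts_differ=int_differ,
        alpha=alpha,
    )


def compare_fits(
    f1: TaperFit, f2: TaperFit, dimension: str = "ID", alpha: float = 0.05
) -> FitComparison:
    """Test whether two tapering lines share slope and intercept.

    Classic two-line ANCOVA: the pooled common-slope model is tested against
    separate slopes with an F-test; if slopes are compatible, a common
    intercept is tested next.  Symmetric in its arguments.
    """
    lo = max(f1.ed_range[0], f2.ed_range[0])
    hi = min(f1.ed_range[1], f2.ed_range[1])
    if lo >= hi:
        raise ValueError("fits do not overlap in ED range")
    a = f1.id_fit if dimension == "ID" else f1.wth_fit
    b = f2.id_fit if dimension == "ID" else f2.wth_fit
    return _ancova(a.x, a.y, b.x, b.y, alpha=alpha)


# ---------------------------------------------------------------------------
# exponential alternative


@dataclass
class ExponentialComparison:
    """Exponential-growth fit and its comparison with the linear model."""

    amplitude: float
    rate: float
    r2: float
    ssr_exp: float
    ssr_lin: float
    aicc_exp: float
    aicc_lin: float
    akaike_weight_exp: float
    preferred: str  # "linear" | "exponential"
    converged: bool
    linear: LineFit


def _aicc(n: int, ssr: float, k: int) -> float:
    # k counts the variance term as a parameter, as in least-squares AICc
    aic = n * math.log(max(ssr, 1e-300) / n) + 2 * k
    corr = 2 * k * (k + 1) / max(n - k - 1, 1e-9)
    return aic + corr


def fit_exponential(
    intervals: pd.DataFrame, dimension: str = "ID", prefer_threshold: float = 0.95
) -> ExponentialComparison:
    """Fit ``y = A*exp(k*ED)`` to interval means and compare with the line.

    Both models have two coefficients, so the comparison uses corrected AIC
    (Akaike weights); the simpler linear model is recommended unless the
    exponential's Akaike weight exceeds ``prefer_threshold``.  On
    non-convergence the linear model is returned as the fallback.
    """
    if len(intervals) < 5:
        raise ValueError(f"need >= 5 bins for the exponential comparison, got {len(intervals)}")
    col = {"ID": "mean_ID", "WTh": "mean_WTh"}[dimension]
    x = intervals["mean_ED"].to_numpy(float)
    y = intervals[col].to_numpy(float)
    lin = _ols(x, y)
    n = len(x)

    converged = True
    try:
        # log-linear start values (y > 0 over the caliber window)
        ylog = np.log(np.maximum(y, 1e-9))
        k0, loga0 = np.polyfit(x, ylog, 1)
        popt, _ = optimize.curve_fit(
            lambda xx, a, k: a * np.exp(k * xx), x, y, p0=[math.exp(loga0), k0], maxfev=10000
        )
        a, k = float(popt[0]), float(popt[1])
        pred = a * np.exp(k * x)
        ssr_exp = float(np.sum((y - pred) ** 2))
    except Exception:
        converged = False
        a, k = float("nan"), float("nan")
        ssr_exp = float("inf")

    sst = float(np.sum((y - y.mean()) ** 2))
    r2_exp = 1 - ssr_exp / sst if sst > 0 and math.isfinite(ssr_exp) else float("nan")
    aicc_lin = _aicc(n, lin.ssr, 3)
    aicc_exp = _aicc(n, ssr_exp, 3) if math.isfinite(ssr_exp) else float("inf")
    d = aicc_exp - aicc_lin
    w_exp = 1.0 / (1.0 + math.exp(min(d / 2.0, 700.0))) if math.isfinite(d) else 0.0
    preferred = "exponential" if (converged and w_exp > prefer_threshold) else "linear"
    return ExponentialComparison(
        amplitude=a,
        rate=k,
        r2=r2_exp,
        ssr_exp=ssr_exp,
        ssr_lin=lin.ssr,
        aicc_exp=aicc_exp,
        aicc_lin=aicc_lin,
        akaike_weight_exp=float(w_exp),
        preferred=preferred,
        converged=converged,
        linear=lin,
    )
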