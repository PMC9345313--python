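"""Case-level group comparisons for nested (case / stack) designs.

The statistical pipeline mirrors common neuropathology practice:
responses (densities, percentages, per-bin contrasts) are optionally
power-transformed towards normality (Tukey's ladder of powers, or
Box–Cox with the power chosen by maximum likelihood or by Guerrero's
variance-stabilization method), checked with Shapiro–Wilk, and
compared between groups with a linear mixed-effects model

    response ~ fixed effect + (1 | case)

whose fixed-effect t-tests use Satterthwaite's degrees-of-freedom
approximation.  The random intercept absorbs between-case variation so
that multiple stacks from one brain are not treated as independent.

Model fitting is delegated to :class:`statsmodels` MixedLM (REML); the
Satterthwaite approximation is computed here from the closed-form REML
log-likelihood of the random-intercept model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "TransformResult",
    "transform",
    "normality_check",
    "ContrastResult",
    "MixedModelFit",
    "fit_group_model",
]


# ---------------------------------------------------------------------
# power transforms
# ---------------------------------------------------------------------

@dataclass
class TransformResult:
    values: np.ndarray
    lam: float
    method: str
    lambda_selection: str | None = None
    shift: float = 0.0


def _tukey_ladder(x: np.ndarray, lam: float) -> np.ndarray:
    # order-preserving ladder of powers
    if lam > 0:
        return x**lam
    if lam == 0:
        return np.log(x)
    return -(x**lam)


def transform(
    data,
    method: str = "box-cox",
    lambda_selection: str = "log-likelihood",
    shift: float | None = None,
) -> TransformResult:
    """Power-transform responses towards normality.

    ``tukey`` scans Tukey's ladder of powers (λ from −2 to 2 in steps
    of 0.025) and keeps the λ whose transformed data maximize the
    Shapiro–Wilk statistic.  ``box-cox`` selects λ either by maximizing
    the Box–Cox log-likelihood or by Guerrero's method.  Both require
    strictly positive data; pass an explicit ``shift`` constant to
    analyse data containing non-positive values (the shift is applied
    before, and reported with, the transform).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 3:
        raise ValueError("transform requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("power selection is undefined for all-equal data")
    applied_shift = float(shift) if shift is not None else 0.0
    x = x + applied_shift
    if np.any(x <= 0):
        raise ValueError(
            "power transforms require strictly positive data; supply a "
            "shift constant to offset non-positive values"
        )
    if method == "tukey":
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.025), 6)
        best_w, best_lam = -np.inf, 1.0
        for lam in grid:
            t = _tukey_ladder(x, lam)
            if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = sps.shapiro(t).statistic
            if w > best_w:
                best_w, best_lam = w, lam
        return TransformResult(
            values=_tukey_ladder(x, best_lam),
            lam=float(best_lam),
            method="tukey",
            shift=applied_shift,
        )
    if method in ("box-cox", "boxcox"):
        if lambda_selection in ("log-likelihood", "mle"):
            t, lam = sps.boxcox(x)
            return TransformResult(
                values=np.asarray(t),
                lam=float(lam),
                method="box-cox",
                lambda_selection="log-likelihood",
                shift=applied_shift,
            )
        if lambda_selection == "guerrero":
            lam = _guerrero_lambda(x)
            return TransformResult(
                values=special.boxcox(x, lam),
                lam=float(lam),
                method="box-cox",
                lambda_selection="guerrero",
                shift=applied_shift,
            )
        raise ValueError(f"unknown lambda selection {lambda_selection!r}")
    raise ValueError(f"unknown transform method {method!r}")


def _guerrero_lambda(x: np.ndarray, block: int = 2) -> float:
    """Guerrero's λ: minimize the coefficient of variation of
    s_h / m_h^(1−λ) over blocks of consecutive observations."""
    n_blocks = x.size // block
    if n_blocks < 2:
        raise ValueError("Guerrero selection needs at least 2 blocks of data")
    xb = x[: n_blocks * block].reshape(n_blocks, block)
    m = xb.mean(axis=1)
    s = xb.std(axis=1, ddof=1)
    valid = (m > 0) & (s > 0)
    if valid.sum() < 2:
        raise ValueError("Guerrero selection is degenerate for these data")
    m, s = m[valid], s[valid]

    def cv(lam):
        q = s / m ** (1.0 - lam)
        return q.std(ddof=1) / q.mean()

    res = optimize.minimize_scalar(cv, bounds=(-3.0, 3.0), method="bounded")
    return float(res.x)


def normality_check(data) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value; requires 3 ≤ n and non-constant data."""
    x = np.asarray(data, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("Shapiro–Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk is degenerate for constant data")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------
# mixed model with Satterthwaite degrees of freedom
# ---------------------------------------------------------------------

@dataclass
class ContrastResult:
    term: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class MixedModelFit:
    contrasts: list[ContrastResult]
    sigma2_case: float
    sigma2_resid: float
    n_obs: int
    n_cases: int
    singular: bool

    def contrast(self, term: str) -> ContrastResult:
        for c in self.contrasts:
            if c.term == term:
                return c
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(term=c.term, estimate=c.estimate, se=c.se,
                     t=c.t, df=c.df, p=c.p)
                for c in self.contrasts
            ]
        )


class _RemlParts:
    """Per-case sufficient statistics for the random-intercept REML
    log-likelihood, allowing O(p²) evaluation at any variance pair."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        order = np.argsort(codes, kind="stable")
        y, X, codes = y[order], X[order], codes[order]
        self.n, self.p = X.shape
        self.sizes = np.bincount(codes)
        self.G, self.g, self.h, self.sy, self.yty = [], [], [], [], []
        start = 0
        for n_i in self.sizes:
            Xi, yi = X[start : start + n_i], y[start : start + n_i]
            self.G.append(Xi.T @ Xi)
            self.g.append(Xi.sum(axis=0))
            self.h.append(Xi.T @ yi)
            self.sy.append(yi.sum())
            self.yty.append(float(yi @ yi))
            start += n_i

    def xtvix(self, s2b: float, s2e: float) -> np.ndarray:
        A = np.zeros((self.p, self.p))
        for G, g, n_i in zip(self.G, self.g, self.sizes):
            c = s2b / (s2e + n_i * s2b)
            A += G - c * np.outer(g, g)
        return A / s2e

    def loglik(self, s2b: float, s2e: float) -> float:
        if s2e <= 0 or s2b < 0:
            return -np.inf
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        quad = 0.0
        logdet_v = 0.0
        for G, g, h, sy, yty, n_i in zip(
            self.G, self.g, self.h, self.sy, self.yty, self.sizes
        ):
            c = s2b / (s2e + n_i * s2b)
            A += G - c * np.outer(g, g)
            b += h - c * g * sy
            quad += yty - c * sy**2
            logdet_v += (n_i - 1) * math.log(s2e) + math.log(s2e + n_i * s2b)
        A /= s2e
        b /= s2e
        quad /= s2e
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(A, b)
        return -0.5 * (logdet_v + logdet_a + quad - b @ beta)


def _satterthwaite_df(
    parts: _RemlParts, theta: np.ndarray, coef_index: int
) -> float:
    """Satterthwaite df for one fixed-effect coefficient.

    df = 2 g² / (∇g' A ∇g) with g(θ) the coefficient's sampling
    variance l'(X'V⁻¹X)⁻¹l, ∇g its numerical gradient over the variance
    components θ = (σ²_case, σ²_resid), and A the asymptotic covariance
    of θ̂ from the numerically observed REML information.
    """
    s2b, s2e = theta

    def gfun(th):
        A = parts.xtvix(max(th[0], 0.0), th[1])
        return float(np.linalg.inv(A)[coef_index, coef_index])

    steps = np.array([max(s2b, 1e-3 * s2e) * 1e-4 + 1e-12, s2e * 1e-4])
    grad = np.zeros(2)
    for k in range(2):
        e = np.zeros(2)
        e[k] = steps[k]
        grad[k] = (gfun(theta + e) - gfun(np.maximum(theta - e, [0.0, 1e-300]))) / (
            steps[k] + min(theta[k], steps[k])
        )
    # observed information: numerical Hessian of the REML log-likelihood
    hstep = np.array([max(s2b, 1e-2 * s2e) * 1e-3, s2e * 1e-3])
    H = np.zeros((2, 2))
    f0 = parts.loglik(s2b, s2e)
    for j in range(2):
        for k in range(j, 2):
            ej = np.zeros(2); ej[j] = hstep[j]
            ek = np.zeros(2); ek[k] = hstep[k]
            if j == k:
                fp = parts.loglik(*(theta + ej))
                fm = parts.loglik(*np.maximum(theta - ej, [0.0, 1e-300]))
                H[j, j] = (fp - 2 * f0 + fm) / (hstep[j] ** 2)
            else:
                fpp = parts.loglik(*(theta + ej + ek))
                fpm = parts.loglik(*np.maximum(theta + ej - ek, [0.0, 1e-300]))
                fmp = parts.loglik(*np.maximum(theta - ej + ek, [0.0, 1e-300]))
                fmm = parts.loglik(*np.maximum(theta - ej - ek, [0.0, 1e-300]))
                H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (
                    4 * hstep[j] * hstep[k]
                )
    g0 = gfun(theta)
    try:
        cov_theta = np.linalg.inv(-H)
        denom = float(grad @ cov_theta @ grad)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        return float(parts.n - parts.p)
    df = 2.0 * g0**2 / denom
    if not np.isfinite(df) or df <= 0:
        return float(parts.n - parts.p)
    return float(min(df, parts.n - parts.p))


def _design_matrix(data: pd.DataFrame, fixed: str, reference) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(data[fixed]))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not found in {fixed!r}")
    others = [lv for lv in levels if lv != reference]
    X = np.ones((len(data), 1 + len(others)))
    names = ["(Intercept)"]
    for j, lv in enumerate(others, start=1):
        X[:, j] = (data[fixed] == lv).to_numpy(dtype=float)
        names.append(f"{fixed}[{lv}]")
    return X, names


def fit_group_model(
    data: pd.DataFrame,
    response: str = "response",
    fixed: str = "group",
    case: str = "case",
    reference=None,
    aggregate: str | None = None,
    stack: str = "stack",
) -> MixedModelFit:
    """Fit ``response ~ fixed + (1 | case)`` and test fixed-effect contrasts.

    Every non-reference level of ``fixed`` is contrasted against the
    reference level (treatment coding; marginal t-tests) with
    Satterthwaite-approximated degrees of freedom.  Requires at least
    two cases.  When between-case variance collapses to zero the fit is
    reported with ``singular=True`` (inference then coincides with
    ordinary least squares) rather than failing.

    ``aggregate="median"`` first takes the median response per case and
    fixed-effect level across stacks, matching per-case reporting.
    """
    df = data.copy()
    for col in (response, fixed, case):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from the observations")
    if not np.all(np.isfinite(df[response].to_numpy(dtype=float))):
        raise ValueError("responses must be finite")
    if aggregate == "median":
        df = (
            df.groupby([case, fixed], sort=False, observed=True)[response]
            .median()
            .reset_index()
        )
    elif aggregate is not None:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    if df[case].nunique() < 2:
        raise ValueError("mixed model requires at least 2 cases")

    y = df[response].to_numpy(dtype=float)
    X, names = _design_matrix(df, fixed, reference)
    codes = pd.factorize(df[case])[0]
    n, p = X.shape

    singular = False
    s2b = s2e = None
    if np.ptp(y) == 0:
        singular = True
        s2b, s2e = 0.0, 0.0
        beta = np.zeros(p)
        beta[0] = y[0]
        cov_beta = np.zeros((p, p))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = MixedLM(y, X, groups=codes).fit(reml=True)
                s2e = float(fit.scale)
                s2b = float(np.asarray(fit.cov_re)[0, 0])
                beta = np.asarray(fit.fe_params, dtype=float)
            except Exception:
                fit = None
        if s2e is None or not np.isfinite(s2e):
            # boundary/converge failure: ordinary least squares fallback
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            s2e = float(resid @ resid / max(n - p, 1))
            s2b = 0.0
            singular = True
        if s2b <= 1e-8 * max(s2e, 1e-300):
            singular = True
        parts = _RemlParts(y, X, codes)
        cov_beta = np.linalg.inv(parts.xtvix(max(s2b, 0.0), s2e))

    contrasts = []
    for j in range(1, p):
        est = float(beta[j])
        se = float(math.sqrt(max(cov_beta[j, j], 0.0)))
        if se == 0.0:
            contrasts.append(
                ContrastResult(names[j], est, 0.0, np.nan, np.nan, np.nan)
            )
            continue
        if singular:
            dof = float(n - p)
        else:
            dof = _satterthwaite_df(parts, np.array([s2b, s2e]), j)
        tval = est / se
        pval = 2.0 * sps.t.sf(abs(tval), dof)
        contrasts.append(ContrastResult(names[j], est, se, tval, dof, pval))

    return MixedModelFit(
        contrasts=contrasts,
        sigma2_case=float(s2b),
        sigma2_resid=float(s2e),
        n_obs=int(n),
        n_cases=int(df[case].nunique()),
        singular=singular,
    )
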