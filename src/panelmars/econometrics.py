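"""Pre-spline screens: 2SLS, the Hausman endogeneity test and the stacked
(common-coefficient) panel Granger causality test.

The Hausman test compares the OLS and instrumental-variable coefficient
vectors in the matrix-difference form
H = (b_IV - b_OLS)' [V_IV - V_OLS]^+ (b_IV - b_OLS), with negative
eigenvalues of the covariance difference clipped at zero before the
pseudo-inverse, so the statistic is always non-negative.  Under the null
of exogeneity H is asymptotically chi-square with df equal to the number
of compared (instrumented) coefficients.

The stacked Granger test pools all countries into one regression with
common coefficients: effect_t on a constant, L lags of itself and L lags
of the candidate cause, lags built within each country (no cross-border
lags).  The F test of joint nullity of the cause lags has df
(L, n_obs - 2L - 1).  By default the series are first-differenced within
each country before lag construction — the standard stationarity
treatment for trending macro panels, and the convention that yields 280
pooled observations on a 14-country x 23-year panel with two lags;
pass ``difference=False`` to run the test on the series as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .panel import PanelDataset

__all__ = [
    "EconError",
    "RegressionResult",
    "TestResult",
    "ols_regression",
    "tsls_fit",
    "hausman_test",
    "hausman_screen",
    "granger_stacked",
    "chi2_sf",
    "f_sf",
]


class EconError(ValueError):
    """Invalid input to an econometric screen."""


@dataclass
class RegressionResult:
    coefficients: np.ndarray
    covariance: np.ndarray
    rss: float
    n: int
    names: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = self.coefficients.size
        if self.covariance.shape != (k, k):
            raise EconError("covariance dimensions do not match coefficients")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise EconError("covariance is not symmetric")
        if len(self.names) != k:
            raise EconError("names do not match coefficients")

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


@dataclass
class TestResult:
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    n_obs: int
    description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise EconError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# distribution tails (validated wrappers)
# ---------------------------------------------------------------------------


def chi2_sf(x: float, df: int) -> float:
    """Upper tail of the chi-square distribution."""
    if df < 1:
        raise EconError(f"chi-square df must be >= 1, got {df}")
    if x < 0:
        raise EconError(f"chi-square statistic must be >= 0, got {x}")
    return float(stats.chi2.sf(x, df))


def f_sf(x: float, df1: int, df2: int) -> float:
    """Upper tail of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise EconError(f"F degrees of freedom must be >= 1, got ({df1}, {df2})")
    if x < 0:
        raise EconError(f"F statistic must be >= 0, got {x}")
    return float(stats.f.sf(x, df1, df2))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def ols_regression(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> RegressionResult:
    """OLS with the classical (non-robust) covariance estimate."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        rss=float(res.ssr),
        n=int(res.nobs),
        names=list(names),
    )


def _as_matrix(a, n: int) -> np.ndarray:
    if a is None:
        return np.empty((n, 0))
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def tsls_fit(
    y: np.ndarray,
    exog,
    endog,
    instruments,
    names: list[str] | None = None,
) -> RegressionResult:
    """Two-stage least squares with classical covariance.

    First stage projects the endogenous columns on [exog, instruments];
    the second stage regresses y on [exog, fitted endogenous columns].
    Residuals (and hence the error variance) are computed against the
    original regressors.  Requires at least as many instruments as
    endogenous columns and a full-rank instrument set.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    exog = _as_matrix(exog, n)
    endog = _as_matrix(endog, n)
    instruments = _as_matrix(instruments, n)
    if endog.shape[0] != n or exog.shape[0] != n or instruments.shape[0] != n:
        raise EconError("row counts of y, exog, endog, instruments disagree")
    if instruments.shape[1] < endog.shape[1]:
        raise EconError(
            f"under-identified: {instruments.shape[1]} instruments for "
            f"{endog.shape[1]} endogenous columns"
        )
    Z = np.column_stack([exog, instruments])
    if np.linalg.matrix_rank(Z) < min(Z.shape):
        raise EconError("instrument set is rank deficient")
    proj, *_ = np.linalg.lstsq(Z, endog, rcond=None)
    endog_hat = Z @ proj
    W_hat = np.column_stack([exog, endog_hat])
    W = np.column_stack([exog, endog])
    beta, *_ = np.linalg.lstsq(W_hat, y, rcond=None)
    resid = y - W @ beta
    rss = float(resid @ resid)
    k = W.shape[1]
    sigma2 = rss / (n - k)
    cov = sigma2 * np.linalg.inv(W_hat.T @ W_hat)
    if names is None:
        names = [f"exog{j}" for j in range(exog.shape[1])] + [
            f"endog{j}" for j in range(endog.shape[1])
        ]
    return RegressionResult(beta, cov, rss, n, list(names))


def hausman_test(
    ols: RegressionResult,
    iv: RegressionResult,
    names: list[str] | None = None,
) -> TestResult:
    """Hausman specification test of OLS against an IV fit.

    ``names`` selects the coefficients to compare (typically the
    instrumented ones); by default all names shared by the two fits are
    used.  The covariance difference is symmetrised, its negative
    eigenvalues clipped at zero, and inverted by pseudo-inverse.
    """
    if names is None:
        names = [nm for nm in iv.names if nm in ols.names]
    if not names:
        raise EconError("no common coefficients to compare")
    try:
        i_ols = [ols.names.index(nm) for nm in names]
        i_iv = [iv.names.index(nm) for nm in names]
    except ValueError as exc:
        raise EconError(f"coefficient name not found: {exc}") from None
    d = iv.coefficients[i_iv] - ols.coefficients[i_ols]
    V = iv.covariance[np.ix_(i_iv, i_iv)] - ols.covariance[np.ix_(i_ols, i_ols)]
    V = (V + V.T) / 2.0
    w, Q = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    tol = 1e-12 * max(float(w.max(initial=0.0)), 1e-300)
    winv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
    stat = float(d @ (Q * winv) @ (Q.T @ d))
    stat = max(stat, 0.0)
    df = len(names)
    return TestResult(
        statistic=stat,
        df=df,
        p_value=chi2_sf(stat, df),
        n_obs=ols.n,
        description=f"Hausman test on {', '.join(names)}",
    )


def hausman_screen(
    ds: PanelDataset,
    response: str,
    instrumented: list[str],
    instruments: list[str],
) -> tuple[RegressionResult, RegressionResult, TestResult]:
    """Panel-level Hausman screen.

    OLS of the response on a constant plus the instrumented variables,
    against the 2SLS fit that instruments those variables with a constant
    plus the given instrument set; the test compares the instrumented
    coefficients (df = len(instrumented)).
    """
    f = ds.frame
    for v in [response, *instrumented, *instruments]:
        if v not in ds.variable_names:
            raise EconError(f"unknown variable {v!r}")
    y = f[response].to_numpy(dtype=float)
    n = y.size
    const = np.ones((n, 1))
    endog = f[list(instrumented)].to_numpy(dtype=float)
    zmat = f[list(instruments)].to_numpy(dtype=float)
    names = ["const", *instrumented]
    ols = ols_regression(y, np.column_stack([const, endog]), names)
    iv = tsls_fit(y, const, endog, zmat, names)
    test = hausman_test(ols, iv, names=list(instrumented))
    return ols, iv, test


# ---------------------------------------------------------------------------
# stacked panel Granger causality
# ---------------------------------------------------------------------------


def granger_stacked(
    ds: PanelDataset,
    cause: str,
    effect: str,
    lags: int = 2,
    difference: bool = True,
) -> TestResult:
    """Pooled common-coefficient Granger causality test.

    Null hypothesis: ``cause`` does not Granger-cause ``effect``.
    """
    if lags < 1:
        raise EconError("lags must be >= 1")
    for v in (cause, effect):
        if v not in ds.variable_names:
            raise EconError(f"unknown variable {v!r}")
    f = ds.frame
    rows_y, rows_full, rows_res = [], [], []
    for _, g in f.groupby("country", sort=True):
        c = g[cause].to_numpy(dtype=float)
        e = g[effect].to_numpy(dtype=float)
        if difference:
            c = np.diff(c)
            e = np.diff(e)
        T = e.size
        if T <= lags:
            raise EconError(
                f"insufficient years: {T} usable observations per country "
                f"for {lags} lags"
            )
        for t in range(lags, T):
            e_lags = [e[t - j] for j in range(1, lags + 1)]
            c_lags = [c[t - j] for j in range(1, lags + 1)]
            rows_y.append(e[t])
            rows_full.append([1.0, *e_lags, *c_lags])
            rows_res.append([1.0, *e_lags])
    yv = np.array(rows_y)
    Xf = np.array(rows_full)
    Xr = np.array(rows_res)
    n_obs = yv.size
    df2 = n_obs - (2 * lags + 1)
    if df2 < 1:
        raise EconError(f"not enough pooled observations ({n_obs}) for the F test")
    full = sm.OLS(yv, Xf).fit()
    restr = sm.OLS(yv, Xr).fit()
    fstat = float(((restr.ssr - full.ssr) / lags) / (full.ssr / df2))
    fstat = max(fstat, 0.0)
    return TestResult(
        statistic=fstat,
        df=(lags, df2),
        p_value=f_sf(fstat, lags, df2),
        n_obs=n_obs,
        description=f"{cause} does not Granger cause {effect} (lags={lags})",
    )
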