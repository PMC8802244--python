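"""Beta regression and auxiliary statistics.

Beta regression models a response strictly inside (0, 1) — here the
heterozygous fraction of sites — with a beta likelihood parameterized by
mean and precision: ``y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)`` with
``logit(mu_i) = x_i' beta`` and a single constant precision ``phi``.
Estimation is by maximum likelihood over ``(beta, log phi)`` with analytic
gradient, quasi-Newton optimization and OLS-on-logit starting values.
The pseudo-R² is the squared Pearson correlation between the link-scale
response ``logit(y)`` and the fitted linear predictor; Wald p-values come
from the observed-information covariance.

Also here: a likelihood-ratio test for nested beta models, the exhaustive
leave-five-out subset-slope distribution, OLS (used by the survivorship
grid scan), and a small formula front-end ("y ~ a * b") building design
matrices with main effects and pairwise products only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("agestruct")


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def sigmoid(x):
    return special.expit(x)


@dataclass
class BetaFit:
    """Maximum-likelihood beta-regression fit."""

    coefficients: np.ndarray       # link-scale, intercept first
    phi_prec: float                # precision parameter
    loglik: float
    pseudo_R2: float
    wald_z: np.ndarray
    wald_p: np.ndarray
    se: np.ndarray
    n: int
    names: list = field(default_factory=list)
    grad_norm: float = float("nan")
    converged: bool = True

    @property
    def n_params(self) -> int:
        return self.coefficients.size + 1

    def summary_frame(self) -> pd.DataFrame:
        names = self.names or [f"x{i}" for i in range(self.coefficients.size)]
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "z": self.wald_z,
                "p": self.wald_p,
            },
            index=names,
        )


def _negloglik_and_grad(params, y, X):
    k = X.shape[1]
    beta, logphi = params[:k], params[k]
    phi = np.exp(min(max(logphi, -30.0), 30.0))
    eta = X @ beta
    mu = np.clip(sigmoid(eta), 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ystar = np.log(y) - np.log1p(-y)          # logit(y)
    ll = (
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    ).sum()
    # d ll / d mu = phi * (ystar - (digamma(a) - digamma(b)))
    mustar = special.digamma(a) - special.digamma(b)
    dmu = phi * (ystar - mustar)
    deta = dmu * mu * (1.0 - mu)
    gbeta = X.T @ deta
    dphi = (
        special.digamma(phi) - mu * special.digamma(a) - (1 - mu) * special.digamma(b)
        + mu * np.log(y) + (1 - mu) * np.log1p(-y)
    ).sum()
    glogphi = dphi * phi
    grad = np.append(gbeta, glogphi)
    return -ll, -grad


def fit_beta_regression(
    y,
    X,
    names: list | None = None,
    tol: float = 1e-10,
) -> BetaFit:
    """ML beta regression with logit link and constant precision.

    Parameters
    ----------
    y : array in (0, 1)
        Response proportions (strictly inside the unit interval).
    X : 2-D array
        Design matrix including the intercept column.
    names : list of str, optional
        Column names for reporting.

    Raises
    ------
    ValueError for responses outside (0, 1) or collinear designs;
    RuntimeError when the optimizer fails to reach a small gradient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per observation")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response values must lie strictly inside (0, 1)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    # starting values: OLS on logit(y); precision from its residual variance
    ystar = logit(y)
    beta0, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    resid = ystar - X @ beta0
    if float(resid.var()) < 1e-14:
        # degenerate perfect fit: logit(y) is exactly affine in X, the
        # precision diverges and the likelihood is unbounded
        k0 = X.shape[1]
        return BetaFit(
            coefficients=beta0, phi_prec=float("inf"), loglik=float("inf"),
            pseudo_R2=1.0, wald_z=np.full(k0, np.inf), wald_p=np.zeros(k0),
            se=np.zeros(k0), n=int(y.size),
            names=list(names) if names is not None else [],
            grad_norm=0.0, converged=True,
        )
    mu0 = sigmoid(X @ beta0)
    s2 = max(float(resid.var()), 1e-6)
    phi0 = max(float(np.mean(1.0 / (s2 * mu0 * (1 - mu0)))) - 1.0, 1.0)
    x0 = np.append(beta0, np.log(phi0))

    res = optimize.minimize(
        _negloglik_and_grad, x0, args=(y, X), jac=True, method="BFGS",
        options={"gtol": tol, "maxiter": 500},
    )
    # polish with a second pass and Newton refinement if needed
    if np.linalg.norm(res.jac) > 1e-6:
        res = optimize.minimize(
            _negloglik_and_grad, res.x, args=(y, X), jac=True,
            method="L-BFGS-B", options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000},
        )
    x_best = res.x
    f_best, g_best = _negloglik_and_grad(x_best, y, X)
    for _ in range(20):
        if np.linalg.norm(g_best) <= 1e-8:
            break
        H = _numerical_hessian(x_best, y, X)
        try:
            step = np.linalg.solve(H, g_best)
        except np.linalg.LinAlgError:
            break
        for damp in (1.0, 0.5, 0.25, 0.1):
            x_try = x_best - damp * step
            f_try, g_try = _negloglik_and_grad(x_try, y, X)
            if np.isfinite(f_try) and (
                f_try <= f_best + 1e-9
                or np.linalg.norm(g_try) < 0.5 * np.linalg.norm(g_best)
            ):
                x_best, f_best, g_best = x_try, f_try, g_try
                break
        else:
            break
    res.x, res.fun, res.jac = x_best, f_best, g_best
    grad_norm = float(np.linalg.norm(res.jac))
    k = X.shape[1]
    if grad_norm > 1e-6:
        # perfect-fit limit: logit(y) exactly affine in X drives the
        # precision to infinity; accept when the mean-model gradient has
        # vanished and the precision sits at its overflow guard
        beta_grad = float(np.linalg.norm(res.jac[:k]))
        if beta_grad < 1e-6 and res.x[k] >= 29.5:
            grad_norm = beta_grad
        else:
            raise RuntimeError(
                f"beta-regression optimizer did not converge: |grad| = {grad_norm:.3g}"
            )

    beta_hat = res.x[:k]
    phi_hat = float(np.exp(min(res.x[k], 30.0)))
    eta = X @ beta_hat

    # observed information in (beta, log phi) via central differences of the
    # analytic gradient; delta method back to (beta, phi) is not needed for
    # the beta block
    hess = _numerical_hessian(res.x, y, X)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se_beta = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    z = beta_hat / se_beta
    p = 2.0 * stats.norm.sf(np.abs(z))

    r = np.corrcoef(logit(y), eta)[0, 1] if np.std(eta) > 0 else 0.0
    return BetaFit(
        coefficients=beta_hat,
        phi_prec=phi_hat,
        loglik=float(-res.fun),
        pseudo_R2=float(r ** 2),
        wald_z=z,
        wald_p=p,
        se=se_beta,
        n=int(y.size),
        names=list(names) if names is not None else [],
        grad_norm=grad_norm,
        converged=True,
    )


def _numerical_hessian(x, y, X, eps: float = 1e-5):
    n = x.size
    H = np.empty((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        _, gp = _negloglik_and_grad(xp, y, X)
        _, gm = _negloglik_and_grad(xm, y, X)
        H[:, j] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def likelihood_ratio_test(fit_full: BetaFit, fit_reduced: BetaFit) -> dict:
    """LR test of nested beta-regression models on the same response."""
    if fit_full.n != fit_reduced.n:
        raise ValueError("models were fitted to different numbers of observations")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("fit_full must not have fewer parameters than fit_reduced")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    if df == 0:
        return {"statistic": stat, "df": 0, "p": 1.0}
    return {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


@dataclass
class SubsetDistribution:
    """Exhaustive leave-out subset distribution of slopes and pseudo-R²."""

    k: int
    n: int
    slopes: np.ndarray
    pseudo_R2: np.ndarray
    n_failed: int

    @property
    def n_subsets(self) -> int:
        return self.slopes.size

    def quantiles(self, qs=(0.025, 0.975)) -> dict:
        return {
            "slope": np.quantile(self.slopes, qs).tolist(),
            "pseudo_R2": np.quantile(self.pseudo_R2, qs).tolist(),
        }


def subset_slope_distribution(y, x, k: int = 11) -> SubsetDistribution:
    """Beta-regression slopes over all C(n, k) subsets of the species.

    Fits ``diversity ~ covariate`` on every subset of size ``k`` (exhaustive
    enumeration, no sampling).  Subsets with a degenerate covariate are
    skipped with a log message.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if k >= n:
        raise ValueError("subset size k must be smaller than n")
    slopes, r2s, failed = [], [], 0
    for idx in itertools.combinations(range(n), k):
        idx = np.asarray(idx)
        xs = x[idx]
        if np.ptp(xs) == 0:
            failed += 1
            logger.warning("skipping degenerate subset (constant covariate)")
            continue
        X = np.column_stack([np.ones(k), xs])
        try:
            fit = fit_beta_regression(y[idx], X)
        except (RuntimeError, ValueError) as exc:
            failed += 1
            logger.warning("subset fit failed: %s", exc)
            continue
        slopes.append(fit.coefficients[1])
        r2s.append(fit.pseudo_R2)
    return SubsetDistribution(
        k=k, n=n, slopes=np.asarray(slopes), pseudo_R2=np.asarray(r2s), n_failed=failed
    )


@dataclass
class OLSFit:
    slope: float
    intercept: float
    R2: float
    p_slope: float


def ols_slope_r2(x, y) -> OLSFit:
    """Ordinary least squares of y on x with slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R2=float(res.rvalue ** 2),
        p_slope=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# formula front-end
# ---------------------------------------------------------------------------

def design_from_formula(df: pd.DataFrame, formula: str):
    """Design matrix from a formula like ``"diversity ~ adult_lifespan * parental_care"``.

    Supports ``+`` (additive terms), ``*`` (main effects plus pairwise
    product) and ``:`` (product only).  Categorical columns are
    dummy-encoded dropping the first level; for interaction purposes a
    binary indicator collapses the category to "non-reference vs reference".

    Returns ``(y, X, names)``.
    """
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = (side.strip() for side in formula.split("~", 1))
    y = df[lhs].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["Intercept"]

    def numeric(term: str) -> np.ndarray:
        col = df[term]
        if col.dtype == object or str(col.dtype) == "category":
            # binary indicator: non-reference level(s) vs the first level
            ref = sorted(col.dropna().unique())[0]
            return (col != ref).to_numpy(dtype=float)
        return col.to_numpy(dtype=float)

    def add(name: str, values: np.ndarray) -> None:
        if name not in names:
            cols.append(values)
            names.append(name)

    for raw in (t.strip() for t in rhs.split("+")):
        if not raw:
            continue
        if "*" in raw:
            a, b = (s.strip() for s in raw.split("*", 1))
            add(a, numeric(a))
            add(b, numeric(b))
            add(f"{a}:{b}", numeric(a) * numeric(b))
        elif ":" in raw:
            a, b = (s.strip() for s in raw.split(":", 1))
            add(f"{a}:{b}", numeric(a) * numeric(b))
        else:
            add(raw, numeric(raw))
    X = np.column_stack(cols)
    return y, X, names


def fit_formula(df: pd.DataFrame, formula: str) -> BetaFit:
    """Beta regression from a trait DataFrame and a formula string."""
    y, X, names = design_from_formula(df, formula)
    return fit_beta_regression(y, X, names=names)
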