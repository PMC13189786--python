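"""Firth bias-reduced logistic regression for rare binary outcomes.

Maximizes the Jeffreys-prior-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 ln det I(beta)

by Newton iterations on the modified score

    U*_r = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ir,

where h_i are the hat values of the penalized weight matrix. Estimates stay
finite even under complete separation, which ordinary maximum likelihood
cannot achieve, and are shrunk toward zero relative to ML. Inference is
Wald by default; penalized-likelihood-ratio profile intervals are available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = ["FirthFit", "firth_fit", "wald_summary", "vif", "build_design", "DesignSpec"]


@dataclass(frozen=True)
class DesignSpec:
    """Model terms for the non-response regression.

    The pattern term is mandatory; covariates are single-column coded (age
    and BMI continuous, binaries 0/1, chemotherapy regimen as one ordinal
    0/1/2 column), so every term maps to exactly one odds ratio.
    """

    terms: tuple[str, ...] = (
        "pattern_b",
        "age",
        "bmi",
        "menopausal_status",
        "family_history",
        "childbirth_history",
        "regimen",
        "er",
        "pr",
        "her2",
        "ki67_high",
    )

    def __post_init__(self) -> None:
        if "pattern_b" not in self.terms:
            raise ValueError("the design must include the pattern term 'pattern_b'")


def build_design(data: pd.DataFrame, pattern_b: np.ndarray, spec: DesignSpec | None = None) -> pd.DataFrame:
    """Assemble the regression design (without intercept) from a cohort table."""
    spec = spec or DesignSpec()
    cols = {}
    for t in spec.terms:
        cols[t] = pattern_b.astype(float) if t == "pattern_b" else data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols)


@dataclass
class FirthFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray               # inverse penalized information
    loglik_penalized: float
    converged: bool
    n_iter: int
    n_obs: int
    n_events: int
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return expit(X @ self.beta)


def _penalized_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    XW = X * w[:, None]
    info = X.T @ XW
    chol = cho_factor(info)
    # h_i = w_i x_i' I^{-1} x_i
    A = cho_solve(chol, X.T)
    h = w * np.einsum("ij,ji->i", X, A)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta))) + 0.5 * logdet
    score = X.T @ (y - p + h * (0.5 - p))
    return p, chol, ll, score


def firth_fit(
    X,
    y,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FirthFit:
    """Fit the Firth-penalized logistic model.

    ``X`` is the predictor matrix (a DataFrame or array, without intercept
    unless ``add_intercept=False``); ``y`` the 0/1 outcome. Raises on a
    rank-deficient design, naming the aliased columns. Convergence: max
    |modified score| < tol, with step-halving on any decrease of the
    penalized log-likelihood.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        names = names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("outcome must contain both levels")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True)
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")

    beta = np.zeros(X.shape[1])
    _, _, ll, score = _penalized_parts(X, y, beta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p, chol, ll, score = _penalized_parts(X, y, beta)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = cho_solve(chol, score)
        # step-halving: accept only non-decreasing penalized log-likelihood
        for _ in range(25):
            beta_new = beta + step
            _, _, ll_new, _ = _penalized_parts(X, y, beta_new)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta_new
        path.append(ll_new)
    p, chol, ll, score = _penalized_parts(X, y, beta)
    if np.max(np.abs(score)) < tol:
        converged = True
    cov = cho_solve(chol, np.eye(X.shape[1]))
    return FirthFit(
        names=names,
        beta=beta,
        cov=cov,
        loglik_penalized=ll,
        converged=converged,
        n_iter=it,
        n_obs=len(y),
        n_events=int(y.sum()),
        loglik_path=np.asarray(path),
    )


def wald_summary(fit: FirthFit, conf_level: float = 0.95, drop_intercept: bool = True) -> pd.DataFrame:
    """Odds-ratio table: OR = exp(beta), Wald CI = exp(beta +/- z*SE), p-values.

    Row order follows the design; suitable as forest-plot export
    (term, OR, ci_low, ci_high, p).
    """
    z = norm.ppf(0.5 + conf_level / 2.0)
    se = fit.se
    zstat = fit.beta / se
    tab = pd.DataFrame(
        {
            "term": fit.names,
            "beta": fit.beta,
            "se": se,
            "or": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
            "p": 2.0 * norm.sf(np.abs(zstat)),
        }
    )
    if drop_intercept and tab["term"].iloc[0] == "intercept":
        tab = tab.iloc[1:].reset_index(drop=True)
    return tab


def profile_ci(X, y, term_index: int, conf_level: float = 0.95, **fit_kwargs) -> tuple[float, float]:
    """Penalized-likelihood-ratio profile CI for one coefficient (slower, more
    accurate than Wald for very rare events)."""
    from scipy.stats import chi2

    full = firth_fit(X, y, **fit_kwargs)
    Xmat = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if fit_kwargs.get("add_intercept", True):
        Xmat = np.column_stack([np.ones(len(y)), Xmat])
        term_index = term_index + 1
    target = full.loglik_penalized - 0.5 * chi2.ppf(conf_level, 1)

    def prof(b_fix: float) -> float:
        others = [j for j in range(Xmat.shape[1]) if j != term_index]
        offset = Xmat[:, term_index] * b_fix
        # profile out remaining coefficients by refitting with an offset
        yv = np.asarray(y, float)
        Xo = Xmat[:, others]
        beta = np.zeros(Xo.shape[1])
        for _ in range(200):
            eta = Xo @ beta + offset
            p = expit(eta)
            w = np.clip(p * (1 - p), 1e-12, None)
            info = Xo.T @ (Xo * w[:, None])
            chol = cho_factor(info)
            h = w * np.einsum("ij,ji->i", Xo, cho_solve(chol, Xo.T))
            score = Xo.T @ (yv - p + h * (0.5 - p))
            if np.max(np.abs(score)) < 1e-6:
                break
            beta = beta + cho_solve(chol, score)
        eta = Xo @ beta + offset
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = Xo.T @ (Xo * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        return float(np.sum(yv * eta - np.logaddexp(0, eta)) + 0.5 * logdet) - target

    bhat = full.beta[term_index]
    sehat = full.se[term_index]
    lo = brentq(prof, bhat - 8 * sehat, bhat)
    hi = brentq(prof, bhat, bhat + 8 * sehat)
    return float(lo), float(hi)


def vif(design) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Each predictor is least-squares-regressed on the remaining predictors
    plus an intercept. Exactly collinear columns are reported as ``inf``.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 predictor columns")
    out = {}
    for j in range(k):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = float(np.sum((target - target.mean()) ** 2))
        if sst <= 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
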