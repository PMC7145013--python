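"""Maximum-likelihood engines for the three model families the analysis uses.

Probit (propensity), logistic (90-day outcomes) and ordinary least squares on
log cost are fitted by Newton–Raphson with step-halving.  Coefficient order is
fixed by an explicit :class:`DesignSpec` (treatment coding against stated
reference levels) so fitted vectors are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .params import AGE_LEVELS, REGION_LEVELS, SEX_LEVELS, SURGERY_LEVELS

__all__ = [
    "DesignSpec",
    "ModelFit",
    "ConvergenceWarning",
    "DegenerateResponseError",
    "RankDeficiencyError",
    "build_design",
    "fit_probit",
    "fit_logistic",
    "fit_ols",
]

#: canonical categorical levels, reference level first
DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "age_group": AGE_LEVELS,
    "region": REGION_LEVELS,
    "surgery_type": SURGERY_LEVELS,
}


class RankDeficiencyError(ValueError):
    """Design matrix is not of full column rank; names the offending columns."""


class DegenerateResponseError(ValueError):
    """Binary response has no variation, so the likelihood carries no information."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Model formula: a response column plus an ordered list of covariate terms.

    Categorical terms are expanded to treatment-coded dummies named
    ``term[level]`` against the first level in ``categories`` (defaults:
    age group 18-59, region north, surgery neurosurgery, sex male).
    """

    response: str
    terms: Sequence[str]
    categories: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES)
    )

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            dupes = [t for t in self.terms if list(self.terms).count(t) > 1]
            raise ValueError(f"duplicate terms in DesignSpec: {sorted(set(dupes))}")


@dataclass
class ModelFit:
    """A fitted model: coefficients, covariance and fit diagnostics."""

    family: str
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    converged: bool
    residuals: np.ndarray | None = None  # ols only
    sigma2: float | None = None  # ols residual variance (MLE denominator n-p)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with 95% Wald interval and p-value (logit family)."""
        if self.family != "logit":
            raise ValueError("odds ratios are defined for logistic fits")
        se = self.bse
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "or_low": np.exp(self.params - 1.959963984540054 * se),
                "or_high": np.exp(self.params + 1.959963984540054 * se),
                "p_value": p,
            },
            index=self.params.index,
        )

    def summary_text(self) -> str:
        lines = [f"family: {self.family}  n: {self.n}  llf: {self.llf:.6f}  "
                 f"converged: {self.converged}"]
        se = self.bse
        for name in self.params.index:
            row = f"{name:<42s} {self.params[name]: .6f}  (se {se[name]:.6f})"
            if self.family == "logit":
                row += f"  OR {np.exp(self.params[name]):.4f}"
            lines.append(row)
        return "\n".join(lines)


def build_design(
    df: pd.DataFrame, spec: DesignSpec, add_intercept: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Expand a DesignSpec into (X, y) with deterministic column order."""
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(df))
    for term in spec.terms:
        if term in spec.categories:
            levels = list(spec.categories[term])
            observed = set(df[term].astype(str))
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} in column {term!r}")
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (df[term].astype(str) == level).to_numpy(float)
        else:
            cols[term] = pd.to_numeric(df[term]).to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    y = pd.to_numeric(df[spec.response]).astype(float)
    return X, y


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify the dependent columns via pivoted QR
        from scipy.linalg import qr as scipy_qr

        _, R, piv = scipy_qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= r or diag[i] <= tol]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear column(s): {sorted(set(bad))}"
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _newton_binary(
    X, y, family: str, max_iter: int = 100, tol_score: float = 1e-8, tol_ll: float = 1e-10
) -> ModelFit:
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, float).ravel()
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    if yv.min() == yv.max():
        raise DegenerateResponseError(
            f"degenerate response: y is constant ({yv[0]:.0f}) — no information to fit"
        )
    _check_rank(Xm, names)
    n, p = Xm.shape
    beta = np.zeros(p)

    def loglik_parts(b):
        eta = Xm @ b
        if family == "probit":
            logF = special.log_ndtr(eta)
            logS = special.log_ndtr(-eta)
            ll = float(yv @ logF + (1 - yv) @ logS)
            # generalized residual g = dll/deta; -d2ll/deta2 = g^2 + g*eta
            logpdf = stats.norm.logpdf(eta)
            g = yv * np.exp(logpdf - logF) - (1 - yv) * np.exp(logpdf - logS)
            w = g * g + g * eta
        else:  # logit
            ll = float(yv @ eta - np.logaddexp(0.0, eta).sum())
            mu = special.expit(eta)
            g = yv - mu
            w = mu * (1 - mu)
        return ll, g, w

    ll, g, w = loglik_parts(beta)
    converged = False
    for _ in range(max_iter):
        score = Xm.T @ g
        info = Xm.T @ (Xm * w[:, None])
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving: the log-likelihood never decreases across iterations
        new_ll = -np.inf
        for _half in range(40):
            cand = beta + step
            new_ll, new_g, new_w = loglik_parts(cand)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        if not np.isfinite(new_ll):
            break
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll, g, w = cand, new_ll, new_g, new_w
        if rel < tol_ll:
            score = Xm.T @ g
            converged = bool(np.max(np.abs(score)) < max(tol_score, 1e-6))
            break
    # a (near-)perfect fit means the MLE is at infinity: flag separation
    if converged and ll > -1e-3:
        converged = False
    if not converged:
        warnings.warn(
            f"{family} fit did not converge (possible separation); "
            "coefficients reported as-is",
            ConvergenceWarning,
            stacklevel=3,
        )
    info = Xm.T @ (Xm * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return ModelFit(
        family=family,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=ll,
        n=n,
        converged=converged,
    )


def fit_probit(X, y, **kw) -> ModelFit:
    """Probit regression by Newton–Raphson; covariance is the inverse observed
    information at the optimum."""
    return _newton_binary(X, y, "probit", **kw)


def fit_logistic(X, y, **kw) -> ModelFit:
    """Logistic regression by Newton–Raphson; ``ModelFit.odds_ratios`` exposes
    exp(beta) with Wald intervals."""
    return _newton_binary(X, y, "logit", **kw)


def fit_ols(X, z) -> ModelFit:
    """Least squares of z on X with classical covariance sigma2 * (X'X)^-1.

    Residuals are retained for the Duan smearing retransformation.
    """
    Xm, names = _as_matrix(X)
    zv = np.asarray(z, float).ravel()
    if not np.isfinite(zv).all():
        raise ValueError("response contains non-finite values")
    _check_rank(Xm, names)
    n, p = Xm.shape
    beta, _, _, _ = np.linalg.lstsq(Xm, zv, rcond=None)
    resid = zv - Xm @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    cov = sigma2 * xtx_inv
    llf = float(-0.5 * n * (np.log(2 * np.pi * max(resid @ resid, 1e-300) / n) + 1))
    return ModelFit(
        family="ols",
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=llf,
        n=n,
        converged=True,
        residuals=resid,
        sigma2=sigma2,
    )
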