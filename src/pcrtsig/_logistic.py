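"""Small dense logistic-regression engine for the combinatorial search.

The signature search fits tens of thousands of tiny logistic models
(n <= ~100 samples, <= ~15 covariates) during beam scoring and the repeated
two-fold cross-validation, so this module provides a minimal Newton/IRLS
solver on numpy arrays.  Reporting-grade fits (tables with standard errors,
the final model) go through statsmodels; the two are cross-checked in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

_MAX_ETA = 30.0  # |linear predictor| beyond this is numerically saturated


@dataclass
class LogitFit:
    coef: np.ndarray          # intercept first
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    separated: bool
    n_iter: int

    @property
    def lr_stat(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lr_p(self) -> float:
        df = len(self.coef) - 1
        if df == 0:
            return 1.0
        return float(chi2.sf(max(self.lr_stat, 0.0), df))

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.wald_z))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xd = np.column_stack([np.ones(len(X)), X])
        return expit(Xd @ self.coef)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogitFit:
    """Fit y ~ intercept + X by IRLS.

    ``ridge`` adds an L2 penalty on the non-intercept coefficients (used as a
    documented fallback under complete separation).  Separation is flagged
    when fitted linear predictors saturate; coefficients are then the last
    stable iterate, so Wald statistics stay finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = np.log(ybar / (1 - ybar))
    pen = np.zeros(p + 1)
    pen[1:] = ridge

    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        if np.max(np.abs(eta)) > _MAX_ETA * 3:
            separated = True
            break
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        # Newton step on the (possibly penalized) log-likelihood
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        g = Xd.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # dampen huge steps for stability
        snorm = np.max(np.abs(step))
        if snorm > 10.0:
            step *= 10.0 / snorm
        beta = beta + step
        if snorm < tol:
            converged = True
            break

    eta = np.clip(Xd @ beta, -_MAX_ETA, _MAX_ETA)
    if ridge == 0.0:
        raw = Xd @ beta
        if np.max(np.abs(raw)) > _MAX_ETA:
            separated = True
        elif not converged and np.all((raw > 0) == (y == 1)):
            # diverging fit that already classifies the data perfectly
            separated = True
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.inf)

    ll = _loglik(y, Xd @ beta) if not separated else _loglik(y, eta)
    # intercept-only log-likelihood has a closed form
    ll0 = _loglik(y, np.full(n, np.log(ybar / (1 - ybar))))
    return LogitFit(beta, se, ll, ll0, converged, separated, it)


def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney rank statistic; ties count one half.

    Equals the probability that a random positive's score exceeds a random
    negative's (plus half the tie probability).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class is empty")
    from scipy.stats import rankdata

    r = rankdata(scores)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
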