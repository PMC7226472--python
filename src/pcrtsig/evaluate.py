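"""Final signature model, cohort evaluation, and regression report tables.

The selected gene signature becomes one logistic model fitted on the
training cohort; its linear predictor defines both the probability cutoff
classifier (for confusion-matrix metrics on either cohort) and a low/high
dichotomy at the median training score (for the clinicopathological
association tables).  Reporting-grade fits go through statsmodels so the
coefficient, standard error, Wald z and odds-ratio columns match standard
glm output; quasi-separated covariates (huge coefficient, huge SE) are
reported as-is with a separation flag, the way they appear in clinical
logistic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._logistic import fit_logit
from .nanostring import CountMatrix

__all__ = [
    "FittedSignatureModel",
    "EvaluationReport",
    "fit_final_model",
    "evaluate",
    "univariate_table",
    "multivariate_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class FittedSignatureModel:
    """Logistic signature model fitted on the training cohort only."""

    genes: tuple[str, ...]
    params: np.ndarray            # intercept first, then one slope per gene
    score_threshold: float        # median training linear predictor
    prob_cutoff: float = 0.5
    ridge_fallback: bool = False  # set when separation forced a penalized fit

    def __post_init__(self) -> None:
        if len(self.params) != len(self.genes) + 1:
            raise ValueError("coefficient count must equal gene count + 1")

    def _expr(self, matrix: CountMatrix) -> np.ndarray:
        pos = {g: i for i, g in enumerate(matrix.gene_ids)}
        missing = [g for g in self.genes if g not in pos]
        if missing:
            raise KeyError(f"model genes absent from matrix: {missing}")
        return matrix.counts[[pos[g] for g in self.genes]].T

    def linear_predictor(self, matrix: CountMatrix) -> np.ndarray:
        X = self._expr(matrix)
        return self.params[0] + X @ self.params[1:]

    def predict_proba(self, matrix: CountMatrix) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(matrix))

    def predict(self, matrix: CountMatrix) -> np.ndarray:
        return self.predict_proba(matrix) >= self.prob_cutoff

    def dichotomize(self, matrix: CountMatrix) -> np.ndarray:
        """Low/high signature score relative to the training median (high = True)."""
        return self.linear_predictor(matrix) > self.score_threshold


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix and derived classification metrics.

    Metrics with an empty denominator are None (undefined), never NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


def fit_final_model(
    genes: Sequence[str],
    matrix: CountMatrix,
    labels,
    *,
    ridge_on_separation: float = 1.0,
) -> FittedSignatureModel:
    """Fit the signature's logistic model on the training cohort.

    Uses the statsmodels Newton optimizer; under complete separation (or
    non-convergence) the fit is redone with a small L2 ridge penalty and the
    model is flagged ``ridge_fallback``.
    """
    genes = tuple(genes)
    y = np.array([float(labels[s]) for s in matrix.sample_ids])
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    X = matrix.counts[[pos[g] for g in genes]].T
    Xd = sm.add_constant(X, has_constant="add")

    params = None
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(
                np.abs(res.params) < 1e3
            ):
                params = np.asarray(res.params)
        except Exception:
            params = None
    if params is None:
        fit = fit_logit(X, y, ridge=ridge_on_separation)
        params = fit.coef
        ridge = True

    lp = params[0] + X @ params[1:]
    return FittedSignatureModel(
        genes, params, score_threshold=float(np.median(lp)), ridge_fallback=ridge
    )


def evaluate(model: FittedSignatureModel, matrix: CountMatrix, labels) -> EvaluationReport:
    """Confusion-matrix evaluation of the model on a cohort."""
    y = np.array([bool(labels[s]) for s in matrix.sample_ids])
    pred = model.predict(matrix)
    return EvaluationReport(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


_SEPARATION_SE = 50.0  # |coef| or SE beyond any plausible clinical odds ratio


def _fit_rows(X: pd.DataFrame, y: np.ndarray, variables: Sequence[str]) -> pd.DataFrame:
    """One joint statsmodels logistic fit -> tidy rows for the given variables."""
    Xd = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        # IRLS (like R's glm) stops with huge but finite estimates under
        # quasi-separation instead of failing, which is what clinical tables print
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    rows = []
    for j, name in enumerate(variables, start=1):
        coef = float(res.params[j])
        se = float(res.bse[j])
        z = coef / se if se > 0 else np.nan
        p = float(res.pvalues[j])
        with np.errstate(over="ignore"):  # CI bound may overflow to inf under separation
            odds_ratio = float(np.exp(coef))
            ci_low = float(np.exp(coef - Z_95 * se))
            ci_high = float(np.exp(coef + Z_95 * se))
        rows.append(
            {
                "variable": name,
                "n_used": int(len(y)),
                "coef": coef,
                "se": se,
                "z": z,
                "p": p,
                "odds_ratio": odds_ratio,
                "ci95_low": ci_low,
                "ci95_high": ci_high,
                "separation_flag": bool(se > _SEPARATION_SE or abs(coef) > _SEPARATION_SE),
            }
        )
    return pd.DataFrame(rows)


def univariate_table(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One single-covariate logistic fit per feature column.

    ``features`` columns must already be numerically encoded contrasts
    (e.g. 0/1 for binary stage groupings); rows with missing values are
    dropped per feature, reflected in ``n_used``.
    """
    out = []
    y_all = labels.astype(float)
    for name in features.columns:
        col = features[name]
        mask = col.notna() & y_all.notna()
        rows = _fit_rows(col[mask].to_frame(), y_all[mask].to_numpy(), [name])
        rows["n_used"] = int(mask.sum())
        out.append(rows)
    return pd.concat(out, ignore_index=True)


def multivariate_table(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One joint logistic fit over all feature columns, with OR and 95% CI.

    Raises on rank deficiency, naming the collinear columns.
    """
    mask = features.notna().all(axis=1) & labels.notna()
    X = features[mask].astype(float)
    y = labels[mask].astype(float).to_numpy()
    M = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # pinpoint columns whose removal restores full rank
        bad = [
            c for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(M, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear variables: {bad}")
    return _fit_rows(X, y, list(X.columns))
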