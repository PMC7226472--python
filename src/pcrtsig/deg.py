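"""Differential-expression screen and univariate logistic shortlist.

Stage 1: a classical pooled-variance Student's t-test per endogenous gene on
log2-normalized expression, with a geometric-mean fold-change filter
(pass = p < 0.05 and |FC| > 1.5).  Stage 2: per passing gene, a univariate
logistic regression of response on expression; genes with Wald p < 0.05 are
shortlisted.  No multiple-testing correction is applied at either stage —
the screen is deliberately permissive and the downstream combinatorial
search plus cross-validation carries the selection burden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import fit_logit
from .nanostring import CountMatrix

__all__ = ["t_test_fc", "univariate_logistic_filter", "signed_fold_change", "shortlist"]

P_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


def signed_fold_change(log2_diff: np.ndarray) -> np.ndarray:
    """Linear fold change with the signed convention |FC| >= 1.

    ``log2_diff`` is mean(log2 responders) - mean(log2 non-responders); a
    ratio below 1 is reported as its negative reciprocal, so a halving is
    -2, not 0.5.
    """
    fc = 2.0 ** np.asarray(log2_diff, dtype=float)
    return np.where(fc >= 1.0, fc, -1.0 / fc)


def t_test_fc(
    matrix: CountMatrix,
    labels: dict[str, bool] | pd.Series,
    *,
    equal_var: bool = True,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene two-sided t-test and fold change on log2 expression.

    ``matrix`` must already be on the log2 scale; only endogenous genes are
    tested.  ``equal_var=True`` gives the classical pooled-variance Student
    test (Welch via ``equal_var=False``).  Genes where both classes are
    constant and equal get t = 0, p = 1, FC = 1 rather than NaN.

    Returns a DEG table indexed by gene with columns ``mean_responder``,
    ``mean_nonresponder``, ``fold_change``, ``t_stat``, ``p_t``,
    ``direction`` and ``passed_deg``.
    """
    endo = matrix.endogenous()
    y = np.array([bool(labels[s]) for s in endo.sample_ids])
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")

    a = endo.counts[:, y]       # responders
    b = endo.counts[:, ~y]      # non-responders
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    diff = mean_a - mean_b

    # both classes constant: equal means -> no evidence; unequal -> certain
    degenerate = np.isnan(t_stat)
    if degenerate.any():
        eq = degenerate & np.isclose(diff, 0.0)
        ne = degenerate & ~np.isclose(diff, 0.0)
        t_stat = np.where(eq, 0.0, t_stat)
        p = np.where(eq, 1.0, p)
        t_stat = np.where(ne, np.sign(diff) * np.inf, t_stat)
        p = np.where(ne, 0.0, p)

    fc = signed_fold_change(diff)
    fc = np.where(np.isclose(diff, 0.0), 1.0, fc)
    table = pd.DataFrame(
        {
            "mean_responder": mean_a,
            "mean_nonresponder": mean_b,
            "fold_change": fc,
            "t_stat": t_stat,
            "p_t": p,
            "direction": np.where(diff >= 0, "up_in_responders", "up_in_nonresponders"),
        },
        index=pd.Index(endo.gene_ids, name="gene"),
    )
    table["passed_deg"] = (table["p_t"] < p_threshold) & (table["fold_change"].abs() > fc_threshold)
    return table


def univariate_logistic_filter(
    matrix: CountMatrix,
    labels: dict[str, bool] | pd.Series,
    degs: pd.DataFrame,
    *,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Univariate logistic shortlist over the genes that passed the DEG screen.

    Fits response ~ intercept + expression per gene and records the Wald p.
    Under complete separation the Wald statistic is taken at the last stable
    iterate (largest finite statistic) and the gene is flagged and retained.

    Returns ``degs`` with added columns ``p_univariate_logistic``,
    ``separated`` and ``passed_univariate``.
    """
    endo = matrix.endogenous()
    y = np.array([bool(labels[s]) for s in endo.sample_ids], dtype=float)
    expr = pd.DataFrame(endo.counts, index=endo.gene_ids, columns=endo.sample_ids)

    out = degs.copy()
    out["p_univariate_logistic"] = np.nan
    out["separated"] = False
    for gene in out.index[out["passed_deg"]]:
        fit = fit_logit(expr.loc[gene].to_numpy()[:, None], y)
        p_wald = float(fit.wald_p[1])
        out.loc[gene, "p_univariate_logistic"] = p_wald
        out.loc[gene, "separated"] = fit.separated
    out["passed_univariate"] = out["passed_deg"] & (
        (out["p_univariate_logistic"] < p_threshold) | out["separated"]
    )
    return out


def shortlist(degs: pd.DataFrame) -> list[str]:
    """Gene ids passing both stages, in stable sorted order."""
    return sorted(degs.index[degs["passed_univariate"]])
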