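"""Combinatorial gene-signature search with repeated 2-fold cross-validation.

The shortlisted genes span 2^n - 1 possible non-empty signatures.  Each
candidate is a multivariable logistic model of response on its member genes;
candidates are retained when the model is jointly significant (likelihood-
ratio p < 0.05) with AUC, sensitivity and specificity all above threshold,
then ranked by mean accuracy over repeated stratified random half-splits of
the training cohort.  Exhaustive enumeration is exact for small n; for
realistic shortlists (n around 40, 2^42 - 1 combinations) a deterministic
forward beam search over AUC explores the space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._logistic import auc_rank, fit_logit
from .nanostring import CountMatrix

__all__ = [
    "CombinationSpec",
    "CVConfig",
    "SignatureCandidate",
    "count_combinations",
    "enumerate_candidates",
    "score_candidate",
    "cross_validate",
    "rank_and_select",
    "run_search",
]

AUC_THRESHOLD = 0.8   # the candidate-filter AUC bound
SENS_THRESHOLD = 0.75
SPEC_THRESHOLD = 0.75


def count_combinations(n: int) -> int:
    """Total number of non-empty gene subsets of an n-gene shortlist.

    sum_{k=1..n} C(n, k) = 2^n - 1, in exact integer arithmetic.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return 2**n - 1


@dataclass(frozen=True)
class CombinationSpec:
    """How the subset space is enumerated."""

    k_range: tuple[int, int]
    strategy: str = "exhaustive"  # or "forward_beam"
    beam_width: int = 10
    budget: int = 200_000  # refuse exhaustive enumeration beyond this

    def __post_init__(self) -> None:
        k_min, k_max = self.k_range
        if not 1 <= k_min <= k_max:
            raise ValueError(f"invalid k_range {self.k_range}")
        if self.strategy not in ("exhaustive", "forward_beam"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified 2-fold resampling parameters."""

    n_folds: int = 2
    repetitions: int = 300
    stratified: bool = True
    seed: int = 0
    require_significant: bool = True  # training-half LR p < 0.05 to contribute

    def __post_init__(self) -> None:
        if self.n_folds != 2:
            raise ValueError("only 2-fold resampling is supported")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class SignatureCandidate:
    """A gene subset with its fitted-model metrics and CV ranking score."""

    genes: tuple[str, ...]
    model_p: float
    auc: float
    sensitivity: float
    specificity: float
    retained: bool
    cv_accuracy: float = math.nan
    cv_reps: int = 0
    rank: int | None = None
    note: str = ""


def _expr_matrix(matrix: CountMatrix, genes: Sequence[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    return matrix.counts[[pos[g] for g in genes]].T  # samples x genes


def _labels_vector(matrix: CountMatrix, labels) -> np.ndarray:
    return np.array([bool(labels[s]) for s in matrix.sample_ids])


def enumerate_candidates(
    shortlist: Sequence[str], spec: CombinationSpec,
    matrix: CountMatrix | None = None, labels=None,
) -> Iterator[tuple[str, ...]]:
    """Yield gene subsets according to the enumeration strategy.

    Exhaustive: every subset with size in ``k_range`` in lexicographic order
    (order of the shortlist as given); refused when the subset count exceeds
    ``spec.budget``.  Forward beam: greedy growth of the ``beam_width`` best
    subsets by training AUC, requiring ``matrix`` and ``labels``; all beam
    members of every size in range are emitted, deterministically
    (ties broken by gene ids).
    """
    genes = list(shortlist)
    k_min, k_max = spec.k_range
    k_max = min(k_max, len(genes))
    if spec.strategy == "exhaustive":
        total = sum(math.comb(len(genes), k) for k in range(k_min, k_max + 1))
        if total > spec.budget:
            raise ValueError(
                f"exhaustive enumeration of {total} subsets exceeds the budget "
                f"of {spec.budget}; use strategy='forward_beam' or raise the budget"
            )
        for k in range(k_min, k_max + 1):
            yield from itertools.combinations(genes, k)
        return

    if matrix is None or labels is None:
        raise ValueError("forward_beam requires matrix and labels")
    y = _labels_vector(matrix, labels)
    expr = _expr_matrix(matrix, genes)
    cols = {g: expr[:, i] for i, g in enumerate(genes)}

    def beam_key(subset: tuple[str, ...]) -> tuple[float, float, tuple[str, ...]]:
        # primary: AUC; AUC ties (common once the model separates the classes
        # in-sample) break on training log-likelihood, then gene ids
        X = np.column_stack([cols[g] for g in subset])
        fit = fit_logit(X, y.astype(float))
        return (-auc_rank(fit.predict(X), y), -fit.loglik, subset)

    beam: list[tuple[str, ...]] = [(g,) for g in genes]
    beam = [s for *_, s in sorted(beam_key(s) for s in beam)[: spec.beam_width]]
    if k_min <= 1 <= k_max:
        yield from beam
    for k in range(2, k_max + 1):
        seen: set[tuple[str, ...]] = set()
        expanded: list[tuple[float, float, tuple[str, ...]]] = []
        for subset in beam:
            for g in genes:
                if g in subset:
                    continue
                cand = tuple(sorted(set(subset) | {g}))
                if cand in seen:
                    continue
                seen.add(cand)
                expanded.append(beam_key(cand))
        if not expanded:
            return
        expanded.sort()
        beam = [s for *_, s in expanded[: spec.beam_width]]
        if k >= k_min:
            yield from beam


def score_candidate(
    genes: Sequence[str],
    matrix: CountMatrix,
    labels,
    *,
    auc_threshold: float = AUC_THRESHOLD,
    sens_threshold: float = SENS_THRESHOLD,
    spec_threshold: float = SPEC_THRESHOLD,
    p_threshold: float = 0.05,
) -> SignatureCandidate:
    """Fit the candidate's multivariable logistic model and apply the filter.

    AUC is the rank statistic over fitted probabilities; sensitivity and
    specificity are read off the confusion matrix at probability cutoff 0.5;
    model significance is the likelihood-ratio test against intercept-only.
    """
    genes = tuple(genes)
    if len(genes) < 1:
        raise ValueError("candidate must contain at least one gene")
    y = _labels_vector(matrix, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    X = _expr_matrix(matrix, genes)
    fit = fit_logit(X, y.astype(float))
    if not (fit.converged or fit.separated):
        return SignatureCandidate(genes, math.nan, math.nan, math.nan, math.nan,
                                  retained=False, note="non-convergent fit, discarded")
    prob = fit.predict(X)
    auc = auc_rank(prob, y)
    pred = prob >= 0.5
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    model_p = fit.lr_p
    retained = (
        model_p < p_threshold and auc > auc_threshold
        and sens > sens_threshold and spec > spec_threshold
    )
    note = "separated" if fit.separated else ""
    return SignatureCandidate(genes, model_p, auc, sens, spec, retained, note=note)


def cross_validate(
    genes: Sequence[str],
    matrix: CountMatrix,
    labels,
    cv: CVConfig,
) -> tuple[float, int]:
    """Mean test-half accuracy over repeated random 2-fold splits.

    Each repetition draws a stratified random half-split, fits the logistic
    model on one half and scores accuracy on the other at probability cutoff
    0.5.  When ``require_significant`` is set, a repetition contributes to
    the mean only if the training-half model is significant (LR p < 0.05);
    non-contributing repetitions are still counted in the returned total.
    Deterministic given ``cv.seed``.

    Returns ``(cv_accuracy, contributing_repetitions)``; the accuracy is NaN
    when no repetition contributes.
    """
    y = _labels_vector(matrix, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    X = _expr_matrix(matrix, tuple(genes))
    rng = np.random.default_rng(cv.seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    all_idx = np.arange(len(y))

    accs: list[float] = []
    for _ in range(cv.repetitions):
        for _attempt in range(100):
            if cv.stratified:
                p = rng.permutation(pos_idx)
                q = rng.permutation(neg_idx)
                train = np.concatenate([p[: len(p) // 2], q[: len(q) // 2]])
            else:
                perm = rng.permutation(all_idx)
                train = perm[: len(perm) // 2]
            test = np.setdiff1d(all_idx, train)
            if y[train].sum() and (~y[train]).sum() and len(test):
                break
        else:  # pragma: no cover - unreachable with class sizes >= 2
            raise RuntimeError("could not draw a split containing both classes")
        fit = fit_logit(X[train], y[train].astype(float))
        if cv.require_significant and fit.lr_p >= 0.05:
            continue
        pred = fit.predict(X[test]) >= 0.5
        accs.append(float(np.mean(pred == y[test])))
    return (float(np.mean(accs)) if accs else math.nan, len(accs))


def rank_and_select(candidates: Sequence[SignatureCandidate]) -> SignatureCandidate | None:
    """Rank retained, cross-validated candidates and return the best.

    Sort key: CV accuracy descending, then fewer genes, then lexicographic
    gene ids.  Returns None when no candidate was retained ("no signature
    found").
    """
    pool = [c for c in candidates if c.retained and not math.isnan(c.cv_accuracy)]
    if not pool:
        return None
    pool.sort(key=lambda c: (-c.cv_accuracy, len(c.genes), c.genes))
    for i, c in enumerate(pool, start=1):
        c.rank = i
    return pool[0]


def run_search(
    matrix: CountMatrix,
    labels,
    shortlist: Sequence[str],
    *,
    spec: CombinationSpec | None = None,
    cv: CVConfig | None = None,
    max_cv_candidates: int = 60,
    auc_threshold: float = AUC_THRESHOLD,
) -> list[SignatureCandidate]:
    """Full stage-3 search: enumerate, score, filter, cross-validate.

    The default enumeration is exhaustive over subset sizes 1-3 plus a
    forward beam search up to 12 genes — exact where exactness is affordable
    and greedy beyond.  To bound runtime, only the ``max_cv_candidates``
    retained candidates with the highest AUC enter cross-validation.
    """
    shortlist = sorted(shortlist)
    cv = cv or CVConfig()
    if spec is None:
        specs = [
            CombinationSpec(k_range=(1, min(3, len(shortlist)))),
            CombinationSpec(k_range=(2, min(12, len(shortlist))),
                            strategy="forward_beam"),
        ]
    else:
        specs = [spec]

    seen: set[tuple[str, ...]] = set()
    candidates: list[SignatureCandidate] = []
    for sp in specs:
        for subset in enumerate_candidates(shortlist, sp, matrix, labels):
            key = tuple(sorted(subset))
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                score_candidate(key, matrix, labels, auc_threshold=auc_threshold)
            )

    # cross-validate the best candidates of every subset size, so large
    # signatures compete with small ones even when in-sample AUC saturates
    retained = [c for c in candidates if c.retained]
    by_size: dict[int, list[SignatureCandidate]] = {}
    for c in retained:
        by_size.setdefault(len(c.genes), []).append(c)
    quota = max(1, max_cv_candidates // max(len(by_size), 1))
    pool: list[SignatureCandidate] = []
    for size in sorted(by_size):
        group = sorted(by_size[size], key=lambda c: (-c.auc, c.model_p, c.genes))
        pool.extend(group[:quota])
    for c in pool[:max_cv_candidates]:
        c.cv_accuracy, c.cv_reps = cross_validate(c.genes, matrix, labels, cv)
    return candidates


def candidates_frame(candidates: Sequence[SignatureCandidate]) -> pd.DataFrame:
    """Candidate table for TSV export."""
    return pd.DataFrame(
        {
            "genes": ["|".join(c.genes) for c in candidates],
            "n_genes": [len(c.genes) for c in candidates],
            "model_p": [c.model_p for c in candidates],
            "auc": [c.auc for c in candidates],
            "sensitivity": [c.sensitivity for c in candidates],
            "specificity": [c.specificity for c in candidates],
            "retained": [c.retained for c in candidates],
            "cv_accuracy": [c.cv_accuracy for c in candidates],
            "cv_reps": [c.cv_reps for c in candidates],
            "note": [c.note for c in candidates],
        }
    )
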