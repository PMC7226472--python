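"""Combinatorial search: counting, enumeration, scoring, cross-validation."""

import itertools
import math

import numpy as np
import pytest

from pcrtsig._logistic import auc_rank, fit_logit
from pcrtsig.search import (
    CombinationSpec,
    CVConfig,
    SignatureCandidate,
    count_combinations,
    cross_validate,
    enumerate_candidates,
    rank_and_select,
    score_candidate,
)
from conftest import make_matrix


def brute_force_auc(scores, y):
    """Concordant-pair counting oracle for the ROC AUC."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


def gene_data(n_genes, n_samples, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    y = np.array([True] * (n_samples // 2) + [False] * (n_samples - n_samples // 2))
    data = rng.normal(6, 1, size=(n_genes, n_samples))
    if effect is not None:
        for g, e in effect.items():
            data[g, y] += e
    m = make_matrix(data)
    labels = {s: bool(v) for s, v in zip(m.sample_ids, y)}
    return m, labels, y


@pytest.mark.parametrize("n,expected", [(0, 0), (1, 1), (2, 3), (9, 511)])
def test_count_combinations_small(n, expected):
    assert count_combinations(n) == expected


def test_count_combinations_equals_binomial_sum_up_to_64():
    for n in range(0, 65):
        assert count_combinations(n) == sum(math.comb(n, k) for k in range(1, n + 1))
    with pytest.raises(ValueError):
        count_combinations(-1)


def test_exhaustive_enumeration_counts_and_order():
    subsets = list(enumerate_candidates(["a", "b", "c"], CombinationSpec(k_range=(1, 3))))
    assert len(subsets) == 7
    assert subsets[:3] == [("a",), ("b",), ("c",)]
    pairs = list(enumerate_candidates(list("abcd"), CombinationSpec(k_range=(2, 2))))
    assert pairs == list(itertools.combinations("abcd", 2))


def test_exhaustive_refuses_over_budget():
    genes = [f"g{i}" for i in range(30)]
    with pytest.raises(ValueError, match="budget"):
        list(enumerate_candidates(genes, CombinationSpec(k_range=(1, 30), budget=1000)))


def test_greedy_beam_keeps_dominant_gene():
    m, labels, _ = gene_data(6, 40, seed=4, effect={0: 4.0})
    spec = CombinationSpec(k_range=(1, 4), strategy="forward_beam", beam_width=1)
    subsets = list(enumerate_candidates(m.gene_ids, spec, m, labels))
    assert subsets, "beam emitted nothing"
    dominant = m.gene_ids[0]
    assert all(dominant in s for s in subsets)


def test_score_candidate_perfect_separation():
    m, labels, _ = gene_data(2, 30, seed=5, effect={0: 50.0})
    cand = score_candidate([m.gene_ids[0]], m, labels)
    assert cand.auc == pytest.approx(1.0)
    assert cand.sensitivity == pytest.approx(1.0)
    assert cand.specificity == pytest.approx(1.0)
    assert cand.retained


def test_score_candidate_null_auc_near_half():
    aucs = []
    for seed in range(8):
        m, labels, _ = gene_data(1, 200, seed=seed)
        aucs.append(score_candidate([m.gene_ids[0]], m, labels).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def test_auc_matches_brute_force_pairs():
    rng = np.random.default_rng(6)
    for _ in range(30):
        n = rng.integers(6, 50)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            continue
        assert auc_rank(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)


def test_cross_validate_bit_reproducible():
    m, labels, _ = gene_data(4, 60, seed=7, effect={0: 1.0, 1: 1.0})
    cv = CVConfig(repetitions=50, seed=123)
    a1 = cross_validate(m.gene_ids[:2], m, labels, cv)
    a2 = cross_validate(m.gene_ids[:2], m, labels, cv)
    assert a1 == a2
    a3 = cross_validate(m.gene_ids[:2], m, labels, CVConfig(repetitions=50, seed=124))
    assert a1 != a3  # different seed, different splits


def test_cross_validate_strong_signal_high_accuracy():
    m, labels, _ = gene_data(3, 60, seed=8, effect={0: 2.5, 1: 2.5})
    acc, n = cross_validate(m.gene_ids[:2], m, labels, CVConfig(repetitions=100, seed=0))
    assert n == 100
    assert acc > 0.9


def test_cross_validate_noise_near_majority_baseline():
    m, labels, y = gene_data(2, 80, seed=9)
    acc, _ = cross_validate(
        m.gene_ids, m, labels,
        CVConfig(repetitions=200, seed=1, require_significant=False),
    )
    baseline = max(np.mean(y), 1 - np.mean(y))
    assert acc == pytest.approx(baseline, abs=0.12)


def make_candidate(genes, cv_acc):
    c = SignatureCandidate(tuple(genes), 0.01, 0.9, 0.8, 0.8, retained=True)
    c.cv_accuracy = cv_acc
    c.cv_reps = 300
    return c


def test_rank_and_select_orders_and_tiebreaks():
    best = rank_and_select([make_candidate("abc", 0.8), make_candidate("de", 0.9)])
    assert best.genes == ("d", "e")
    tie = rank_and_select(
        [make_candidate("abcde", 0.85), make_candidate("xyz", 0.85)]
    )
    assert tie.genes == ("x", "y", "z")  # fewer genes wins the tie
    assert rank_and_select([]) is None


def test_irls_matches_statsmodels():
    """The fast IRLS engine agrees with statsmodels on a well-posed fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(10)
    X = rng.normal(size=(80, 3))
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.2])
    y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
    ours = fit_logit(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.se, ref.bse, atol=1e-5)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)
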