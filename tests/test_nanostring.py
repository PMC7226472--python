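"""Count I/O and nCounter-style normalization."""

import numpy as np
import pytest

from pcrtsig.nanostring import (
    CountMatrix,
    log2_counts,
    normalize,
    read_counts,
    write_counts,
    write_rcc_dir,
)
from conftest import make_matrix


def control_matrix(n_samples=4, scale=None, seed=0, vary=False):
    """Small matrix with all four gene classes.

    By default every sample is the same per-gene profile times its ``scale``
    factor (pure library-size structure); ``vary=True`` adds independent
    per-sample variation instead.
    """
    rng = np.random.default_rng(seed)
    scale = np.ones(n_samples) if scale is None else np.asarray(scale, float)
    reps = n_samples if vary else 1
    endo = np.tile(rng.integers(50, 500, size=(5, reps)), (1, n_samples))[:, :n_samples]
    hk = np.tile(rng.integers(200, 800, size=(3, reps)), (1, n_samples))[:, :n_samples]
    pos = np.outer([1000.0, 250.0, 60.0], np.ones(n_samples))
    neg = np.full((2, n_samples), 3.0)
    counts = np.vstack([endo.astype(float), hk.astype(float), pos, neg]) * scale
    return make_matrix(
        counts,
        gene_ids=[f"E{i}" for i in range(5)] + [f"H{i}" for i in range(3)]
        + [f"P{i}" for i in range(3)] + [f"N{i}" for i in range(2)],
        classes=["endogenous"] * 5 + ["housekeeping"] * 3
        + ["positive"] * 3 + ["negative"] * 2,
    )


def test_tsv_round_trip(tmp_path):
    m = make_matrix([[1, 2], [3, 4], [5, 6]])
    path = tmp_path / "c.tsv"
    write_counts(m, path)
    back = read_counts(path)
    assert back.gene_ids == m.gene_ids
    assert back.sample_ids == m.sample_ids
    np.testing.assert_array_equal(back.counts, m.counts)


def test_rcc_round_trip(tmp_path):
    m = control_matrix()
    write_rcc_dir(m, tmp_path / "rcc")
    back = read_counts(tmp_path / "rcc", format="rcc_dir")
    assert sorted(back.sample_ids) == sorted(m.sample_ids)
    assert back.gene_ids == m.gene_ids
    np.testing.assert_allclose(
        back.subset_samples(m.sample_ids).counts, m.counts
    )


def test_rcc_inconsistent_gene_list_names_sample(tmp_path):
    m = control_matrix(n_samples=2)
    write_rcc_dir(m, tmp_path / "rcc")
    bad = tmp_path / "rcc" / "S1.RCC"
    text = bad.read_text().replace("Endogenous,E0,", "Endogenous,WRONG,")
    bad.write_text(text)
    with pytest.raises(ValueError, match="S1"):
        read_counts(tmp_path / "rcc", format="rcc_dir")


def test_duplicate_gene_id_rejected():
    with pytest.raises(ValueError, match="duplicate gene ids"):
        make_matrix([[1], [2]], gene_ids=["A", "A"])


def test_negative_counts_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        make_matrix([[-1.0]])


def test_identical_samples_all_factors_one():
    m = control_matrix(n_samples=3, scale=[1, 1, 1])
    normed, rep = normalize(m)
    for f in rep.positive_factor.values():
        assert f == pytest.approx(1.0)
    for f in rep.housekeeping_factor.values():
        assert f == pytest.approx(1.0)
    # output equals input after the background floor
    bg = next(iter(rep.background_threshold.values()))
    np.testing.assert_allclose(normed.counts, np.maximum(m.counts - bg, 0.0))


def test_uniformly_doubled_sample_gets_half_the_combined_factor():
    """Under a pure scale change, relative combined factors invert the scale."""
    m = control_matrix(n_samples=3, scale=[1.0, 1.0, 2.0])
    _, rep = normalize(m)
    combined = {
        s: rep.positive_factor[s] * rep.housekeeping_factor[s]
        for s in m.sample_ids
    }
    assert combined["S2"] / combined["S0"] == pytest.approx(0.5, abs=1e-9)


def test_zero_negative_controls_give_zero_background():
    m = control_matrix()
    neg_rows = [i for i, c in enumerate(m.gene_class) if c == "negative"]
    m.counts[neg_rows] = 0.0
    _, rep = normalize(m)
    assert all(v == 0.0 for v in rep.background_threshold.values())


def test_normalization_idempotent_under_library_size_variation():
    """Re-normalizing a normalized matrix yields factors within 1e-6 of one."""
    m = control_matrix(n_samples=5, scale=[0.6, 1.0, 1.4, 2.0, 0.9])
    normed, _ = normalize(m, background_subtraction=False)
    _, rep2 = normalize(normed, background_subtraction=False)
    for f in rep2.positive_factor.values():
        assert f == pytest.approx(1.0, abs=1e-6)
    for f in rep2.housekeeping_factor.values():
        assert f == pytest.approx(1.0, abs=1e-6)


def test_sample_permutation_equivariance():
    m = control_matrix(n_samples=4, scale=[1.0, 0.5, 2.0, 1.2], seed=3, vary=True)
    normed, _ = normalize(m)
    perm = ["S2", "S0", "S3", "S1"]
    normed_perm, _ = normalize(m.subset_samples(perm))
    np.testing.assert_allclose(
        normed_perm.counts, normed.subset_samples(perm).counts, rtol=1e-12
    )


def test_zero_positive_control_flags_and_excludes_sample():
    m = control_matrix(n_samples=3)
    pos_rows = [i for i, c in enumerate(m.gene_class) if c == "positive"]
    m.counts[pos_rows[0], 1] = 0.0  # kills the geometric mean of sample S1
    normed, rep = normalize(m)
    assert ("S1", "positive-control geometric mean is zero") in rep.flagged_samples
    assert normed.sample_ids == ["S0", "S2"]


def test_log2_transform():
    m = make_matrix([[0.0, 3.0], [7.0, 15.0]])
    out = log2_counts(m)
    np.testing.assert_allclose(out.counts, [[0.0, 2.0], [3.0, 4.0]])
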