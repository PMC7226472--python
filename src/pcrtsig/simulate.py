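"""Synthetic two-cohort NanoString-style count data with a planted signature.

The generator emulates the data structure the discovery pipeline assumes: a
730-endogenous-gene panel plus control genes (positive titration, negative
background, housekeeping), a training cohort (n = 60) and a validation cohort
(n = 96), responder/non-responder labels derived from tumor regression grade,
and a small set of truly predictive genes whose class means differ by a
specified log2 fold-change.  Counts are negative-binomial on the count scale
with log-normal per-sample library-size factors; everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohorts import SampleAnnotation
from .nanostring import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "TABLE1_POOLED_FREQUENCIES",
    "generate_cohort",
    "generate_table1_covariates",
]

#: Default planted signature: nine gene symbols from the interleukin / FGF /
#: Wnt / MAPK signalling space that the panel covers.
DEFAULT_SIGNATURE = (
    "FGFR3", "GNA11", "H3F3A", "IL12A", "IL1R1", "IL2RB", "NKD1", "SGK2", "SPRY2",
)

#: Pooled (both cohorts) marginal category counts of the clinicopathological
#: covariates; categories with zero pooled count keep weight 0 so the closed
#: vocabularies stay complete.
TABLE1_POOLED_FREQUENCIES: dict[str, dict[str, int]] = {
    "gender": {"male": 80, "female": 76},
    "differentiation": {"well": 27, "moderate": 127, "poor": 2},
    "clin_T": {"T1": 0, "T2": 13, "T3": 131, "T4": 7},
    "clin_N": {"N0": 12, "N1": 64, "N2": 80},
    "clin_M": {"M0": 152, "M1": 4},
    "path_T": {"Tis": 3, "T0": 25, "T1": 7, "T2": 42, "T3": 76, "T4": 3},
    "path_N": {"N0": 107, "N1": 32, "N2": 13},
    "path_M": {"M0": 154, "M1": 2},
}

_CONTROL_PREFIXES = ("POS_", "NEG_", "HK_")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for :func:`generate_cohort`.

    ``dispersion`` is the negative-binomial size parameter r (variance
    mu + mu^2/r); ``effect_log2fc`` is the absolute between-class shift of
    each planted gene on the log2 scale, applied half up / half down around
    the gene's baseline, with alternating direction across the signature.
    """

    n_training: int = 60
    n_validation: int = 96
    n_endogenous: int = 730
    n_housekeeping: int = 20
    n_pos_control: int = 6
    n_neg_control: int = 8
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE
    effect_log2fc: float = 1.0
    baseline_log_mean_range: tuple[float, float] = (5.0, 10.0)  # log2 scale
    dispersion: float = 5.0
    responder_fraction: float = 72 / 156
    library_size_cv: float = 0.15
    path_t_confounding: float = 0.0  # log-odds shift of path T3 with response
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_training < 4 or self.n_validation < 4:
            raise ValueError("cohorts need at least 4 samples each")
        if len(self.signature_genes) > self.n_endogenous:
            raise ValueError("more signature genes than endogenous genes")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be non-negative")
        for g in self.signature_genes:
            if g.startswith(_CONTROL_PREFIXES):
                raise ValueError(f"effect placed on a control gene: {g}")


@dataclass
class SyntheticCohort:
    """Generated counts, annotations, and the ground truth behind them."""

    counts: CountMatrix
    annotations: list[SampleAnnotation]
    truth: dict[str, float]  # planted gene -> signed log2 fold-change (R vs NR)

    @property
    def labels(self) -> dict[str, bool]:
        return {a.sample_id: a.responder for a in self.annotations}


def _sample_categorical(rng: np.random.Generator, counts: dict[str, int], n: int) -> np.ndarray:
    levels = list(counts)
    w = np.array([counts[level] for level in levels], dtype=float)
    return rng.choice(levels, size=n, p=w / w.sum())


def generate_table1_covariates(n: int, seed: int) -> pd.DataFrame:
    """Sample clinicopathological covariates from the pooled cohort frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {
        var: _sample_categorical(rng, freqs, n)
        for var, freqs in TABLE1_POOLED_FREQUENCIES.items()
    }
    return pd.DataFrame(cols)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, size_r: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with mean mu and size (shape) r."""
    lam = rng.gamma(shape=size_r, scale=np.maximum(mu, 1e-12) / size_r)
    return rng.poisson(lam).astype(float)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate both cohorts as one count matrix plus annotations and truth.

    Planted genes are shifted by ``effect_log2fc`` between responders and
    non-responders, alternating direction along the signature (some genes up
    in responders, some up in non-responders).  Positive controls follow the
    standard two-fold-step geometric titration (128 down to 0.125 fM scaled
    to counts); negative controls are near-zero Poisson background;
    housekeeping genes are high-expressed with no class effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_training + config.n_validation

    # --- sample-level structure -------------------------------------------
    responder = rng.random(n) < config.responder_fraction
    trg = np.where(
        responder,
        rng.choice([1, 2], size=n),
        rng.choice([3, 4, 5], size=n, p=[0.5, 0.3, 0.2]),
    )
    lib = (
        rng.lognormal(mean=-0.5 * np.log1p(config.library_size_cv**2),
                      sigma=np.sqrt(np.log1p(config.library_size_cv**2)), size=n)
        if config.library_size_cv > 0
        else np.ones(n)
    )

    covar = generate_table1_covariates(n, seed=int(rng.integers(2**31)))
    if config.path_t_confounding != 0.0:
        # re-draw path_T with class-dependent odds on the T3 level
        base = TABLE1_POOLED_FREQUENCIES["path_T"]
        levels = list(base)
        w = np.array([base[level] for level in levels], dtype=float)
        for shift, mask in ((-config.path_t_confounding, responder),
                            (+config.path_t_confounding, ~responder)):
            w_cls = w.copy()
            w_cls[levels.index("T3")] *= np.exp(shift)
            covar.loc[mask, "path_T"] = rng.choice(
                levels, size=int(mask.sum()), p=w_cls / w_cls.sum()
            )

    # --- gene-level structure ---------------------------------------------
    sig = list(config.signature_genes)
    n_filler = config.n_endogenous - len(sig)
    endo_ids = sig + [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    hk_ids = [f"HK_{i:02d}" for i in range(1, config.n_housekeeping + 1)]
    pos_ids = [f"POS_{chr(65 + i)}" for i in range(config.n_pos_control)]
    neg_ids = [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_control)]

    lo, hi = config.baseline_log_mean_range
    base_endo = rng.uniform(lo, hi, size=config.n_endogenous)
    delta = np.zeros(config.n_endogenous)
    truth: dict[str, float] = {}
    for i, g in enumerate(sig):
        d = config.effect_log2fc * (1.0 if i % 2 == 0 else -1.0)
        delta[i] = d
        truth[g] = d

    # log2 mean per gene per sample: baseline +/- half the class shift
    shift = np.outer(delta, np.where(responder, 0.5, -0.5))
    mu_endo = 2.0 ** (base_endo[:, None] + shift) * lib[None, :]
    counts_endo = _nb_counts(rng, mu_endo, config.dispersion)

    base_hk = rng.uniform(8.0, 11.0, size=config.n_housekeeping)
    mu_hk = 2.0 ** base_hk[:, None] * lib[None, :]
    counts_hk = _nb_counts(rng, mu_hk, config.dispersion * 4)

    titration = 128.0 / 4.0 ** np.arange(config.n_pos_control)  # 128,32,8,... fM
    mu_pos = 200.0 * titration[:, None] * lib[None, :]  # lowest level ~25 counts
    counts_pos = rng.poisson(mu_pos).astype(float)
    counts_neg = rng.poisson(np.full((config.n_neg_control, n), 2.0)).astype(float)

    gene_ids = endo_ids + hk_ids + pos_ids + neg_ids
    gene_class = (
        ["endogenous"] * config.n_endogenous
        + ["housekeeping"] * config.n_housekeeping
        + ["positive"] * config.n_pos_control
        + ["negative"] * config.n_neg_control
    )
    counts = np.vstack([counts_endo, counts_hk, counts_pos, counts_neg])

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    matrix = CountMatrix(gene_ids, gene_class, sample_ids, counts)

    annotations = [
        SampleAnnotation(
            sample_id=sample_ids[j],
            trg=int(trg[j]),
            cohort="training" if j < config.n_training else "validation",
            gender=covar.loc[j, "gender"],
            clin_T=covar.loc[j, "clin_T"],
            clin_N=covar.loc[j, "clin_N"],
            clin_M=covar.loc[j, "clin_M"],
            path_T=covar.loc[j, "path_T"],
            path_N=covar.loc[j, "path_N"],
            path_M=covar.loc[j, "path_M"],
            differentiation=covar.loc[j, "differentiation"],
        )
        for j in range(n)
    ]
    return SyntheticCohort(matrix, annotations, truth)
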