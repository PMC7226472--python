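"""Count-matrix container, TSV/RCC reading, and nCounter-style normalization.

The normalization is the standard published three-step nCounter scheme:

1. *Positive-control scaling* — each sample is scaled by the ratio of the
   across-sample mean of positive-control geometric means to its own
   positive-control geometric mean (lane-to-lane technical correction).
2. *Background subtraction* — the background threshold is the mean plus
   ``background_sd_mult`` standard deviations of the negative-control counts
   per sample; counts are floored at zero after subtraction.
3. *Housekeeping (content) scaling* — same geometric-mean ratio construction
   over the housekeeping genes, correcting for RNA input.

Each step can be toggled off.  Downstream statistics operate on
``log2(normalized + 1)`` (see :func:`log2_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENE_CLASSES",
    "CountMatrix",
    "NormalizationReport",
    "read_counts",
    "write_counts",
    "normalize",
    "log2_counts",
]

GENE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative counts with per-gene class labels.

    Raw matrices hold integers; normalized matrices hold non-negative reals.
    """

    gene_ids: list[str]
    gene_class: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n_g, n_s = self.counts.shape
        if len(self.gene_ids) != n_g or len(self.sample_ids) != n_s:
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if len(set(self.gene_ids)) != n_g:
            dupes = pd.Index(self.gene_ids)
            raise ValueError(
                f"duplicate gene ids: {sorted(dupes[dupes.duplicated()].unique())}"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        bad = set(self.gene_class) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_index(self, gene_class: str) -> np.ndarray:
        return np.array([c == gene_class for c in self.gene_class])

    def endogenous(self) -> "CountMatrix":
        """Sub-matrix of endogenous genes only."""
        keep = self.class_index("endogenous")
        return CountMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            ["endogenous"] * int(keep.sum()),
            list(self.sample_ids),
            self.counts[keep],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            list(self.gene_ids), list(self.gene_class), list(sample_ids),
            self.counts[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.insert(0, "gene_class", self.gene_class)
        df.index.name = "gene_id"
        return df


@dataclass
class NormalizationReport:
    """Per-sample factors and flags from :func:`normalize`."""

    positive_factor: dict[str, float]
    housekeeping_factor: dict[str, float]
    background_threshold: dict[str, float]
    flagged_samples: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """TSV layout: gene_id, gene_class, then one column per sample."""
    matrix.to_frame().to_csv(path, sep="\t")


def _read_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_class" not in df.columns:
        raise ValueError("count TSV must have a 'gene_class' second column")
    classes = df["gene_class"].tolist()
    data = df.drop(columns="gene_class")
    return CountMatrix(
        [str(g) for g in df.index], classes, [str(s) for s in data.columns],
        data.to_numpy(dtype=float),
    )


def _parse_rcc(path: Path) -> tuple[str, dict[str, tuple[str, float]]]:
    """Parse one minimal RCC file: Header section for the sample id, then a
    CodeSummary section of CodeClass,Name,Count rows."""
    sample_id = path.stem
    genes: dict[str, tuple[str, float]] = {}
    section = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("<") and line.endswith(">"):
            section = line.strip("<>").lower()
            continue
        if section == "header" and line.lower().startswith("id,"):
            sample_id = line.split(",", 1)[1]
        elif section == "code_summary":
            parts = line.split(",")
            if parts[0] == "CodeClass":
                continue
            cls, name, count = parts[0].lower(), parts[1], float(parts[2])
            if name in genes:
                raise ValueError(f"{path.name}: duplicate gene id {name!r}")
            genes[name] = (cls, count)
    return sample_id, genes


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from a TSV file or a directory of RCC files.

    RCC files are merged on gene id; every sample must report the identical
    gene list, otherwise the offending sample is named in the error.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format != "rcc_dir":
        raise ValueError(f"unknown format {format!r}")

    files = sorted(path.glob("*.RCC")) + sorted(path.glob("*.rcc"))
    if not files:
        raise FileNotFoundError(f"no RCC files under {path}")
    samples: list[tuple[str, dict[str, tuple[str, float]]]] = [_parse_rcc(f) for f in files]
    ref_id, ref = samples[0]
    gene_ids = list(ref)
    for sid, genes in samples[1:]:
        missing = [g for g in gene_ids if g not in genes]
        extra = [g for g in genes if g not in ref]
        if missing or extra:
            raise ValueError(
                f"sample {sid!r}: inconsistent gene list "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
    class_map = {"endogenous": "endogenous", "positive": "positive",
                 "negative": "negative", "housekeeping": "housekeeping"}
    classes = [class_map[ref[g][0]] for g in gene_ids]
    counts = np.array([[genes[g][1] for _, genes in samples] for g in gene_ids])
    return CountMatrix(gene_ids, classes, [sid for sid, _ in samples], counts)


def write_rcc_dir(matrix: CountMatrix, path: str | Path) -> None:
    """Write one minimal RCC file per sample (Header + CodeSummary sections)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    class_name = {"endogenous": "Endogenous", "positive": "Positive",
                  "negative": "Negative", "housekeeping": "Housekeeping"}
    for j, sid in enumerate(matrix.sample_ids):
        lines = ["<Header>", f"ID,{sid}", "</Header>", "<Code_Summary>",
                 "CodeClass,Name,Count"]
        for g, cls, row in zip(matrix.gene_ids, matrix.gene_class, matrix.counts):
            lines.append(f"{class_name[cls]},{g},{row[j]:g}")
        lines.append("</Code_Summary>")
        (path / f"{sid}.RCC").write_text("\n".join(lines) + "\n")


def _geomean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def normalize(
    raw: CountMatrix,
    background_sd_mult: float = 2.0,
    *,
    positive_scaling: bool = True,
    background_subtraction: bool = True,
    housekeeping_scaling: bool = True,
) -> tuple[CountMatrix, NormalizationReport]:
    """nCounter-style normalization; see module docstring for the scheme.

    Samples whose positive-control or housekeeping geometric mean is zero are
    flagged and excluded from the output matrix.
    """
    pos = raw.counts[raw.class_index("positive")]
    neg = raw.counts[raw.class_index("negative")]
    hk = raw.counts[raw.class_index("housekeeping")]
    if positive_scaling and pos.size == 0:
        raise ValueError("no positive-control genes present")
    if background_subtraction and neg.size == 0:
        raise ValueError("no negative-control genes present")
    if housekeeping_scaling and hk.size == 0:
        raise ValueError("no housekeeping genes present")

    report = NormalizationReport({}, {}, {})
    keep: list[int] = []
    out = raw.counts.copy()

    # per-sample positive-control factors
    with np.errstate(divide="ignore"):
        pos_gm = _geomean(pos, axis=0) if pos.size else np.ones(raw.n_samples)
    pos_ok = pos_gm > 0
    grand = pos_gm[pos_ok].mean() if pos_ok.any() else np.nan

    for j, sid in enumerate(raw.sample_ids):
        if positive_scaling and pos_gm[j] == 0:
            report.flagged_samples.append((sid, "positive-control geometric mean is zero"))
            continue
        pf = float(grand / pos_gm[j]) if positive_scaling else 1.0
        col = out[:, j] * pf

        if background_subtraction:
            bg = float(neg[:, j].mean() + background_sd_mult * neg[:, j].std(ddof=0))
            bg *= pf  # threshold estimated on the same scale as the column
            col = np.maximum(col - bg, 0.0)
        else:
            bg = 0.0

        report.positive_factor[sid] = pf
        report.background_threshold[sid] = bg
        out[:, j] = col
        keep.append(j)

    # housekeeping factors are computed after the first two steps
    if housekeeping_scaling and keep:
        hk_rows = raw.class_index("housekeeping")
        hk_now = out[np.ix_(hk_rows, keep)]
        with np.errstate(divide="ignore"):
            hk_gm = _geomean(hk_now, axis=0)
        ok = hk_gm > 0
        grand_hk = hk_gm[ok].mean() if ok.any() else np.nan
        kept2 = []
        for idx, j in enumerate(keep):
            sid = raw.sample_ids[j]
            if hk_gm[idx] == 0:
                report.flagged_samples.append((sid, "housekeeping geometric mean is zero"))
                report.positive_factor.pop(sid, None)
                report.background_threshold.pop(sid, None)
                continue
            hf = float(grand_hk / hk_gm[idx])
            report.housekeeping_factor[sid] = hf
            out[:, j] *= hf
            kept2.append(j)
        keep = kept2
    else:
        for j in keep:
            report.housekeeping_factor[raw.sample_ids[j]] = 1.0

    normed = CountMatrix(
        list(raw.gene_ids), list(raw.gene_class),
        [raw.sample_ids[j] for j in keep], out[:, keep],
    )
    return normed, report


def log2_counts(matrix: CountMatrix) -> CountMatrix:
    """log2(count + 1) transform; the scale all downstream statistics use."""
    return CountMatrix(
        list(matrix.gene_ids), list(matrix.gene_class), list(matrix.sample_ids),
        np.log2(matrix.counts + 1.0),
    )
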