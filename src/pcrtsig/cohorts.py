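"""Sample-level domain types: tumor regression grades, response dichotomy, cohorts.

Pathological response to preoperative chemoradiotherapy (PCRT) is graded on a
five-tier tumor regression grade (TRG): 1 = complete regression, 2 =
near-complete, 3 = moderate, 4 = minimal, 5 = no regression.  Patients with
grade 1 or 2 are analyzed as *responders*, everyone else as *non-responders*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TRG_GRADES",
    "STAGE_VOCABULARY",
    "SampleAnnotation",
    "CohortSplit",
    "dichotomize_response",
    "annotations_to_frame",
    "annotations_from_frame",
    "write_annotations",
    "read_annotations",
]

TRG_GRADES = (1, 2, 3, 4, 5)

#: Closed, ordered categorical vocabularies for every staging variable.
#: An unknown label is a hard error, never silently recoded.
STAGE_VOCABULARY: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "differentiation": ("well", "moderate", "poor"),
    "clin_T": ("T1", "T2", "T3", "T4"),
    "clin_N": ("N0", "N1", "N2"),
    "clin_M": ("M0", "M1"),
    "path_T": ("Tis", "T0", "T1", "T2", "T3", "T4"),
    "path_N": ("N0", "N1", "N2"),
    "path_M": ("M0", "M1"),
}

COHORTS = ("training", "validation")


def dichotomize_response(trg: int) -> bool:
    """Map a five-tier TRG grade to the responder/non-responder dichotomy.

    Grades 1 (complete regression) and 2 (near-complete regression) are
    responders; grades 3-5 are non-responders.

    Raises
    ------
    ValueError
        If ``trg`` is not an integer in 1..5.
    """
    if trg not in TRG_GRADES:
        raise ValueError(f"TRG grade must be in {TRG_GRADES}, got {trg!r}")
    return trg <= 2


def _validate_label(var: str, value: str) -> str:
    vocab = STAGE_VOCABULARY[var]
    if value not in vocab:
        raise ValueError(f"unknown {var} label {value!r}; expected one of {vocab}")
    return value


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample clinical annotation.

    ``responder`` is derived from ``trg`` and validated against it.
    """

    sample_id: str
    trg: int
    cohort: str
    gender: str
    clin_T: str
    clin_N: str
    clin_M: str
    path_T: str
    path_N: str
    path_M: str
    differentiation: str
    responder: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = dichotomize_response(self.trg)
        if self.responder is None:
            object.__setattr__(self, "responder", expected)
        elif self.responder != expected:
            raise ValueError(
                f"sample {self.sample_id}: responder={self.responder} inconsistent "
                f"with TRG {self.trg}"
            )
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        for var in STAGE_VOCABULARY:
            _validate_label(var, getattr(self, var))


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint training/validation partition of sample ids."""

    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"cohorts overlap: {sorted(overlap)}")

    @classmethod
    def from_annotations(cls, annotations: Iterable[SampleAnnotation]) -> "CohortSplit":
        train, valid = [], []
        for a in annotations:
            (train if a.cohort == "training" else valid).append(a.sample_id)
        return cls(tuple(train), tuple(valid))


_COLUMNS = [
    "sample_id", "trg", "responder", "cohort", "gender",
    "clin_T", "clin_N", "clin_M", "path_T", "path_N", "path_M",
    "differentiation",
]


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Annotations as a DataFrame; response serialized as responder/non-responder."""
    rows = []
    for a in annotations:
        d = {f.name: getattr(a, f.name) for f in fields(a)}
        d["responder"] = "responder" if a.responder else "non-responder"
        rows.append(d)
    return pd.DataFrame(rows, columns=_COLUMNS)


def annotations_from_frame(frame: pd.DataFrame) -> list[SampleAnnotation]:
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        resp = row["responder"]
        if resp not in ("responder", "non-responder"):
            raise ValueError(f"bad responder label {resp!r}")
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                trg=int(row["trg"]),
                responder=(resp == "responder"),
                cohort=row["cohort"],
                gender=row["gender"],
                clin_T=row["clin_T"],
                clin_N=row["clin_N"],
                clin_M=row["clin_M"],
                path_T=row["path_T"],
                path_N=row["path_N"],
                path_M=row["path_M"],
                differentiation=row["differentiation"],
            )
        )
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    return annotations_from_frame(pd.read_csv(path, sep="\t", dtype=str).astype({"trg": int}))
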