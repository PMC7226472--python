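"""Top-level Model/Results interface for the signature-discovery pipeline.

`SignatureDiscoveryModel` is constructed from a raw count matrix plus sample
annotations (or read from TSV files); its :meth:`fit` runs the whole
discovery procedure on the training cohort — normalization, the
t-test/fold-change DEG screen, the univariate logistic shortlist, the
combinatorial search ranked by repeated 2-fold cross-validation, and the
final logistic model — and returns a `SignatureDiscoveryResults` carrying
the selected signature, its fitted coefficients, cross-validation accuracy,
and confusion-matrix evaluations on both cohorts, with `summary()` and
Table-2/3-style regression tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import deg as _deg
from . import search as _search
from .evaluate import (
    EvaluationReport,
    FittedSignatureModel,
    evaluate as _evaluate,
    fit_final_model as _fit_final_model,
    multivariate_table as _multivariate_table,
    univariate_table as _univariate_table,
)
from .cohorts import SampleAnnotation, read_annotations
from .nanostring import CountMatrix, log2_counts, normalize, read_counts

__all__ = ["SignatureDiscoveryModel", "SignatureDiscoveryResults"]


class SignatureDiscoveryModel:
    """Signature discovery on a two-cohort expression study.

    Parameters
    ----------
    counts
        Raw gene-by-sample count matrix including control genes.
    annotations
        Per-sample clinical annotations; the ``cohort`` field defines the
        training/validation split and ``responder`` the outcome.
    """

    def __init__(self, counts: CountMatrix, annotations: Sequence[SampleAnnotation]):
        ids = set(counts.sample_ids)
        missing = [a.sample_id for a in annotations if a.sample_id not in ids]
        if missing:
            raise ValueError(f"annotated samples absent from counts: {missing}")
        self.counts = counts
        self.annotations = list(annotations)
        self.labels = {a.sample_id: a.responder for a in annotations}

    @classmethod
    def from_files(cls, counts_tsv: str | Path, annotations_tsv: str | Path):
        return cls(read_counts(counts_tsv, format="tsv"), read_annotations(annotations_tsv))

    def _cohort_ids(self, cohort: str) -> list[str]:
        return [a.sample_id for a in self.annotations if a.cohort == cohort]

    def fit(
        self,
        *,
        cv_seed: int = 0,
        cv_repetitions: int = 300,
        spec: _search.CombinationSpec | None = None,
        auc_threshold: float = _search.AUC_THRESHOLD,
        max_cv_candidates: int = 60,
        equal_var: bool = True,
        background_sd_mult: float = 2.0,
    ) -> "SignatureDiscoveryResults":
        normed, report = normalize(self.counts, background_sd_mult=background_sd_mult)
        logm = log2_counts(normed)
        train_ids = [s for s in self._cohort_ids("training") if s in normed.sample_ids]
        valid_ids = [s for s in self._cohort_ids("validation") if s in normed.sample_ids]
        train = logm.subset_samples(train_ids)
        valid = logm.subset_samples(valid_ids)

        degs = _deg.t_test_fc(train, self.labels, equal_var=equal_var)
        degs = _deg.univariate_logistic_filter(train, self.labels, degs)
        shortlist = _deg.shortlist(degs)

        candidates: list[_search.SignatureCandidate] = []
        best = None
        if shortlist:
            cv = _search.CVConfig(repetitions=cv_repetitions, seed=cv_seed)
            candidates = _search.run_search(
                train, self.labels, shortlist,
                spec=spec, cv=cv, max_cv_candidates=max_cv_candidates,
                auc_threshold=auc_threshold,
            )
            best = _search.rank_and_select(candidates)

        final = train_report = valid_report = None
        if best is not None:
            final = _fit_final_model(best.genes, train, self.labels)
            train_report = _evaluate(final, train, self.labels)
            valid_report = _evaluate(final, valid, self.labels)

        return SignatureDiscoveryResults(
            model=self,
            normalization_report=report,
            deg_table=degs,
            shortlist=shortlist,
            candidates=candidates,
            selected=best,
            final_model=final,
            training_matrix=train,
            validation_matrix=valid,
            training_report=train_report,
            validation_report=valid_report,
        )


def _contrast_features(
    annotations: Sequence[SampleAnnotation],
    signature_high: pd.Series | None,
) -> pd.DataFrame:
    """Table-2-style binary contrasts; the second-named group codes 1."""
    idx = [a.sample_id for a in annotations]
    f = pd.DataFrame(index=idx)
    if signature_high is not None:
        f["signature (low vs high)"] = signature_high.reindex(idx).astype(float)
    f["gender (male vs female)"] = [1.0 if a.gender == "female" else 0.0 for a in annotations]
    f["differentiation (moderate vs well)"] = [
        {"moderate": 0.0, "well": 1.0}.get(a.differentiation, np.nan) for a in annotations
    ]
    f["clin_T (T2 vs T3-T4)"] = [
        np.nan if a.clin_T == "T1" else (1.0 if a.clin_T in ("T3", "T4") else 0.0)
        for a in annotations
    ]
    f["clin_N (N0-N1 vs N2)"] = [1.0 if a.clin_N == "N2" else 0.0 for a in annotations]
    f["clin_M (M0 vs M1)"] = [1.0 if a.clin_M == "M1" else 0.0 for a in annotations]
    f["path_T (Tis-T0-T1-T2 vs T3-T4)"] = [
        1.0 if a.path_T in ("T3", "T4") else 0.0 for a in annotations
    ]
    f["path_N (N0-N1 vs N2)"] = [1.0 if a.path_N == "N2" else 0.0 for a in annotations]
    f["path_M (M0 vs M1)"] = [1.0 if a.path_M == "M1" else 0.0 for a in annotations]
    return f


@dataclass
class SignatureDiscoveryResults:
    """Everything the discovery run produced; see the attributes."""

    model: SignatureDiscoveryModel
    normalization_report: object
    deg_table: pd.DataFrame
    shortlist: list[str]
    candidates: list[_search.SignatureCandidate]
    selected: _search.SignatureCandidate | None
    final_model: FittedSignatureModel | None
    training_matrix: CountMatrix
    validation_matrix: CountMatrix
    training_report: EvaluationReport | None
    validation_report: EvaluationReport | None

    @property
    def signature(self) -> tuple[str, ...] | None:
        return self.selected.genes if self.selected else None

    def _training_annotations(self) -> list[SampleAnnotation]:
        return [a for a in self.model.annotations if a.cohort == "training"]

    def _features(self) -> tuple[pd.DataFrame, pd.Series]:
        if self.final_model is None:
            raise ValueError("no signature was selected; tables unavailable")
        ann = self._training_annotations()
        high = pd.Series(
            self.final_model.dichotomize(self.training_matrix),
            index=self.training_matrix.sample_ids,
        )
        feats = _contrast_features(ann, high)
        y = pd.Series({a.sample_id: float(a.responder) for a in ann}).reindex(feats.index)
        return feats, y

    def univariate_table(self) -> pd.DataFrame:
        """Per-feature logistic associations with response (training cohort)."""
        feats, y = self._features()
        keep = [c for c in feats.columns if feats[c].nunique(dropna=True) > 1]
        return _univariate_table(feats[keep], y)

    def multivariate_table(self, variables: list[str] | None = None) -> pd.DataFrame:
        """Joint logistic model over the univariately significant features.

        By default the variables with univariate p < 0.05 enter the joint
        model (the usual two-step clinical selection); pass ``variables`` to
        override.
        """
        feats, y = self._features()
        if variables is None:
            uni = self.univariate_table()
            ok = uni[(uni["p"] < 0.05) & ~uni["separation_flag"]]
            variables = list(ok["variable"])
        if not variables:
            raise ValueError("no univariately significant variables to model")
        return _multivariate_table(feats[variables], y)

    def summary(self) -> str:
        lines = ["Signature discovery summary", "=" * 27]
        degs = self.deg_table
        lines.append(f"Endogenous genes tested: {len(degs)}")
        lines.append(f"DEGs (p<0.05, |FC|>1.5): {int(degs['passed_deg'].sum())}")
        lines.append(f"Shortlist after univariate logistic: {len(self.shortlist)}")
        lines.append(f"Candidates scored: {len(self.candidates)} "
                     f"(retained: {sum(c.retained for c in self.candidates)})")
        if self.selected is None:
            lines.append("No signature found (no candidate passed the filters).")
            return "\n".join(lines)
        sel = self.selected
        lines.append(f"Selected signature ({len(sel.genes)} genes): {', '.join(sel.genes)}")
        lines.append(f"  model LR p = {sel.model_p:.3g}; AUC = {sel.auc:.3f}")
        lines.append(f"  CV accuracy = {sel.cv_accuracy:.1%} over {sel.cv_reps} contributing splits")
        for name, rep in (("Training", self.training_report), ("Validation", self.validation_report)):
            d = rep.as_dict()
            fmt = lambda v: "undefined" if v is None else f"{v:.1%}"
            lines.append(
                f"{name}: accuracy {fmt(d['accuracy'])}, sensitivity {fmt(d['sensitivity'])}, "
                f"specificity {fmt(d['specificity'])}, PPV {fmt(d['ppv'])}, NPV {fmt(d['npv'])}"
            )
        return "\n".join(lines)
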