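"""Leave-one-subject-out evaluation and the modality-combination grid.

Each participant's trials form one test fold while all other participants
form the training set, so every reported number is subject-independent.
Metrics follow the standard one-vs-rest definitions, reported in percent:

    precision = TP / (TP + FP) * 100
    recall    = TP / (TP + FN) * 100
    F1        = 2 * precision * recall / (precision + recall)

with 0 reported (and the class flagged) when a denominator is zero. The
headline score is the macro (unweighted) mean F1 over the three intensity
classes, computed on predictions pooled across folds; per-fold macro-F1
lists are retained for downstream statistical comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CLASSIFIER_KINDS, ClassifierSpec, train
from .dataio import filter_trials
from .errors import DataError
from .features import FeatureMatrix, extract_matrix
from .fusion import (MODALITY_COMBOS, decision_fuse, feature_fuse,
                     fit_fusion_weights)
from .selection import fit_selection

__all__ = [
    "EvalConfig",
    "loso_folds",
    "precision_recall_f1",
    "run_single_cell",
    "run_experiment",
    "ExperimentReport",
]

CLASS_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class EvalConfig:
    """Grid specification for one experiment run."""

    combos: tuple = MODALITY_COMBOS
    classifiers: tuple = CLASSIFIER_KINDS
    fusion_modes: tuple = ("feature", "decision")
    selection_scope: str = "complete"  # "complete" (dataset-level, as run
    # historically; leakage-prone) or "train_only" (recommended)
    k_features: int = 15
    window_mode: str = "full_trial"
    include_person: bool = True
    fusion_rule: str = "weighted_sum"
    inner_cv_groups: int | None = 5  # None = inner leave-one-subject-out
    rng_seed: int = 0


def loso_folds(participant_ids) -> list:
    """One (train_ids, test_id) fold per participant."""
    unique = sorted(set(participant_ids))
    if len(unique) < 2:
        raise DataError(f"need >= 2 participants for LOSO, got {len(unique)}")
    return [([p for p in unique if p != test], test) for test in unique]


def precision_recall_f1(confusion) -> dict:
    """Per-class and macro precision/recall/F1 (percent) from a 3x3
    confusion matrix with rows = truth, columns = prediction."""
    confusion = np.asarray(confusion)
    if np.any(confusion < 0):
        raise DataError("confusion matrix has negative entries")
    confusion = confusion.astype(float)
    tp = np.diag(confusion)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    per_class = {}
    degenerate = []
    f1s = []
    for i, label in enumerate(CLASS_LABELS):
        p = 100.0 * tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
        r = 100.0 * tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            degenerate.append(label)
        per_class[label] = {"precision": p, "recall": r, "f1": f1}
        f1s.append(f1)
    return {
        "per_class": per_class,
        "macro_f1": float(np.mean(f1s)),
        "degenerate_classes": degenerate,
    }


def _confusion(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return m


def _fold_masks(matrix: FeatureMatrix, train_ids, test_id):
    pids = matrix.participant_ids
    return np.isin(pids, list(train_ids)), pids == test_id


def _inner_groups(train_ids, n_groups):
    """Deterministic subject-grouped partition of the training participants."""
    train_ids = sorted(train_ids)
    if n_groups is None or n_groups >= len(train_ids):
        return [[p] for p in train_ids]  # inner leave-one-subject-out
    return [train_ids[i::n_groups] for i in range(n_groups)]


@dataclass
class CellResult:
    """Pooled LOSO outcome for one (combo, classifier, fusion-mode) cell."""

    combo: tuple
    classifier: str
    fusion: str
    pooled_confusion: np.ndarray
    metrics: dict
    fold_macro_f1: dict  # participant_id -> macro F1 (%)

    @property
    def macro_f1(self) -> float:
        return self.metrics["macro_f1"]

    def to_json_dict(self) -> dict:
        return {
            "combo": list(self.combo),
            "classifier": self.classifier,
            "fusion": self.fusion,
            "pooled_confusion": self.pooled_confusion.tolist(),
            "metrics": self.metrics,
            "fold_macro_f1": self.fold_macro_f1,
        }


def run_single_cell(
    matrix: FeatureMatrix,
    combo,
    clf_kind: str,
    config: EvalConfig = EvalConfig(),
) -> CellResult:
    """LOSO over a single merged (feature-fused) modality combination."""
    data = feature_fuse(matrix, combo, include_person=config.include_person)
    y = matrix.labels
    spec = ClassifierSpec(kind=clf_kind, rng_seed=config.rng_seed)
    shared_selection = (
        fit_selection(data, y, k=config.k_features, scope="complete")
        if config.selection_scope == "complete"
        else None
    )
    fold_conf = {}
    for train_ids, test_id in loso_folds(matrix.participant_ids):
        tr, te = _fold_masks(matrix, train_ids, test_id)
        sel = shared_selection or fit_selection(
            data[tr], y[tr], k=config.k_features, scope="train_only"
        )
        model = train(spec, sel.transform(data[tr]), y[tr])
        y_pred = model.predict(sel.transform(data[te]))
        fold_conf[test_id] = _confusion(y[te], y_pred)
    pooled = sum(fold_conf.values())
    return CellResult(
        combo=tuple(combo),
        classifier=clf_kind,
        fusion="feature",
        pooled_confusion=pooled,
        metrics=precision_recall_f1(pooled),
        fold_macro_f1={
            pid: precision_recall_f1(c)["macro_f1"] for pid, c in fold_conf.items()
        },
    )


def _decision_fusion_cells(matrix, config: EvalConfig) -> list:
    """All decision-fusion cells, sharing per-modality base models per fold."""
    y = matrix.labels
    folds = loso_folds(matrix.participant_ids)
    modalities = sorted({m for combo in config.combos for m in combo})
    results = []
    for clf_kind in config.classifiers:
        spec = ClassifierSpec(kind=clf_kind, rng_seed=config.rng_seed)
        # per fold: posterior on the test subject + class weights, per modality
        per_fold = []
        for train_ids, test_id in folds:
            tr, te = _fold_masks(matrix, train_ids, test_id)
            posteriors, inner_preds = {}, {}
            for modality in modalities:
                data = feature_fuse(matrix, (modality,),
                                    include_person=config.include_person)
                if config.selection_scope == "complete":
                    sel = fit_selection(data, y, k=config.k_features,
                                        scope="complete")
                else:
                    sel = fit_selection(data[tr], y[tr], k=config.k_features,
                                        scope="train_only")
                model = train(spec, sel.transform(data[tr]), y[tr])
                posteriors[modality] = model.predict_posterior(
                    sel.transform(data[te]))
                # internal subject-grouped CV on the training participants
                pred = np.full(int(tr.sum()), -1)
                tr_idx = np.flatnonzero(tr)
                tr_pids = matrix.participant_ids[tr_idx]
                for group in _inner_groups(train_ids, config.inner_cv_groups):
                    in_te = np.isin(tr_pids, group)
                    inner_model = train(
                        spec, sel.transform(data.iloc[tr_idx[~in_te]]),
                        y[tr_idx[~in_te]],
                    )
                    pred[in_te] = inner_model.predict(
                        sel.transform(data.iloc[tr_idx[in_te]]))
                inner_preds[modality] = pred
            weights = fit_fusion_weights(inner_preds, y[tr])
            per_fold.append((test_id, te, posteriors, weights))
        for combo in config.combos:
            fold_conf = {}
            for test_id, te, posteriors, weights in per_fold:
                sub = {m: posteriors[m] for m in combo}
                y_pred = decision_fuse(weights, sub, rule=config.fusion_rule)
                fold_conf[test_id] = _confusion(y[te], y_pred)
            pooled = sum(fold_conf.values())
            results.append(
                CellResult(
                    combo=tuple(combo),
                    classifier=clf_kind,
                    fusion="decision",
                    pooled_confusion=pooled,
                    metrics=precision_recall_f1(pooled),
                    fold_macro_f1={
                        pid: precision_recall_f1(c)["macro_f1"]
                        for pid, c in fold_conf.items()
                    },
                )
            )
    return results


@dataclass
class ExperimentReport:
    """Full grid of pooled LOSO results plus the exclusion ledger."""

    cells: list
    ledger: object = None
    config: EvalConfig = field(default_factory=EvalConfig)

    def cell(self, combo, classifier: str, fusion: str = "feature") -> CellResult:
        combo = tuple(combo)
        for c in self.cells:
            if (c.combo, c.classifier, c.fusion) == (combo, classifier, fusion):
                return c
        raise KeyError((combo, classifier, fusion))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "combo": "+".join(c.combo),
                "classifier": c.classifier,
                "fusion": c.fusion,
                "macro_f1": c.macro_f1,
            }
            for c in self.cells
        )

    def save(self, directory) -> None:
        """report.json, folds.csv and per-cell confusion CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "ledger": self.ledger.to_dict() if self.ledger else None,
            "cells": [c.to_json_dict() for c in self.cells],
        }
        (directory / "report.json").write_text(json.dumps(payload, indent=2))
        rows = [
            {
                "combo": "+".join(c.combo),
                "classifier": c.classifier,
                "fusion": c.fusion,
                "participant_id": pid,
                "macro_f1": f1,
            }
            for c in self.cells
            for pid, f1 in c.fold_macro_f1.items()
        ]
        pd.DataFrame(rows).to_csv(directory / "folds.csv", index=False)
        for c in self.cells:
            name = f"confusion_{'+'.join(c.combo)}_{c.classifier}_{c.fusion}.csv"
            pd.DataFrame(
                c.pooled_confusion, index=CLASS_LABELS, columns=CLASS_LABELS
            ).to_csv(directory / name)


def run_experiment(study, config: EvalConfig = EvalConfig()) -> ExperimentReport:
    """Run the modality-combination x classifier x fusion-mode grid.

    Feature fusion runs for every requested combination (a single modality
    reduces to its own classifier); decision fusion reduces to the base
    classifier for single-modality combinations.
    """
    kept, ledger = filter_trials(study.records)
    matrix = extract_matrix(
        kept,
        study.participants,
        window_mode=config.window_mode,
        include_person=config.include_person,
    )
    cells = []
    if "feature" in config.fusion_modes:
        for combo in config.combos:
            for clf_kind in config.classifiers:
                cells.append(run_single_cell(matrix, combo, clf_kind, config))
    if "decision" in config.fusion_modes:
        # a single modality has nothing to fuse: the cell reduces exactly to
        # the no-fusion (base classifier) run
        existing = {(c.combo, c.classifier): c for c in cells}
        for combo in config.combos:
            if len(combo) == 1:
                for clf_kind in config.classifiers:
                    base = existing.get((tuple(combo), clf_kind)) or run_single_cell(
                        matrix, combo, clf_kind, config
                    )
                    cells.append(
                        CellResult(
                            combo=base.combo,
                            classifier=base.classifier,
                            fusion="decision",
                            pooled_confusion=base.pooled_confusion,
                            metrics=base.metrics,
                            fold_macro_f1=base.fold_macro_f1,
                        )
                    )
        decision_combos = tuple(c for c in config.combos if len(c) >= 2)
        if decision_combos:
            sub = EvalConfig(
                combos=decision_combos,
                classifiers=config.classifiers,
                fusion_modes=("decision",),
                selection_scope=config.selection_scope,
                k_features=config.k_features,
                window_mode=config.window_mode,
                include_person=config.include_person,
                fusion_rule=config.fusion_rule,
                inner_cv_groups=config.inner_cv_groups,
                rng_seed=config.rng_seed,
            )
            cells.extend(_decision_fusion_cells(matrix, sub))
    return ExperimentReport(cells=cells, ledger=ledger, config=config)
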