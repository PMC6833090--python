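"""Multimodal combination: feature-level and decision-level fusion.

Feature fusion concatenates the modality feature sets (person columns
de-duplicated) and lets selection + a single classifier run on the merged
matrix.

Decision fusion trains one classifier per modality and combines their
posteriors with class-based weights learned from performance on the
training data: weight(m, c) is the per-class F1 (0..1) of modality m's
classifier measured by an internal subject-grouped cross-validation pass
over the training participants. At test time the fused score of class c is

    score(c) = sum over modalities m of weight(m, c) * posterior(m, c)

and the class with the highest score wins, ties resolved toward the
higher intensity. Additive and product-of-experts variants are available
behind ``rule`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import argmax_high
from .errors import ConfigError, ContractError, DataError

__all__ = ["FusionWeights", "feature_fuse", "per_class_f1", "fit_fusion_weights",
           "decision_fuse", "MODALITY_COMBOS"]

#: The seven non-empty modality combinations.
MODALITY_COMBOS = (
    ("hr",), ("eda",), ("temp",),
    ("hr", "eda"), ("hr", "temp"), ("eda", "temp"),
    ("hr", "eda", "temp"),
)


@dataclass
class FusionWeights:
    """Per-(modality, class) weights in [0, 1]."""

    weights: dict  # modality -> np.ndarray of shape (3,)

    def __post_init__(self):
        for m, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if not np.all(np.isfinite(w)) or np.any(w < 0):
                raise ConfigError("weights", f"invalid weight vector for {m!r}: {w}")
            self.weights[m] = w

    @property
    def inert_modalities(self) -> list:
        """Modalities whose every class weight is zero (contribute nothing)."""
        return [m for m, w in self.weights.items() if np.all(w == 0)]

    def to_json_dict(self) -> dict:
        return {m: list(map(float, w)) for m, w in self.weights.items()}


def feature_fuse(matrix, modalities, include_person: bool = True) -> pd.DataFrame:
    """Column-wise concatenation of the requested modality feature groups.

    Duplicate groups and shared person columns appear once (set
    semantics); a single group reduces to that modality's own matrix.
    """
    cols = matrix.columns_for(modalities, include_person=include_person)
    return matrix.data[cols]


def per_class_f1(confusion: np.ndarray) -> np.ndarray:
    """Per-class one-vs-rest F1 on the 0..1 scale; 0 where undefined."""
    confusion = np.asarray(confusion, dtype=float)
    tp = np.diag(confusion)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    return f1


def fit_fusion_weights(
    modality_predictions: dict,
    y_true: np.ndarray,
    n_classes: int = 3,
) -> FusionWeights:
    """Class-based weights from internal training-data predictions.

    ``modality_predictions`` maps each modality to hard labels obtained on
    training participants the modality's classifier had not seen (an
    internal subject-grouped CV pass, produced by the caller); the weight
    of (modality, class) is that class's F1.
    """
    y_true = np.asarray(y_true, dtype=int)
    weights = {}
    for modality, y_pred in modality_predictions.items():
        y_pred = np.asarray(y_pred, dtype=int)
        if y_pred.shape != y_true.shape:
            raise DataError(
                f"modality {modality!r}: {len(y_pred)} predictions for "
                f"{len(y_true)} training labels"
            )
        confusion = np.zeros((n_classes, n_classes))
        np.add.at(confusion, (y_true, y_pred), 1)
        weights[modality] = per_class_f1(confusion)
    return FusionWeights(weights=weights)


def decision_fuse(
    weights: FusionWeights,
    posteriors: dict,
    rule: str = "weighted_sum",
) -> np.ndarray:
    """Fuse per-modality posterior matrices into hard labels.

    posteriors: modality -> (n, 3) row-stochastic array. Scores are
    invariant to modality order and to scaling all weights by a positive
    constant.
    """
    if not posteriors:
        raise DataError("no posteriors supplied")
    missing = set(posteriors) - set(weights.weights)
    if missing:
        raise ContractError(f"no fusion weights for modalities {sorted(missing)}")
    mods = sorted(posteriors)
    n = len(next(iter(posteriors.values())))
    if rule == "weighted_sum":
        scores = np.zeros((n, 3))
        for m in mods:
            scores += weights.weights[m][None, :] * np.asarray(posteriors[m])
    elif rule == "additive":
        scores = np.zeros((n, 3))
        for m in mods:
            scores += weights.weights[m][None, :] + np.asarray(posteriors[m])
    elif rule == "product":
        scores = np.ones((n, 3))
        for m in mods:
            scores *= 1e-12 + weights.weights[m][None, :] * np.asarray(posteriors[m])
    else:
        raise ConfigError("fusion_rule", f"unknown rule {rule!r}")
    return argmax_high(scores)
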