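"""Feature normalisation and minimum-redundancy-maximum-relevance selection.

MRMR is the greedy forward scheme with the MID (mutual-information
difference) criterion: at each step pick the unselected feature f
maximising  I(f; class) - mean over already-selected s of I(f; s).
Mutual information is estimated after equal-frequency discretisation of
each feature into 10 bins (class labels are used as-is). Ties are broken
by higher relevance I(f; class), then lexicographically by name, so the
procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError

__all__ = ["Normaliser", "fit_normaliser", "mrmr_select", "fit_selection"]

N_BINS = 10


@dataclass
class Normaliser:
    """Column-wise z-scoring with training-median imputation of NaNs.

    Zero-variance columns are flagged and centred only (their z-score is 0
    everywhere), so degenerate features cannot blow up downstream models.
    """

    means: pd.Series
    sds: pd.Series
    medians: pd.Series
    constant_columns: list = field(default_factory=list)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.means.index) - set(data.columns)
        if missing:
            raise DataError(f"columns absent at transform time: {sorted(missing)}")
        x = data[self.means.index].copy()
        x = x.fillna(self.medians)
        x = x - self.means
        nondeg = [c for c in x.columns if c not in self.constant_columns]
        x[nondeg] = x[nondeg] / self.sds[nondeg]
        return x


def fit_normaliser(data: pd.DataFrame) -> Normaliser:
    """Fit per-column mean/SD (sample, n-1) and imputation medians."""
    if len(data) < 2:
        raise DataError(f"need >= 2 rows to fit a normaliser, got {len(data)}")
    medians = data.median()
    filled = data.fillna(medians)
    means = filled.mean()
    sds = filled.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    # medians of all-NaN columns fall back to 0
    medians = medians.fillna(0.0)
    means = means.fillna(0.0)
    return Normaliser(means=means, sds=sds, medians=medians, constant_columns=constant)


def _equal_frequency_bins(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Rank-based equal-frequency discretisation.

    Tied values share a rank and therefore a bin, and any strictly
    monotone transform that preserves the ordering yields identical codes.
    """
    ranks = rankdata(x, method="average")  # 1..n
    codes = np.floor((ranks - 0.5) / x.size * n_bins).astype(int)
    return np.clip(codes, 0, n_bins - 1)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two integer-coded
    variables, from the joint contingency table."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(
    data: pd.DataFrame,
    labels: np.ndarray,
    k: int = 15,
    n_bins: int = N_BINS,
) -> list:
    """Greedy forward MRMR (MID criterion); returns k names in selection order."""
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("labels contain fewer than 2 classes")
    columns = sorted(data.columns)
    label_codes = np.unique(labels, return_inverse=True)[1]
    codes = {c: _equal_frequency_bins(data[c].to_numpy(dtype=float), n_bins)
             for c in columns}
    relevance = {c: mutual_information(label_codes, codes[c]) for c in columns}

    selected: list = []
    redundancy_sum = dict.fromkeys(columns, 0.0)
    pair_mi: dict = {}
    while len(selected) < min(k, len(columns)):
        best = None
        for c in columns:
            if c in selected:
                continue
            red = redundancy_sum[c] / len(selected) if selected else 0.0
            score = relevance[c] - red
            key = (score, relevance[c], _NameOrder(c))
            if best is None or key > best[0]:
                best = (key, c)
        chosen = best[1]
        selected.append(chosen)
        for c in columns:
            if c in selected:
                continue
            pair = (chosen, c)
            if pair not in pair_mi:
                pair_mi[pair] = mutual_information(codes[chosen], codes[c])
            redundancy_sum[c] += pair_mi[pair]
    return selected


class _NameOrder(str):
    """Reverses lexicographic comparison so max() prefers the earlier name."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


@dataclass
class SelectionModel:
    """Fitted normalisation + ordered selected-feature list."""

    normaliser: Normaliser
    selected: list
    scope: str = "train_only"  # or "complete"

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return self.normaliser.transform(data)[self.selected]

    def to_json_dict(self) -> dict:
        return {"scope": self.scope, "selected": list(self.selected)}


def fit_selection(
    data: pd.DataFrame,
    labels: np.ndarray,
    k: int = 15,
    scope: str = "train_only",
) -> SelectionModel:
    """Fit the normaliser then run MRMR on the z-scored matrix."""
    norm = fit_normaliser(data)
    z = norm.transform(data)
    selected = mrmr_select(z, labels, k=k)
    return SelectionModel(normaliser=norm, selected=selected, scope=scope)
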