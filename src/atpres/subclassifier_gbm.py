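"""Gradient-boosted-trees subclassifier on the flattened 510-feature vector.

The boosting machinery itself is delegated to scikit-learn's histogram-based
``HistGradientBoostingClassifier`` — the same histogram-GBDT family the
field's dedicated libraries implement.  The positive class is up-weighted by
``scale_pos_weight`` = n_neg / n_pos (the ratio of the two cross-entropy
class weights used by the convolutional subclassifiers), applied as a
per-sample weight, which is mathematically equivalent for binary log-loss.

Feature order of the flat vector: the 17x20 profile window row-major, then
the 17x3 secondary-structure window, then the 17x7 one-hot window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier

from .features import WindowedDataset


@dataclass
class GBMConfig:
    num_leaves: int = 31
    learning_rate: float = 0.1
    n_estimators: int = 500
    early_stopping_rounds: int = 50
    scale_pos_weight: float | None = None  # None -> computed from the labels
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_pos_weight is not None and self.scale_pos_weight <= 0:
            raise ValueError("scale_pos_weight must be > 0")


def pos_weight(labels: np.ndarray) -> float:
    """Weight for positive samples: n_neg / n_pos.

    Equals W_pos / W_neg of the cross-entropy class weights, so both
    subclassifier families counteract the same imbalance the same way.
    """
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("pos_weight undefined: no positive samples")
    return n_neg / n_pos


def train_gbm(
    dataset: WindowedDataset, config: GBMConfig | None = None
) -> HistGradientBoostingClassifier:
    """Fit the booster on the flattened features with positive up-weighting.

    Early stopping monitors log-loss on an internal validation split.
    Deterministic under a fixed seed and a single thread.
    """
    config = config or GBMConfig()
    if dataset.labels is None:
        raise ValueError("training requires a labeled dataset")
    labels = np.asarray(dataset.labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")
    spw = config.scale_pos_weight
    if spw is None:
        spw = pos_weight(labels)
    sample_weight = np.where(labels == 1, spw, 1.0)
    booster = HistGradientBoostingClassifier(
        max_leaf_nodes=config.num_leaves,
        learning_rate=config.learning_rate,
        max_iter=config.n_estimators,
        early_stopping=True,
        n_iter_no_change=config.early_stopping_rounds,
        validation_fraction=config.validation_fraction,
        random_state=config.seed,
    )
    try:
        booster.fit(dataset.flat, labels, sample_weight=sample_weight)
    except ValueError as exc:
        raise ValueError(
            f"gradient-boosting fit failed on {len(dataset)} samples: {exc}"
        ) from exc
    return booster


def predict_proba_gbm(
    booster: HistGradientBoostingClassifier, dataset: WindowedDataset
) -> np.ndarray:
    """Positive-class probability per residue, aligned to the dataset."""
    return booster.predict_proba(dataset.flat)[:, 1]


def save_gbm(booster, path: str | Path) -> None:
    joblib.dump(booster, path)


def load_gbm(path: str | Path):
    return joblib.load(path)
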