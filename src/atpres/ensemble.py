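"""Combining the three subclassifiers and choosing weights and threshold.

Four combination strategies are supported for the aligned per-residue
probability tracks: elementwise maximum, minimum, mean, and a convex
weighted sum w1*s1 + w2*s2 + w3*s3 with w1 + w2 + w3 = 1.  The weight
distribution is grid-searched (w1, w2 in 0.1..0.9 step 0.1, w3 = 1-w1-w2
kept >= 0.1 so every subclassifier contributes) against pooled AUC of
out-of-fold predictions from five-fold cross-validation split at *chain*
level — adjacent residues share 16/17 of their windows, so residue-level
splits would leak.  The operating threshold is the probability cut that
maximizes the Matthews correlation coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import confusion, metrics_from_confusion, roc_auc
from .features import WindowedDataset

logger = logging.getLogger("atpres")

STRATEGIES = ("max", "min", "mean", "weighted")


@dataclass(frozen=True)
class EnsembleWeights:
    """Convex weights for (multi-IncepResNet, multi-Xception, GBM)."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        for w in (self.w1, self.w2, self.w3):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weights must lie in [0, 1], got {w}")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.w1 + self.w2 + self.w3}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


def combine(
    tracks,
    strategy: str = "weighted",
    weights: EnsembleWeights | None = None,
) -> np.ndarray:
    """Merge three aligned probability tracks into one."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    arr = np.vstack([np.asarray(t, dtype=float) for t in tracks])
    if arr.shape[0] != 3:
        raise ValueError(f"expected 3 tracks, got {arr.shape[0]}")
    if strategy == "max":
        return arr.max(axis=0)
    if strategy == "min":
        return arr.min(axis=0)
    if strategy == "mean":
        return arr.mean(axis=0)
    if weights is None:
        raise ValueError("strategy 'weighted' requires weights")
    return weights.as_array() @ arr


@dataclass
class CVPlan:
    """Chain-level assignment of every chain to one of k folds."""

    folds: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def heldout_chains(self, fold: int) -> list[str]:
        return self.folds[fold]

    def training_chains(self, fold: int) -> list[str]:
        return [c for i, f in enumerate(self.folds) if i != fold for c in f]


def make_cv_plan(chains, k: int = 5, seed: int = 0) -> CVPlan:
    """Shuffle chains under the seed, deal them round-robin into k folds."""
    ids = [c if isinstance(c, str) else c.chain_id for c in chains]
    if len(ids) < k:
        raise ValueError(f"need at least {k} chains for {k}-fold CV, "
                         f"got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, cid in enumerate(order):
        folds[i % k].append(cid)
    return CVPlan(folds=folds, seed=seed)


def out_of_fold_tracks(
    dataset: WindowedDataset, plan: CVPlan, trainers
) -> list[np.ndarray]:
    """Out-of-fold probability tracks covering every residue.

    ``trainers`` is a sequence of callables ``(train_ds, test_ds) -> probs``,
    one per subclassifier.  For each fold the subclassifiers are fitted on
    the other folds' chains and predict the held-out chains, so no residue
    is ever predicted by a model trained on its own chain.
    """
    n = len(dataset)
    tracks = [np.full(n, np.nan) for _ in trainers]
    for fold in range(plan.k):
        held = set(plan.heldout_chains(fold))
        mask = np.fromiter(
            (c in held for c in dataset.chain_ids), dtype=bool, count=n
        )
        train_ds = dataset.subset(~mask)
        test_ds = dataset.subset(mask)
        logger.info(
            "fold %d/%d: %d train / %d held-out residues",
            fold + 1, plan.k, len(train_ds), len(test_ds),
        )
        for t, trainer in enumerate(trainers):
            tracks[t][mask] = trainer(train_ds, test_ds)
    for t, track in enumerate(tracks):
        if np.isnan(track).any():
            raise RuntimeError(f"track {t}: residues left unpredicted")
    return tracks


def weight_grid() -> list[EnsembleWeights]:
    """The 36 grid points: w1, w2 in {0.1..0.9}, w3 = 1-w1-w2 >= 0.1."""
    points = []
    for i in range(1, 10):
        for j in range(1, 10):
            k = 10 - i - j
            if k >= 1:
                points.append(EnsembleWeights(i / 10, j / 10, k / 10))
    return points


def grid_search_weights(
    tracks, labels: np.ndarray
) -> tuple[EnsembleWeights, pd.DataFrame]:
    """Pick the weight distribution maximizing pooled AUC over the grid.

    Returns the argmax and the full (w1, w2, w3, auc) surface.  Ties break
    toward larger w3, then larger w1.  A flat surface (identical tracks)
    returns the first point under that ordering with a logged note.
    """
    labels = np.asarray(labels).astype(int)
    rows = []
    for w in weight_grid():
        merged = combine(tracks, "weighted", w)
        auc, _ = roc_auc(labels, merged)
        rows.append((w.w1, w.w2, w.w3, auc))
    surface = pd.DataFrame(rows, columns=["w1", "w2", "w3", "auc"])
    if np.allclose(surface["auc"], surface["auc"].iloc[0]):
        logger.warning(
            "weight surface is flat (identical tracks?); returning the "
            "largest-w3 grid point"
        )
    best = surface.sort_values(
        ["auc", "w3", "w1"], ascending=[False, False, False]
    ).iloc[0]
    return EnsembleWeights(float(best.w1), float(best.w2),
                           float(best.w3)), surface


def select_threshold(track: np.ndarray, labels: np.ndarray) -> float:
    """The probability cut that maximizes MCC.

    Candidates are the midpoints between adjacent sorted unique
    probabilities (plus end cuts just outside the observed range); the
    smallest maximizing threshold is returned.
    """
    track = np.asarray(track, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection undefined: labels are "
                         "single-class (MCC has no signal)")
    uniq = np.unique(track)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 0.5], mids, [uniq[-1] + 0.5]])
    best_thr, best_mcc = candidates[0], -np.inf
    for thr in candidates:
        preds = (track > thr).astype(int)
        mcc = metrics_from_confusion(confusion(labels, preds))["mcc"]
        if mcc > best_mcc + 1e-12:
            best_mcc, best_thr = mcc, thr
    return float(best_thr)
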