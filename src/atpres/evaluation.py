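"""Threshold-dependent criteria, ROC/AUC, and the per-chain probability plot.

The threshold-dependent criteria are the four standard confusion-matrix
summaries:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    Sen = TP / (TP + FN)            Spe = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a denominator factor vanishes, so
comparisons stay total on degenerate predictions.  The ROC curve sweeps all
distinct thresholds; AUC is the trapezoidal area, which with half-credit
ties equals the normalized Mann-Whitney rank statistic.  Because binding
residues are rare (roughly 25 nonbinding per binding residue), AUC and MCC
are the headline criteria — accuracy saturates near the class prior.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from sklearn.metrics import roc_curve  # noqa: E402


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Full evaluation of one probability track at one threshold."""

    threshold: float
    counts: ConfusionCounts
    acc: float
    sen: float
    spe: float
    mcc: float
    auc: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("counts"))
        return d


def confusion(labels: np.ndarray, binary_preds: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(binary_preds).astype(int)
    if labels.shape != preds.shape:
        raise ValueError(
            f"shape mismatch: {labels.shape} labels vs {preds.shape} preds"
        )
    return ConfusionCounts(
        tp=int(((labels == 1) & (preds == 1)).sum()),
        tn=int(((labels == 0) & (preds == 0)).sum()),
        fp=int(((labels == 0) & (preds == 1)).sum()),
        fn=int(((labels == 1) & (preds == 0)).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """ACC, sensitivity, specificity and MCC from confusion counts."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spe = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"acc": acc, "sen": sen, "spe": spe, "mcc": float(mcc)}


def roc_auc(
    labels: np.ndarray, probability_track: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """ROC swept over all distinct thresholds; trapezoidal AUC.

    Tied probabilities straddling the classes contribute half credit, the
    rank-statistic convention.  Raises on single-class labels.
    """
    labels = np.asarray(labels).astype(int)
    track = np.asarray(probability_track, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: labels contain a single class")
    fpr, tpr, thresholds = roc_curve(labels, track)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame(
        {"threshold": thresholds, "fpr": fpr, "tpr": tpr}
    )
    return auc, points


def evaluate_track(
    labels: np.ndarray, probability_track: np.ndarray, threshold: float,
    binary_override: np.ndarray | None = None,
) -> MetricsReport:
    """Score a probability track at a threshold.

    ``binary_override`` substitutes the thresholded calls (used for the
    template-OR-combined final prediction) while AUC still reflects the
    underlying probabilities.
    """
    labels = np.asarray(labels).astype(int)
    track = np.asarray(probability_track, dtype=float)
    preds = (
        np.asarray(binary_override).astype(int)
        if binary_override is not None
        else (track > threshold).astype(int)
    )
    counts = confusion(labels, preds)
    metrics = metrics_from_confusion(counts)
    auc, _ = roc_auc(labels, track)
    return MetricsReport(
        threshold=float(threshold), counts=counts, auc=auc, **metrics
    )


def write_metrics_tsv(report: MetricsReport, path: str | Path) -> None:
    d = report.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join(
            f"{v:.6f}" if isinstance(v, float) else str(v)
            for v in d.values()
        ) + "\n")


def plot_probability_tracks(
    chain,
    tracks: dict[str, np.ndarray],
    true_labels: np.ndarray | None,
    calls: np.ndarray | None,
    path: str | Path,
) -> None:
    """Per-residue probability lines with dots at predicted/true positions.

    One line per supplied track (subclassifiers and ensemble); pink dots on
    true binding residues, slate-gray dots on the final calls.
    """
    fig, ax = plt.subplots(figsize=(10, 3.2))
    n = len(chain.sequence)
    x = np.arange(1, n + 1)
    for name, track in tracks.items():
        track = np.asarray(track, dtype=float)
        if track.shape != (n,):
            raise ValueError(
                f"track {name!r} has length {track.size}, chain has {n}"
            )
        ax.plot(x, track, label=name, linewidth=1)
    if true_labels is not None:
        pos = x[np.asarray(true_labels).astype(bool)]
        ax.scatter(pos, np.full(pos.shape, 1.04), s=12, color="pink",
                   label="true binding", zorder=3)
    if calls is not None:
        pos = x[np.asarray(calls).astype(bool)]
        ax.scatter(pos, np.full(pos.shape, 1.10), s=12, color="slategray",
                   label="final call", zorder=3)
    ax.set_xlabel(f"residue position ({chain.chain_id})")
    ax.set_ylabel("P(ATP-binding)")
    ax.set_ylim(-0.05, 1.2)
    ax.legend(fontsize=7, ncol=3, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
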