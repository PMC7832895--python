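"""The two multi-stream convolutional subclassifiers.

Both networks take the three per-residue feature windows as *separate*
input streams — the evolutionary-profile window (17 x 20), the predicted
secondary-structure window (17 x 3) and the physicochemical one-hot window
(17 x 7), each as a single-channel 2-D map — extract deep representations
per stream, and merge them in a dense head with a 2-way softmax:

* **multi-IncepResNet** — profile and one-hot streams pass through two
  stacked Inception blocks with a concatenating shortcut that carries the
  (width-projected) stream input alongside the block output; the low-
  dimensional secondary-structure stream gets a single Inception block.
* **multi-Xception** — profile and one-hot streams use an entry pointwise
  convolution followed by six depthwise-separable convolution layers
  grouped into three identity-residual units; the secondary-structure
  stream uses two separable layers without residuals.  Streams are
  flattened rather than globally pooled: pooling would discard *where* in
  the window a feature sits, and the window's centre position is exactly
  what per-residue classification keys on.

Class imbalance (about 25 nonbinding residues per binding residue) is
handled by weighting the cross-entropy: class c gets weight
N / (l * n_c) with l = 2 classes, so rare binding residues count more.
Training uses Adam at 1e-4, batch 256, at most 60 epochs, dropout 0.4 and
early stopping on a 10% stratified validation split with patience 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn
from .features import WindowedDataset

logger = logging.getLogger("atpres")

EPSILON = 1e-7  # probability clip for the standalone loss


@dataclass
class TrainingConfig:
    """Training regime of the convolutional subclassifiers."""

    optimizer_name: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 60
    dropout_rate: float = 0.4
    early_stop_patience: int = 8
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        for name in ("learning_rate", "batch_size", "max_epochs",
                     "dropout_rate", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NetworkSpec:
    """Architecture widths; defaults are this package's CPU-scale choices.

    ``branch_filters`` is the per-branch width of each Inception block and
    the channel width of the Xception streams (the canonical Inception value
    of 32 is reachable but slow without hardware acceleration).
    """

    branch_filters: int = 8
    head_units: int = 128
    dropout_rate: float = 0.4
    window: int = 17
    stream_widths: tuple[int, int, int] = (20, 3, 7)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class loss weights W_c = N / (l * n_c), l = number of classes (2).

    The weights satisfy sum_c W_c * n_c = N, so balanced labels give weight
    1 to both classes while the rare class is up-weighted in proportion to
    its scarcity.
    """
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if (counts == 0).any():
        raise ValueError(
            "class weights undefined: a class is absent from the labels"
        )
    n, l = labels.size, 2
    return n / (l * counts.astype(float))


def weighted_cross_entropy(
    y_true: np.ndarray, y_pred_probs: np.ndarray, weights: np.ndarray
) -> float:
    """Sum over samples of W(class_i) * (-sum_l y_il log p_il).

    ``y_true`` may be integer labels or one-hot rows; probabilities are
    clipped to [1e-7, 1 - 1e-7] before the log.
    """
    y_pred_probs = np.asarray(y_pred_probs, dtype=float)
    y_true = np.asarray(y_true)
    if y_true.ndim == 1:
        onehot = np.zeros_like(y_pred_probs)
        onehot[np.arange(y_true.size), y_true.astype(int)] = 1.0
        y_true = onehot
    if y_true.shape != y_pred_probs.shape:
        raise ValueError(
            f"shape mismatch: labels {y_true.shape} vs "
            f"probabilities {y_pred_probs.shape}"
        )
    probs = np.clip(y_pred_probs, EPSILON, 1.0 - EPSILON)
    per_sample = -(y_true * np.log(probs)).sum(axis=1)
    w = np.asarray(weights, dtype=float)[y_true.argmax(axis=1)]
    return float((w * per_sample).sum())


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


def _conv_bn_relu(in_ch, out_ch, kh, kw, rng):
    return [
        nn.Conv2D(in_ch, out_ch, kh, kw, rng),
        nn.BatchNorm(out_ch),
        nn.ReLU(),
    ]


def _inception_block(in_ch: int, f: int, rng) -> nn.Parallel:
    """Four parallel branches: 1x1 | 1x1->3x3 | 1x1->5x5 | pool->1x1.

    Each branch ends at ``f`` channels; outputs are channel-concatenated to
    4f.  Batch normalization follows every convolution.
    """
    return nn.Parallel(
        [
            nn.Sequential(_conv_bn_relu(in_ch, f, 1, 1, rng)),
            nn.Sequential(
                _conv_bn_relu(in_ch, f, 1, 1, rng)
                + _conv_bn_relu(f, f, 3, 3, rng)
            ),
            nn.Sequential(
                _conv_bn_relu(in_ch, f, 1, 1, rng)
                + _conv_bn_relu(f, f, 5, 5, rng)
            ),
            nn.Sequential(
                [nn.MaxPool2D(3)] + _conv_bn_relu(in_ch, f, 1, 1, rng)
            ),
        ]
    )


def _separable(in_ch, out_ch, rng):
    """Depthwise 3x3 then pointwise 1x1, batch-normalized, ReLU."""
    return [
        nn.DepthwiseConv2D(in_ch, 3, 3, rng),
        nn.BatchNorm(in_ch),
        nn.Conv2D(in_ch, out_ch, 1, 1, rng),
        nn.BatchNorm(out_ch),
        nn.ReLU(),
    ]


class CNNModel:
    """A trained (or trainable) multi-stream network plus its metadata."""

    def __init__(self, net: nn.MultiStreamNet, spec: NetworkSpec, name: str,
                 rng: np.random.Generator):
        self.net = net
        self.spec = spec
        self.name = name
        self.rng = rng
        self.history: dict[str, list[float]] = {}

    def n_params(self) -> int:
        return self.net.n_params()

    def forward_logits(self, inputs, training=False):
        return self.net.forward(inputs, training)

    @staticmethod
    def _inputs_from(dataset: WindowedDataset, idx=None):
        sl = slice(None) if idx is None else idx
        return [
            dataset.w_pssm[sl][..., None].astype(nn.DTYPE),
            dataset.w_ss[sl][..., None].astype(nn.DTYPE),
            dataset.w_onehot[sl][..., None].astype(nn.DTYPE),
        ]

    def predict_proba(self, dataset: WindowedDataset,
                      batch_size: int = 1024) -> np.ndarray:
        """Positive-class probability per residue, aligned to the dataset."""
        out = np.empty(len(dataset))
        for start in range(0, len(dataset), batch_size):
            idx = slice(start, start + batch_size)
            logits = self.net.forward(self._inputs_from(dataset, idx), False)
            out[idx] = nn.softmax(logits)[:, 1]
        return out

    def save(self, path: str | Path) -> None:
        state = self.net.get_state()
        np.savez_compressed(
            path,
            **{f"arr_{i}": a for i, a in enumerate(state)},
            meta=np.array(
                [self.name, self.spec.branch_filters, self.spec.head_units,
                 self.spec.window], dtype=object
            ),
        )

    def load_weights(self, path: str | Path) -> None:
        data = np.load(path, allow_pickle=True)
        n = len([k for k in data.files if k.startswith("arr_")])
        self.net.set_state([data[f"arr_{i}"] for i in range(n)])


def build_multi_incepresnet(
    spec: NetworkSpec | None = None, seed: int = 0
) -> CNNModel:
    """Construct the multi-IncepResNet: stacked Inception blocks with a
    concatenating shortcut on the wide streams, one block on the SS stream,
    flattened streams, dense head, 2-way softmax."""
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    f = spec.branch_filters
    h = spec.window

    def wide_stream():
        body = nn.Sequential(
            [_inception_block(1, f, rng), _inception_block(4 * f, f, rng)]
        )
        shortcut = nn.Sequential(_conv_bn_relu(1, 4 * f, 1, 1, rng))
        return nn.Sequential([nn.ConcatShortcut(body, shortcut), nn.Flatten()])

    streams = [wide_stream(),
               nn.Sequential([_inception_block(1, f, rng), nn.Flatten()]),
               wide_stream()]
    # flat widths: wide streams end at 8f channels, the SS stream at 4f
    w_pssm, w_ss, w_onehot = spec.stream_widths
    feat_dim = h * w_pssm * 8 * f + h * w_ss * 4 * f + h * w_onehot * 8 * f
    head = nn.Sequential(
        [
            nn.Dense(feat_dim, spec.head_units, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout_rate, rng),
            nn.Dense(spec.head_units, 2, rng),
        ]
    )
    return CNNModel(nn.MultiStreamNet(streams, head), spec, "incepres", rng)


def build_multi_xception(
    spec: NetworkSpec | None = None, seed: int = 0
) -> CNNModel:
    """Construct the multi-Xception: entry pointwise conv then six separable
    conv layers in three identity-residual units on the wide streams, two
    separable layers on the SS stream, global average pooling, dense head."""
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    f = spec.branch_filters

    def wide_stream():
        layers = _conv_bn_relu(1, f, 1, 1, rng)
        for _ in range(3):  # three residual units, two separable layers each
            body = nn.Sequential(_separable(f, f, rng) + _separable(f, f, rng))
            layers.append(nn.AddShortcut(body))
            layers.append(nn.ReLU())
        layers.append(nn.Flatten())
        return nn.Sequential(layers)

    ss_stream = nn.Sequential(
        _separable(1, f, rng) + _separable(f, f, rng) + [nn.Flatten()]
    )
    streams = [wide_stream(), ss_stream, wide_stream()]
    w_pssm, w_ss, w_onehot = spec.stream_widths
    feat_dim = spec.window * (w_pssm + w_ss + w_onehot) * f
    head = nn.Sequential(
        [
            nn.Dense(feat_dim, spec.head_units, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout_rate, rng),
            nn.Dense(spec.head_units, 2, rng),
        ]
    )
    return CNNModel(nn.MultiStreamNet(streams, head), spec, "xception", rng)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    model: CNNModel,
    dataset: WindowedDataset,
    config: TrainingConfig | None = None,
) -> CNNModel:
    """Fit a subclassifier with the imbalance-aware regime.

    Class weights come from the training labels; the loss is the weighted
    cross-entropy.  A stratified ``validation_fraction`` split monitors the
    validation loss for early stopping (patience epochs without improvement,
    best weights restored).  History (epoch, train_loss, val_loss) is kept
    on ``model.history``.
    """
    config = config or TrainingConfig()
    if dataset.labels is None:
        raise ValueError("training requires a labeled dataset")
    labels = np.asarray(dataset.labels, dtype=int)
    weights = class_weights(labels)  # raises if a class is absent

    idx_train, idx_val = train_test_split(
        np.arange(len(dataset)),
        test_size=config.validation_fraction,
        stratify=labels,
        random_state=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    loss_fn = nn.WeightedSoftmaxCE(weights)
    optimizer = nn.Adam(model.net.params(), lr=config.learning_rate)

    best_val = np.inf
    best_state = None
    patience_left = config.early_stop_patience
    history = {"epoch": [], "train_loss": [], "val_loss": []}

    val_inputs = model._inputs_from(dataset, idx_val)
    val_labels = labels[idx_val]

    for epoch in range(config.max_epochs):
        order = rng.permutation(idx_train)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            logits = model.net.forward(
                model._inputs_from(dataset, batch), True
            )
            loss = loss_fn.forward(logits, labels[batch])
            model.net.backward(loss_fn.backward())
            optimizer.step(model.net.grads())
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)

        val_logits = model.net.forward(val_inputs, False)
        val_loss = loss_fn.forward(val_logits, val_labels)

        history["epoch"].append(epoch + 1)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        logger.debug(
            "%s epoch %d: train %.4f val %.4f",
            model.name, epoch + 1, train_loss, val_loss,
        )

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.net.get_state()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info(
                    "%s: early stop at epoch %d (best val %.4f)",
                    model.name, epoch + 1, best_val,
                )
                break

    if best_state is not None:
        model.net.set_state(best_state)
    model.history = history
    return model


def write_history_tsv(model: CNNModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\n")
        for e, t, v in zip(
            model.history["epoch"],
            model.history["train_loss"],
            model.history["val_loss"],
        ):
            fh.write(f"{e}\t{t:.6f}\t{v:.6f}\n")


def predict_proba(model: CNNModel, dataset: WindowedDataset) -> np.ndarray:
    """Positive-class probability per residue (thin alias on the model)."""
    return model.predict_proba(dataset)
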