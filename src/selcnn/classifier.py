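"""The codon-aware convolutional classifier: model spec, training, results.

The public surface follows the model/results idiom of statistical modelling
packages: ``SelectionCNN`` is constructed from encoded training examples and
a ``ModelSpec``; ``fit()`` performs the full training run and returns a
``SelectionCNNResults`` object carrying the learned network, the per-epoch
history, and prediction/evaluation/saliency methods.

Architecture (defaults): seven convolutional layers with ReLU activation,
batch normalization, dropout (p = 0.5) and width-2 average pooling; the first
convolution is an n x 3 filter applied with stride 3 so each position sees
one codon column across all taxa, later convolutions are width-3 same-padded
over codon columns.  Global average pooling condenses the feature maps, a
ReLU dense layer follows, and a single sigmoid unit emits the score
Z in [0, 1].  Training minimizes binary cross-entropy with Adam
(learning rate 0.001), batches of 512 alignments zero-padded to the longest
member, reshuffled every epoch, for 50 epochs with a 5% validation split —
no early stopping; the epoch-`epochs` model is the final model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoding import EncodedExample, make_batches, pad_batch, read_records

DEFAULT_FILTERS = (32, 32, 64, 64, 128, 128, 256)


class DegenerateDataError(ValueError):
    """Training data containing a single class cannot be fit."""


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters."""

    n_taxa: int = 8
    conv_filters: tuple[int, ...] = DEFAULT_FILTERS
    kernel_width: int = 3  # later-layer kernel width, in codon columns
    pool_width: int = 2
    dense_width: int = 64
    dropout: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 512
    epochs: int = 50
    validation_fraction: float = 0.05
    shuffle_rows: bool = False  # permute MSA rows per epoch (tree-info ablation)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ValueError("at least one convolutional layer is required")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.conv_filters) < 1 or self.dense_width < 1 or self.pool_width < 1:
            raise ValueError("all layer widths must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation fraction must lie in [0, 1)")

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_filters)


def build_model(spec: ModelSpec, rng: np.random.Generator | None = None) -> nn.Network:
    """Instantiate the untrained network with Glorot-uniform weights."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    layers: list[nn.Layer] = []
    in_ch = None
    for i, f in enumerate(spec.conv_filters):
        if i == 0:
            layers.append(nn.CodonConv(spec.n_taxa, f, rng))
        else:
            layers.append(nn.Conv1D(in_ch, f, rng, kernel_width=spec.kernel_width))
        layers.append(nn.ReLU())
        layers.append(nn.BatchNorm(f))
        layers.append(nn.Dropout(spec.dropout, dropout_rng))
        layers.append(nn.AvgPool(spec.pool_width))
        in_ch = f
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(in_ch, spec.dense_width, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(spec.dense_width, 1, rng))
    return nn.Network(layers)


def predict(
    model: nn.Network, examples: Sequence[EncodedExample], batch_size: int = 64
) -> np.ndarray:
    """Order-preserving scores in [0, 1]; dropout off, batch-norm frozen.

    Examples are bucketed by alignment length so no zero-padding enters at
    inference time; scores are therefore independent of how the example set
    is partitioned into batches.
    """
    scores = np.empty(len(examples))
    by_length: dict[int, list[int]] = {}
    for i, ex in enumerate(examples):
        by_length.setdefault(ex.length, []).append(i)
    for indices in by_length.values():
        for start in range(0, len(indices), batch_size):
            chunk = indices[start : start + batch_size]
            batch = pad_batch([examples[i] for i in chunk])
            scores[chunk] = model.forward(batch.tensors, train=False)
    return scores


def _epoch_metrics(model: nn.Network, examples, batch_size) -> tuple[float, float]:
    scores = predict(model, examples, batch_size=batch_size)
    y = np.array([e.label for e in examples], dtype=float)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(scores + eps) + (1 - y) * np.log(1 - scores + eps)))
    acc = float(np.mean((scores >= 0.5) == (y == 1)))
    return loss, acc


def train(
    model: nn.Network,
    examples: Sequence[EncodedExample],
    spec: ModelSpec,
    seed: int = 0,
    verbose: bool = False,
) -> list[dict]:
    """Train in place; returns the per-epoch history.

    The data are split once (seeded shuffle) into training and validation
    subsets by ``spec.validation_fraction``; each epoch is one reshuffled
    full pass over the training subset.
    """
    labels = {e.label for e in examples}
    if labels != {0, 1}:
        raise DegenerateDataError(
            f"training data must contain both classes, found labels {sorted(labels)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    n_val = int(round(spec.validation_fraction * len(examples)))
    val = [examples[i] for i in order[:n_val]]
    tr = [examples[i] for i in order[n_val:]]
    if {e.label for e in tr} != {0, 1}:
        raise DegenerateDataError("training split contains a single class")

    optimizer = nn.Adam(lr=spec.learning_rate)
    history: list[dict] = []
    for epoch in range(spec.epochs):
        losses = []
        for batch in make_batches(
            tr, batch_size=spec.batch_size,
            shuffle_rows_flag=spec.shuffle_rows, rng=rng,
        ):
            losses.append(model.train_step(batch.tensors, batch.labels, optimizer))
        row = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        tr_loss, tr_acc = _epoch_metrics(model, tr, spec.batch_size)
        row["train_loss_eval"], row["train_accuracy"] = tr_loss, tr_acc
        if val:
            val_loss, val_acc = _epoch_metrics(model, val, spec.batch_size)
            row["val_loss"], row["val_accuracy"] = val_loss, val_acc
        history.append(row)
        if verbose:
            print(
                "epoch {epoch}: train_loss={train_loss:.4f} "
                "train_acc={train_accuracy:.3f}".format(**row)
                + (f" val_acc={row['val_accuracy']:.3f}" if val else "")
            )
    return history


class SelectionCNN:
    """Model object: encoded training alignments plus an architecture spec."""

    def __init__(self, examples: Sequence[EncodedExample], spec: ModelSpec | None = None):
        self.examples = list(examples)
        self.spec = spec if spec is not None else ModelSpec()

    @classmethod
    def from_records(cls, path: str | Path, spec: ModelSpec | None = None) -> "SelectionCNN":
        return cls(list(read_records(path)), spec=spec)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "SelectionCNNResults":
        seed = self.spec.seed if seed is None else seed
        network = build_model(self.spec, rng=np.random.default_rng(seed))
        history = train(network, self.examples, self.spec, seed=seed, verbose=verbose)
        return SelectionCNNResults(
            network=network, spec=self.spec, history=history, seed=seed,
            n_train=len(self.examples),
        )


@dataclass
class SelectionCNNResults:
    """Fitted classifier: learned weights, history, and inference methods."""

    network: nn.Network
    spec: ModelSpec
    history: list[dict]
    seed: int = 0
    n_train: int = 0

    def predict(self, examples: Sequence[EncodedExample], batch_size: int = 64) -> np.ndarray:
        return predict(self.network, examples, batch_size=batch_size)

    def evaluate(self, examples: Sequence[EncodedExample], threshold: float = 0.5):
        from .metrics import compute_report

        scores = self.predict(examples)
        truth = np.array([e.label for e in examples])
        return compute_report(scores, truth, threshold=threshold)

    def saliency(self, example: EncodedExample):
        from .saliency import saliency_map

        return saliency_map(self.network, example)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        lines = [
            "Positive-selection CNN classifier",
            "=" * 44,
            f"taxa rows (n):        {self.spec.n_taxa}",
            f"conv layers:          {self.spec.n_conv_layers} "
            f"(filters {list(self.spec.conv_filters)})",
            f"dropout:              {self.spec.dropout}",
            f"dense width:          {self.spec.dense_width}",
            f"parameters:           {sum(p.value.size for p in self.network.params())}",
            f"training examples:    {self.n_train}",
            f"epochs:               {len(self.history)}",
            f"batch size:           {self.spec.batch_size}",
            f"learning rate:        {self.spec.learning_rate}",
            f"seed:                 {self.seed}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(f"final train loss:     {last['train_loss']:.4f}")
            lines.append(f"final train accuracy: {last['train_accuracy']:.3f}")
            if "val_accuracy" in last:
                lines.append(f"final val accuracy:   {last['val_accuracy']:.3f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.network.state_arrays()
        meta = {
            "spec": {**asdict(self.spec), "conv_filters": list(self.spec.conv_filters)},
            "history": self.history,
            "seed": self.seed,
            "n_train": self.n_train,
        }
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                **state,
            )

    @classmethod
    def load(cls, path: str | Path) -> "SelectionCNNResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            spec_dict = meta["spec"]
            spec_dict["conv_filters"] = tuple(spec_dict["conv_filters"])
            spec = ModelSpec(**spec_dict)
            network = build_model(spec)
            network.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        return cls(network=network, spec=spec, history=meta["history"],
                   seed=meta["seed"], n_train=meta["n_train"])
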