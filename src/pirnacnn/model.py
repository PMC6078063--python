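"""The convolutional classifier: architecture, training, persistence.

The network is deliberately small — the input is only a 4x341 matrix
and overfitting is the main risk: two valid 2x2 convolution layers of
32 filters each, one 2x2 max-pool, dropout 0.25, a 512-unit dense
layer with dropout 0.50, and a 2-unit softmax output.  Labels are
one-hot: [0, 1] = piRNA, [1, 0] = non-piRNA.

Training minimizes categorical cross-entropy with Adam at framework
defaults, batch size 32, and early stopping: if the loss monitored on
the held-out fold has not decreased for 10 consecutive epochs, training
stops and the best-epoch weights are restored.  Model selection and
reporting use stratified 10-fold cross validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from pirnacnn import nn
from pirnacnn.errors import DataError, ModelVersionError, TrainingError
from pirnacnn.evaluate import AggregateReport, ConfusionCounts, MetricsReport, aggregate, metrics
from pirnacnn.features import build_catalog, featurize_many
from pirnacnn.seqio import PredictionRecord, SmallRNASequence

#: index of the piRNA component in the softmax output ([0,1] = piRNA)
PIRNA_INDEX = 1
PIRNA_ONEHOT = (0, 1)
NONPIRNA_ONEHOT = (1, 0)

#: tolerated deviation of the positive-class fraction from 0.5
BALANCE_TOLERANCE = 0.05


@dataclass(frozen=True)
class CNNArchitecture:
    """Hyperparameters of the fixed network topology."""

    input_shape: tuple = (4, 341, 1)
    conv_layers: int = 2
    filters: int = 32
    kernel: tuple = (2, 2)
    pool: tuple = (2, 2)
    dropout_after_pool: float = 0.25
    dense_units: int = 512
    dropout_after_dense: float = 0.50
    n_classes: int = 2

    def shape_trace(self) -> list[tuple]:
        """Per-layer output shapes under valid padding / floor pooling."""
        h, w = self.input_shape[:2]
        trace: list[tuple] = []
        for _ in range(self.conv_layers):
            h, w = nn.conv_output_shape((h, w), self.kernel)
            trace.append((h, w, self.filters))
        h, w = nn.pool_output_shape((h, w), self.pool)
        trace.append((h, w, self.filters))
        flat = h * w * self.filters
        trace.extend([(flat,), (self.dense_units,), (self.n_classes,)])
        return trace


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol parameters.

    batch_size 32, 10 folds and patience 10 are the protocol constants;
    max_epochs is a safety cap — early stopping governs in practice.
    """

    batch_size: int = 32
    folds: int = 10
    early_stop_patience: int = 10
    max_epochs: int = 200
    seed: int = 0


@dataclass(frozen=True)
class LabeledExample:
    """A feature matrix with its one-hot class label."""

    matrix: np.ndarray
    label: tuple

    def __post_init__(self) -> None:
        if tuple(self.label) not in (PIRNA_ONEHOT, NONPIRNA_ONEHOT):
            raise ValueError(f"label must be {PIRNA_ONEHOT} or {NONPIRNA_ONEHOT}")


@dataclass
class TrainingLog:
    """Per-epoch losses and the early-stopping outcome."""

    rows: list = field(default_factory=list)  # (epoch, train_loss, monitor_loss)
    best_epoch: int = 0
    best_monitor_loss: float = float("inf")
    stopped_epoch: int = 0
    wait_at_stop: int = 0
    stopped_early: bool = False

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("epoch,train_loss,monitor_loss\n")
            for epoch, train_loss, monitor_loss in self.rows:
                handle.write(f"{epoch},{train_loss:.6f},{monitor_loss:.6f}\n")


@dataclass
class TrainedModel:
    """A fitted network plus the metadata needed to apply it safely."""

    network: nn.Network
    catalog_fingerprint: str
    metadata: dict = field(default_factory=dict)

    @property
    def architecture(self) -> CNNArchitecture:
        return self.network.arch


def make_examples(
    positives: Sequence[SmallRNASequence],
    negatives: Sequence[SmallRNASequence],
) -> list[LabeledExample]:
    """Featurize labelled sequences into training examples."""
    examples = [LabeledExample(m, PIRNA_ONEHOT) for m in featurize_many(positives)]
    examples += [LabeledExample(m, NONPIRNA_ONEHOT) for m in featurize_many(negatives)]
    return examples


def _stack(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([e.matrix for e in examples]).astype(np.float32)
    y = np.array([e.label for e in examples], dtype=np.float32)
    return x, y


def _check_balance(y: np.ndarray, what: str) -> None:
    frac = float(y[:, PIRNA_INDEX].mean())
    if abs(frac - 0.5) > BALANCE_TOLERANCE:
        raise DataError(
            f"{what} set is label-unbalanced: piRNA fraction {frac:.3f} "
            f"outside [{0.5 - BALANCE_TOLERANCE}, {0.5 + BALANCE_TOLERANCE}]"
        )


def build_network(arch: CNNArchitecture | None = None, seed: int = 0) -> nn.Network:
    """Instantiate an untrained network with seeded initialization."""
    return nn.Network(arch or CNNArchitecture(), seed)


def _fold_counts(probs: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    called = probs[:, PIRNA_INDEX] >= threshold
    truth = y[:, PIRNA_INDEX] == 1
    return ConfusionCounts(
        tp=int(np.sum(called & truth)),
        fp=int(np.sum(called & ~truth)),
        tn=int(np.sum(~called & ~truth)),
        fn=int(np.sum(~called & truth)),
    )


def train_fold(
    train: Sequence[LabeledExample],
    heldout: Sequence[LabeledExample],
    config: TrainingConfig,
    arch: CNNArchitecture | None = None,
    check_balance: bool = True,
) -> tuple[TrainedModel, MetricsReport, TrainingLog]:
    """Train one network on ``train``, monitoring loss on ``heldout``.

    Stops when the monitored loss has not improved for
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``)
    and restores the best-epoch weights.  Returns the fitted model,
    metrics on the held-out set, and the epoch log.
    """
    if not train or not heldout:
        raise DataError("train and heldout sets must be non-empty")
    x_train, y_train = _stack(train)
    x_val, y_val = _stack(heldout)
    if check_balance:
        _check_balance(y_train, "training")
        _check_balance(y_val, "held-out")

    arch = arch or CNNArchitecture()
    seeds = np.random.SeedSequence(config.seed).generate_state(3)
    network = build_network(arch, seed=int(seeds[0]))
    shuffle_rng = np.random.default_rng(int(seeds[1]))
    drop_rng = np.random.default_rng(int(seeds[2]))
    optimizer = nn.Adam(network.params)

    log = TrainingLog()
    best_params = network.copy_params()
    wait = 0
    n = x_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = network.forward(x_train[idx], train=True, drop_rng=drop_rng)
            loss = nn.cross_entropy(probs, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training loss diverged (epoch {epoch}, batch at {start}): {loss}"
                )
            grads = network.backward(cache, y_train[idx])
            optimizer.step(network.params, grads)
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        monitor_loss = nn.cross_entropy(network.predict_proba(x_val), y_val)
        log.rows.append((epoch, train_loss, monitor_loss))
        if monitor_loss < log.best_monitor_loss:
            log.best_monitor_loss = monitor_loss
            log.best_epoch = epoch
            best_params = network.copy_params()
            wait = 0
        else:
            wait += 1
        log.stopped_epoch = epoch
        log.wait_at_stop = wait
        if wait >= config.early_stop_patience:
            log.stopped_early = True
            break

    network.set_params(best_params)
    report = metrics(_fold_counts(network.predict_proba(x_val), y_val))
    model = TrainedModel(
        network=network,
        catalog_fingerprint=build_catalog().fingerprint,
        metadata={
            "seed": config.seed,
            "best_epoch": log.best_epoch,
            "stopped_epoch": log.stopped_epoch,
            "stopped_early": log.stopped_early,
            "label_convention": {"piRNA": list(PIRNA_ONEHOT), "non-piRNA": list(NONPIRNA_ONEHOT)},
        },
    )
    return model, report, log


@dataclass
class CVResult:
    """Outcome of stratified k-fold cross validation."""

    fold_reports: list
    fold_counts: list
    logs: list
    summary: AggregateReport


def cross_validate(
    data: Sequence[LabeledExample],
    config: TrainingConfig,
    arch: CNNArchitecture | None = None,
) -> CVResult:
    """Stratified k-fold cross validation over labelled examples.

    Folds are disjoint, exhaustive and stratified by label; each fold's
    network trains on the other k-1 folds and is scored on the held-out
    fold.  Reports per-fold metrics and the Table-style mean ± sd.
    """
    if len(data) < 100:
        raise DataError(f"need at least 100 examples for cross validation, got {len(data)}")
    labels = np.array([e.label[PIRNA_INDEX] for e in data])
    if min(labels.sum(), len(labels) - labels.sum()) < config.folds:
        raise DataError("too few examples in one class to stratify")
    splitter = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=int(config.seed) % (2**31)
    )
    fold_reports: list[MetricsReport] = []
    fold_counts: list[ConfusionCounts] = []
    logs: list[TrainingLog] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(data)), labels)):
        fold_config = TrainingConfig(
            batch_size=config.batch_size,
            folds=config.folds,
            early_stop_patience=config.early_stop_patience,
            max_epochs=config.max_epochs,
            seed=(int(config.seed) * 1009 + fold) % (2**31),
        )
        model, report, log = train_fold(
            [data[i] for i in train_idx],
            [data[i] for i in test_idx],
            fold_config,
            arch,
        )
        x_val, y_val = _stack([data[i] for i in test_idx])
        fold_counts.append(_fold_counts(model.network.predict_proba(x_val), y_val))
        fold_reports.append(report)
        logs.append(log)
    summary = aggregate(fold_reports, fold_counts)
    return CVResult(fold_reports, fold_counts, logs, summary)


def predict(
    model: TrainedModel,
    seqs: Sequence[SmallRNASequence],
    threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Classify sequences; one record per input, order preserved."""
    if model.catalog_fingerprint != build_catalog().fingerprint:
        raise ModelVersionError(
            "model was trained under a different k-mer catalog ordering"
        )
    if not seqs:
        return []
    probs = model.network.predict_proba(featurize_many(seqs))
    return [
        PredictionRecord(seq.id, float(p[PIRNA_INDEX]), threshold)
        for seq, p in zip(seqs, probs)
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist weights + architecture + catalog fingerprint as one .npz."""
    meta = {
        "format_version": 1,
        "architecture": asdict(model.architecture),
        "init_seed": model.network.seed,
        "catalog_fingerprint": model.catalog_fingerprint,
        "metadata": model.metadata,
    }
    arrays = {f"param_{k}": v for k, v in model.network.params.items()}
    with open(path, "wb") as handle:  # np.savez would append ".npz" to a bare path
        np.savez(handle, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive; rejects catalog-fingerprint mismatches."""
    try:
        with np.load(path) as archive:
            meta = json.loads(archive["meta"].tobytes().decode())
            params = {
                k[len("param_"):]: archive[k] for k in archive.files if k.startswith("param_")
            }
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ModelVersionError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("catalog_fingerprint") != build_catalog().fingerprint:
        raise ModelVersionError(
            f"model file {path} was built under a different k-mer catalog ordering"
        )
    arch_fields = meta["architecture"]
    for key in ("input_shape", "kernel", "pool"):
        arch_fields[key] = tuple(arch_fields[key])
    network = build_network(CNNArchitecture(**arch_fields), seed=meta["init_seed"])
    network.set_params(params)
    return TrainedModel(network, meta["catalog_fingerprint"], meta.get("metadata", {}))
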