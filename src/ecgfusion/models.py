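"""The two dual-branch architectures and their training protocol.

Both networks pair a 1-D convolutional branch over the raw 12-lead signal
with a small dense branch over (age, sex), concatenate the branch features
and classify through a shared dense head with K-way softmax:

* ``custom_cnn`` — five conv blocks (32, 64, 128, 256, 512 filters, 3x1
  kernels, 2x1 max pooling, batch norm after each pool), flatten, dense
  [100, 32] with dropout 0.4;
* ``vgg_style`` — eight conv blocks (64, 64, 128, 128, 256, 256, 512, 512;
  pooling after every conv), global average pooling, dense [512, 512] with
  dropout 0.5.

The demographic branch is dense [100, 64, 32, 16] with dropout 0.4 in both;
the head is dense [10, 10, K] with dropout 0.2. Training uses categorical
cross-entropy, Adam at learning rate 0.001, batch size 16, at most 60
epochs, with early stopping, learning-rate reduction on plateau, and
restoration of the weights from the epoch of minimum validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    DualBranchNet,
    Flatten,
    GlobalAvgPool1D,
    MaxPool1D,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .records import ECGRecord
from .scenarios import LabeledDataset

logger = logging.getLogger(__name__)

ARCHITECTURES = {
    "custom_cnn": dict(
        conv_filters=(32, 64, 128, 256, 512),
        batch_norm=True,
        global_pool=False,
        ecg_dense=(100, 32),
        ecg_dropout=0.4,
    ),
    "vgg_style": dict(
        conv_filters=(64, 64, 128, 128, 256, 256, 512, 512),
        batch_norm=False,
        global_pool=True,
        ecg_dense=(512, 512),
        ecg_dropout=0.5,
    ),
}


@dataclass(frozen=True)
class ModelConfig:
    architecture: str
    input_length: int
    num_classes: int
    n_leads: int = 12
    kernel_size: int = 3
    pool_size: int = 2
    demo_dense: tuple[int, ...] = (100, 64, 32, 16)
    demo_dropout: float = 0.4
    head_dense: tuple[int, ...] = (10, 10)
    head_dropout: float = 0.2
    use_demographics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        n_pools = len(self.conv_filters)
        if self.input_length < self.pool_size ** n_pools:
            raise ValueError(
                f"input_length {self.input_length} too short for "
                f"{n_pools} pooling stages of size {self.pool_size}"
            )

    @property
    def _arch(self) -> dict:
        return ARCHITECTURES[self.architecture]

    @property
    def conv_filters(self) -> tuple[int, ...]:
        return self._arch["conv_filters"]

    @property
    def ecg_dense(self) -> tuple[int, ...]:
        return self._arch["ecg_dense"]

    @property
    def ecg_dropout(self) -> float:
        return self._arch["ecg_dropout"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 60
    batch_size: int = 16
    early_stopping_patience: int = 10
    min_delta: float = 1e-4
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 5
    lr_floor: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_model(config: ModelConfig) -> DualBranchNet:
    """Instantiate a dual-branch network from its configuration."""
    rng = np.random.default_rng(config.seed)
    arch = config._arch
    layers: list = []
    in_ch = config.n_leads
    length = config.input_length
    for f in config.conv_filters:
        layers += [
            Conv1D(in_ch, f, config.kernel_size, rng=rng),
            ReLU(),
            MaxPool1D(config.pool_size),
        ]
        if arch["batch_norm"]:
            layers.append(BatchNorm1D(f))
        in_ch = f
        length //= config.pool_size
    if arch["global_pool"]:
        layers.append(GlobalAvgPool1D())
        feat = in_ch
    else:
        layers.append(Flatten())
        feat = in_ch * length
    for units in config.ecg_dense:
        layers += [
            Dense(feat, units, rng=rng),
            ReLU(),
            Dropout(config.ecg_dropout),
        ]
        feat = units
    ecg_branch = Sequential(layers)

    demo_branch = None
    concat_dim = feat
    if config.use_demographics:
        dlayers: list = []
        d_in = 2  # age, sex
        for units in config.demo_dense:
            dlayers += [Dense(d_in, units, rng=rng), ReLU()]
            d_in = units
        dlayers.append(Dropout(config.demo_dropout))
        demo_branch = Sequential(dlayers)
        concat_dim = feat + d_in

    hlayers: list = []
    h_in = concat_dim
    for units in config.head_dense:
        hlayers += [
            Dense(h_in, units, rng=rng),
            ReLU(),
            Dropout(config.head_dropout),
        ]
        h_in = units
    hlayers.append(Dense(h_in, config.num_classes, rng=rng))
    head = Sequential(hlayers)

    model = DualBranchNet(ecg_branch, demo_branch, head)
    model.config = config
    return model


def architecture_summary(model: DualBranchNet) -> dict:
    """Structural introspection of a built network.

    Walks the realized layers (not the config) and reports the conv filter
    sequence, kernel/pool sizes, batch-norm placement, dense widths and
    dropout rates of every branch — the basis of the architecture audit.
    """
    from .nn.layers import (
        BatchNorm1D, Conv1D, Dense, Dropout, GlobalAvgPool1D, MaxPool1D,
    )

    def walk(layers):
        out = {
            "conv_filters": [], "kernel_sizes": [], "pool_sizes": [],
            "batch_norm_after_pool": [], "dense_units": [],
            "dropout_rates": [], "global_pool": False,
        }
        prev_pool = False
        for layer in layers:
            if isinstance(layer, Conv1D):
                out["conv_filters"].append(layer.out_channels)
                out["kernel_sizes"].append(layer.kernel_size)
            elif isinstance(layer, MaxPool1D):
                out["pool_sizes"].append(layer.pool_size)
                prev_pool = True
                continue
            elif isinstance(layer, BatchNorm1D):
                out["batch_norm_after_pool"].append(prev_pool)
            elif isinstance(layer, Dense):
                out["dense_units"].append(layer.out_features)
            elif isinstance(layer, Dropout):
                out["dropout_rates"].append(layer.rate)
            elif isinstance(layer, GlobalAvgPool1D):
                out["global_pool"] = True
            prev_pool = False
        return out

    summary = {"ecg_branch": walk(model.ecg_branch.layers),
               "head": walk(model.head.layers)}
    if model.demo_branch is not None:
        demo = walk(model.demo_branch.layers)
        demo["n_weights"] = int(
            sum(l.params[k].size for l, k in model.demo_branch.parameters())
        )
        summary["demo_branch"] = demo
    return summary


class DemographicScaler:
    """Age z-scoring + binary sex encoding, fitted on the training set only."""

    def __init__(self, impute_missing: bool = False) -> None:
        self.impute_missing = impute_missing
        self.age_mean: float | None = None
        self.age_sd: float | None = None
        self.age_median: float | None = None

    def fit(self, records: list[ECGRecord]) -> "DemographicScaler":
        ages = np.array([r.age for r in records if r.age is not None], dtype=float)
        if ages.size == 0:
            raise ValueError("no ages available to fit the demographic scaler")
        self.age_mean = float(ages.mean())
        self.age_sd = float(ages.std()) or 1.0
        self.age_median = float(np.median(ages))
        return self

    def transform(self, records: list[ECGRecord]) -> np.ndarray:
        if self.age_mean is None:
            raise ValueError("scaler is not fitted")
        out = np.empty((len(records), 2), dtype=np.float64)
        for i, r in enumerate(records):
            if r.age is None or r.sex is None:
                if not self.impute_missing:
                    raise ValueError(
                        f"record {r.record_id} lacks demographics; enable "
                        "impute_missing or exclude it upstream"
                    )
                age = self.age_median if r.age is None else r.age
                sex = 0.5 if r.sex is None else (1.0 if r.sex == "female" else 0.0)
            else:
                age = r.age
                sex = 1.0 if r.sex == "female" else 0.0
            out[i, 0] = (age - self.age_mean) / self.age_sd
            out[i, 1] = sex
        return out


def featurize(
    dataset: LabeledDataset, scaler: DemographicScaler | None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Stack a LabeledDataset into (X_ecg, X_demo, y) arrays."""
    recs = [r for r, _ in dataset.records]
    y = np.array([c for _, c in dataset.records], dtype=np.int64)
    X = np.stack([r.signal for r in recs]).astype(np.float32) if recs else (
        np.empty((0, 0, 12), dtype=np.float32)
    )
    X_demo = scaler.transform(recs).astype(np.float32) if scaler else None
    return X, X_demo, y


def _forward_proba(model: DualBranchNet, X, X_demo, chunk: int = 128) -> np.ndarray:
    k = model.config.num_classes
    out = np.empty((X.shape[0], k), dtype=np.float64)
    for i in range(0, X.shape[0], chunk):
        xd = X_demo[i:i + chunk] if X_demo is not None else None
        logits = model.forward(X[i:i + chunk], xd, train=False)
        out[i:i + chunk] = softmax(logits.astype(np.float64))
    return out


def predict_proba(
    model: DualBranchNet,
    records: list[ECGRecord],
    demographics: np.ndarray | None = None,
) -> np.ndarray:
    """Class probabilities for a batch of records; rows sum to 1.

    ``demographics`` is an (n, 2) encoded array; if omitted, the scaler
    fitted during training (``model.demo_scaler``) is applied.
    """
    k = model.config.num_classes
    if not records:
        return np.empty((0, k))
    X = np.stack([r.signal for r in records]).astype(np.float32)
    if X.shape[1] != model.config.input_length:
        raise ValueError(
            f"record length {X.shape[1]} != model input_length "
            f"{model.config.input_length}"
        )
    X_demo = None
    if model.use_demographics:
        if demographics is not None:
            X_demo = np.asarray(demographics, dtype=np.float32)
            if X_demo.shape != (len(records), 2):
                raise ValueError("demographics must be (n_records, 2)")
        else:
            scaler = getattr(model, "demo_scaler", None)
            if scaler is None:
                raise ValueError("model has no fitted demographic scaler")
            X_demo = scaler.transform(records).astype(np.float32)
    return _forward_proba(model, X, X_demo)


def _eval_loss_acc(model, X, X_demo, y) -> tuple[float, float]:
    p = _forward_proba(model, X, X_demo)
    onehot = np.eye(p.shape[1])[y]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / len(y))
    acc = float((p.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    model: DualBranchNet,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: TrainConfig,
    impute_missing_demographics: bool = False,
) -> dict[str, list]:
    """Fit the model; returns the per-epoch history.

    The returned model carries the weights of the epoch with minimum
    validation loss. Optimization: Adam on categorical cross-entropy with
    shuffled mini-batches; early stopping and learning-rate halving both
    watch the validation loss.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if train_set.scenario != val_set.scenario:
        raise ValueError("train and validation sets must share a scenario")
    k = model.config.num_classes
    if train_set.scenario.num_classes != k:
        raise ValueError("scenario class count does not match the model")
    present = {c for _, c in train_set.records}
    missing = set(range(k)) - present
    if missing:
        logger.warning("classes absent from training set: %s", sorted(missing))

    scaler = None
    if model.use_demographics:
        scaler = DemographicScaler(impute_missing=impute_missing_demographics)
        scaler.fit([r for r, _ in train_set.records])
        model.demo_scaler = scaler
    X, X_demo, y = featurize(train_set, scaler)
    Xv, Xv_demo, yv = featurize(val_set, scaler)
    onehot = np.eye(k, dtype=np.float32)[y]

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list] = {
        "epoch": [], "train_loss": [], "train_acc": [],
        "val_loss": [], "val_acc": [], "lr": [],
    }
    best_loss = np.inf  # strict minimum: drives the checkpoint
    plateau_loss = np.inf  # min_delta-gated: drives patience counters
    best_state = model.get_state()
    since_improve = 0
    since_lr = 0
    n = len(y)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            xd = X_demo[idx] if X_demo is not None else None
            logits = model.forward(X[idx], xd, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        val_loss, val_acc = _eval_loss_acc(model, Xv, Xv_demo, yv) if len(yv) else (
            float(np.mean(losses)), correct / n
        )
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
        if val_loss < plateau_loss - config.min_delta:
            plateau_loss = val_loss
            since_improve = 0
            since_lr = 0
        else:
            since_improve += 1
            since_lr += 1
        if since_lr >= config.lr_reduce_patience and opt.lr > config.lr_floor:
            opt.lr = max(opt.lr * config.lr_reduce_factor, config.lr_floor)
            since_lr = 0
        if since_improve >= config.early_stopping_patience:
            break
    model.set_state(best_state)
    model.best_val_loss = best_loss
    return history
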