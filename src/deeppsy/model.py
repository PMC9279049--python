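"""The DeepPsy fusion classifier.

Two branches trained jointly end to end:

* **trajectory branch** — each weekly 7x24 activity grid passes through
  conv(4, 3x3, same) - batchnorm - pool(2x2) - conv(32, 3x3, same) -
  batchnorm - pool(2x2) - fc(16) - dropout(0.5); the per-week vectors are
  linearly projected to width 64 and fed as a sequence to a 4-unit LSTM;
* **basic branch** — fc(8) - fc(4) over the engineered tabular features.

The branch outputs are concatenated, passed through a 4-neuron fusion
layer and a softmax output head (2 classes by default: MD vs none; a
4-class severity mode is supported). Training uses Adam (lr 1e-3),
batch size 4, 60 epochs, class-weighted cross-entropy, with dropout
active and batch statistics used only during training. Fixed seed and
batch order make runs bit-reproducible on one platform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .features import FEATURE_COLUMNS, build_feature_table, clean_cohort


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class DeepPsySpec:
    """Architecture and training hyperparameters of the fusion model."""

    conv1_kernels: int = 4
    conv2_kernels: int = 32
    ksize: int = 3
    fc_width: int = 16
    dropout: float = 0.5
    lstm_input: int = 64
    lstm_units: int = 4
    basic_widths: tuple = (8, 4)
    fusion_width: int = 4
    n_classes: int = 2
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 4
    use_trajectory: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if min(
            self.conv1_kernels,
            self.conv2_kernels,
            self.fc_width,
            self.lstm_units,
            self.fusion_width,
            self.n_classes,
            *self.basic_widths,
        ) < 1:
            raise ValueError("all layer widths must be positive")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


@dataclass
class TrainLog:
    """Per-epoch training and validation loss/accuracy."""

    epochs: list = field(default_factory=list)
    seed: int = 0
    spec_hash: str = ""

    def append(self, **kw):
        self.epochs.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


# ---------------------------------------------------------------------------
# input preparation


def activity_grid(record, n_days: int) -> np.ndarray:
    """Weekly day x hour activity grids for one student.

    Returns (n_weeks, 7, 24) with each cell the fraction of that hour
    spent online (minutes / 60, clipped to [0, 1]).
    """
    n_weeks = n_days // 7
    grid = np.zeros((n_weeks * 7, 24))
    for day, start, end in record.net_sessions:
        if day >= n_weeks * 7:
            continue
        for hour in range(int(start) // 60, min(int(end) // 60 + 1, 24)):
            lo, hi = hour * 60, (hour + 1) * 60
            overlap = min(end, hi) - max(start, lo)
            if overlap > 0:
                grid[day, hour] += overlap
    grid = np.clip(grid / 60.0, 0.0, 1.0)
    return grid.reshape(n_weeks, 7, 24)


def make_dataset(
    cohort: list,
    n_days: int,
    seed: int = 0,
    feature_columns=None,
    binary: bool = True,
) -> dict:
    """Assemble model inputs from a raw cohort.

    Returns a dict with ``grids`` (N, n_weeks, 7, 24), ``features``
    (N, d) raw (unstandardized), ``labels`` (N,), ``student_ids`` and
    ``feature_columns``.
    """
    cohort = clean_cohort(cohort)
    table = build_feature_table(cohort, n_days, seed=seed)
    cols = list(feature_columns) if feature_columns is not None else list(
        FEATURE_COLUMNS
    )
    grids = np.stack([activity_grid(r, n_days) for r in cohort])
    if binary:
        labels = table["label"].to_numpy()
    else:
        order = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
        labels = np.array([order[r.label] for r in cohort])
    return {
        "grids": grids,
        "features": table[cols].to_numpy(dtype=float),
        "labels": labels.astype(int),
        "student_ids": table["student_id"].tolist(),
        "feature_columns": cols,
    }


# ---------------------------------------------------------------------------
# model


class DeepPsy:
    """Built (untrained) fusion network for a given input geometry."""

    def __init__(self, spec: DeepPsySpec, grid_shape=(7, 24), n_features=6):
        self.spec = spec
        self.grid_shape = tuple(grid_shape)
        self.n_features = n_features
        rng = np.random.default_rng(spec.seed)
        h, w = grid_shape
        h2, w2 = -(-h // 2), -(-w // 2)
        h4, w4 = -(-h2 // 2), -(-w2 // 2)
        self._flat = spec.conv2_kernels * h4 * w4
        s = spec
        if s.use_trajectory:
            self.traj = {
                "conv1": nn.Conv2D(
                    1, s.conv1_kernels, s.ksize, "same", rng, input_layer=True
                ),
                "bn1": nn.BatchNorm2D(s.conv1_kernels),
                "relu1": nn.ReLU(),
                "pool1": nn.Pool2D(s.conv1_kernels),
                "conv2": nn.Conv2D(s.conv1_kernels, s.conv2_kernels, s.ksize, "same", rng),
                "bn2": nn.BatchNorm2D(s.conv2_kernels),
                "relu2": nn.ReLU(),
                "pool2": nn.Pool2D(s.conv2_kernels),
                "flatten": nn.Flatten(),
                "fc": nn.Dense(self._flat, s.fc_width, rng),
                "relu3": nn.ReLU(),
                "dropout": nn.Dropout(s.dropout, np.random.default_rng(s.seed + 7)),
                "proj": nn.Dense(s.fc_width, s.lstm_input, rng),
                "lstm": nn.LSTM(s.lstm_input, s.lstm_units, rng),
            }
        else:
            self.traj = {}
        w1, w2_ = s.basic_widths
        self.basic = {
            "fc1": nn.Dense(n_features, w1, rng),
            "relu1": nn.ReLU(),
            "fc2": nn.Dense(w1, w2_, rng),
            "relu2": nn.ReLU(),
        }
        fusion_in = w2_ + (s.lstm_units if s.use_trajectory else 0)
        self.head = {
            "fusion": nn.Dense(fusion_in, s.fusion_width, rng),
            "relu": nn.ReLU(),
            "out": nn.Dense(s.fusion_width, s.n_classes, rng),
        }
        self.loss_fn = nn.SoftmaxCrossEntropy()
        # feature standardization fitted on the training split
        self.feat_mean = np.zeros(n_features)
        self.feat_std = np.ones(n_features)

    # -- parameter plumbing -------------------------------------------------
    def trajectory_params(self):
        return [p for layer in self.traj.values() for p in layer.params]

    def basic_params(self):
        return [p for layer in self.basic.values() for p in layer.params]

    def head_params(self):
        return [p for layer in self.head.values() for p in layer.params]

    def params(self):
        return self.trajectory_params() + self.basic_params() + self.head_params()

    def param_count(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def _forward_traj(self, grids, train):
        n, wk = grids.shape[0], grids.shape[1]
        x = grids.reshape(n * wk, 1, *self.grid_shape)
        t = self.traj
        x = t["conv1"].forward(x, train)
        x = t["bn1"].forward(x, train)
        x = t["relu1"].forward(x, train)
        x = t["pool1"].forward(x, train)
        x = t["conv2"].forward(x, train)
        x = t["bn2"].forward(x, train)
        x = t["relu2"].forward(x, train)
        x = t["pool2"].forward(x, train)
        x = t["flatten"].forward(x, train)
        x = t["fc"].forward(x, train)
        x = t["relu3"].forward(x, train)
        x = t["dropout"].forward(x, train)
        x = t["proj"].forward(x, train)
        seq = x.reshape(n, wk, self.spec.lstm_input)
        return t["lstm"].forward(seq, train)

    def _backward_traj(self, dout):
        t = self.traj
        d = t["lstm"].backward(dout)
        n, wk, _ = d.shape
        d = d.reshape(n * wk, self.spec.lstm_input)
        d = t["proj"].backward(d)
        d = t["dropout"].backward(d)
        d = t["relu3"].backward(d)
        d = t["fc"].backward(d)
        d = t["flatten"].backward(d)
        d = t["pool2"].backward(d)
        d = t["relu2"].backward(d)
        d = t["bn2"].backward(d)
        d = t["conv2"].backward(d)
        d = t["pool1"].backward(d)
        d = t["relu1"].backward(d)
        d = t["bn1"].backward(d)
        t["conv1"].backward(d)

    def forward(self, grids, feats, train=False, zero_trajectory=False):
        z = (feats - self.feat_mean) / self.feat_std
        b = self.basic
        hb = b["relu2"].forward(
            b["fc2"].forward(b["relu1"].forward(b["fc1"].forward(z, train), train), train),
            train,
        )
        if self.spec.use_trajectory:
            ht = self._forward_traj(grids, train)
            if zero_trajectory:
                ht = np.zeros_like(ht)
            fused = np.concatenate([ht, hb], axis=1)
        else:
            fused = hb
        self._zero_traj = zero_trajectory
        h = self.head
        return h["out"].forward(
            h["relu"].forward(h["fusion"].forward(fused, train), train), train
        )

    def backward(self, dlogits):
        h = self.head
        d = h["fusion"].backward(h["relu"].backward(h["out"].backward(dlogits)))
        if self.spec.use_trajectory:
            k = self.spec.lstm_units
            dt, db = d[:, :k], d[:, k:]
            if not self._zero_traj:
                self._backward_traj(dt)
        else:
            db = d
        b = self.basic
        b["fc1"].backward(
            b["relu1"].backward(b["fc2"].backward(b["relu2"].backward(db)))
        )

    def predict_proba(self, grids, feats, zero_trajectory=False):
        logits = self.forward(grids, feats, train=False, zero_trajectory=zero_trajectory)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, grids, feats, zero_trajectory=False):
        return self.predict_proba(grids, feats, zero_trajectory).argmax(axis=1)


def save_model(model: DeepPsy, path) -> None:
    """Checkpoint: all parameters plus a self-describing header
    (spec JSON, spec hash, input geometry, feature standardization)."""
    import json as _json
    from pathlib import Path as _Path

    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    bn_state = {}
    for prefix, layers in (("traj", model.traj), ("basic", model.basic)):
        for name, layer in layers.items():
            if isinstance(layer, nn.BatchNorm2D):
                bn_state[f"{prefix}.{name}.mean"] = layer.running_mean
                bn_state[f"{prefix}.{name}.var"] = layer.running_var
    header = {
        "spec": asdict(model.spec),
        "spec_hash": model.spec.hash(),
        "grid_shape": list(model.grid_shape),
        "n_features": model.n_features,
    }
    np.savez(
        _Path(path),
        header=np.frombuffer(_json.dumps(header).encode(), dtype=np.uint8),
        feat_mean=model.feat_mean,
        feat_std=model.feat_std,
        **arrays,
        **bn_state,
    )


def load_model(path) -> DeepPsy:
    import json as _json

    with np.load(path) as data:
        header = _json.loads(bytes(data["header"]).decode())
        spec_d = header["spec"]
        spec_d["basic_widths"] = tuple(spec_d["basic_widths"])
        spec = DeepPsySpec(**spec_d)
        if spec.hash() != header["spec_hash"]:
            raise ValueError("checkpoint spec hash mismatch")
        model = DeepPsy(
            spec,
            grid_shape=tuple(header["grid_shape"]),
            n_features=header["n_features"],
        )
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for prefix, layers in (("traj", model.traj), ("basic", model.basic)):
            for name, layer in layers.items():
                key = f"{prefix}.{name}.mean"
                if isinstance(layer, nn.BatchNorm2D) and key in data:
                    layer.running_mean = data[key]
                    layer.running_var = data[f"{prefix}.{name}.var"]
        model.feat_mean = data["feat_mean"]
        model.feat_std = data["feat_std"]
    return model


def save_grids(grids: np.ndarray, path_prefix) -> None:
    """Dense grid array plus a JSON shape manifest."""
    import json as _json
    from pathlib import Path as _Path

    prefix = _Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), np.asarray(grids))
    manifest = {
        "shape": list(np.asarray(grids).shape),
        "axes": ["student", "week", "day_of_week", "hour"],
        "values": "fraction of hour online, in [0, 1]",
    }
    prefix.with_suffix(".json").write_text(_json.dumps(manifest, indent=2))


def load_grids(path_prefix) -> np.ndarray:
    from pathlib import Path as _Path

    return np.load(_Path(path_prefix).with_suffix(".npy"))


def deeppsy_param_count(spec: DeepPsySpec, grid_shape=(7, 24), n_features=6) -> int:
    """Closed-form layer-by-layer parameter count of the fusion model."""
    h, w = grid_shape
    h2, w2 = -(-h // 2), -(-w // 2)
    h4, w4 = -(-h2 // 2), -(-w2 // 2)
    k2 = spec.ksize**2
    n = 0
    if spec.use_trajectory:
        n += spec.conv1_kernels * k2 + spec.conv1_kernels  # conv1
        n += 2 * spec.conv1_kernels  # bn1 gamma/beta
        n += 2 * spec.conv1_kernels  # pool1 scale/bias
        n += spec.conv2_kernels * spec.conv1_kernels * k2 + spec.conv2_kernels
        n += 2 * spec.conv2_kernels  # bn2
        n += 2 * spec.conv2_kernels  # pool2
        flat = spec.conv2_kernels * h4 * w4
        n += flat * spec.fc_width + spec.fc_width  # fc
        n += spec.fc_width * spec.lstm_input + spec.lstm_input  # projection
        n += 4 * spec.lstm_units * (spec.lstm_input + spec.lstm_units + 1)  # lstm
    w1, w2_ = spec.basic_widths
    n += n_features * w1 + w1
    n += w1 * w2_ + w2_
    fusion_in = w2_ + (spec.lstm_units if spec.use_trajectory else 0)
    n += fusion_in * spec.fusion_width + spec.fusion_width
    n += spec.fusion_width * spec.n_classes + spec.n_classes
    return n


def build_deeppsy(spec: DeepPsySpec, grid_shape=(7, 24), n_features=6) -> DeepPsy:
    return DeepPsy(spec, grid_shape=grid_shape, n_features=n_features)


# ---------------------------------------------------------------------------
# training


def _eval(model, grids, feats, labels, class_weights):
    """One forward pass: (weighted loss, accuracy)."""
    logits = model.forward(grids, feats, train=False)
    loss, probs = model.loss_fn.forward(logits, labels, class_weights)
    acc = float((probs.argmax(axis=1) == labels).mean())
    return loss, acc


def train(
    model: DeepPsy,
    train_data: dict,
    val_data: dict = None,
    spec: DeepPsySpec = None,
) -> tuple:
    """Train the fusion model; returns (model, TrainLog).

    ``train_data`` / ``val_data`` carry ``grids``, ``features`` and
    ``labels``. Cross-entropy is weighted inversely to class frequency.
    Deterministic under the spec seed (fixed init, batch order and
    dropout stream).
    """
    spec = spec or model.spec
    labels = np.asarray(train_data["labels"])
    if len(np.unique(labels)) < 2:
        raise TrainingError("training split must contain both classes")
    model.feat_mean = train_data["features"].mean(axis=0)
    std = train_data["features"].std(axis=0)
    std[std == 0] = 1.0
    model.feat_std = std

    counts = np.bincount(labels, minlength=spec.n_classes).astype(float)
    counts[counts == 0] = 1.0
    class_weights = len(labels) / (spec.n_classes * counts)

    opt = nn.Adam(model.params(), lr=spec.lr)
    rng = np.random.default_rng(spec.seed + 1)
    log = TrainLog(seed=spec.seed, spec_hash=spec.hash())
    grids, feats = train_data["grids"], train_data["features"]
    n = len(labels)
    for epoch in range(spec.epochs):
        perm = rng.permutation(n)
        loss_sum = 0.0
        hit_sum = 0
        for lo in range(0, n, spec.batch_size):
            idx = perm[lo : lo + spec.batch_size]
            logits = model.forward(grids[idx], feats[idx], train=True)
            loss, probs = model.loss_fn.forward(logits, labels[idx], class_weights)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch start {lo}"
                )
            opt.zero_grad()
            model.backward(model.loss_fn.backward())
            opt.step()
            loss_sum += loss * len(idx)
            hit_sum += int((probs.argmax(axis=1) == labels[idx]).sum())
        # epoch statistics aggregated over the minibatch passes
        entry = {
            "epoch": epoch + 1,
            "train_loss": loss_sum / n,
            "train_acc": hit_sum / n,
        }
        if val_data is not None:
            entry["val_loss"], entry["val_acc"] = _eval(
                model,
                val_data["grids"],
                val_data["features"],
                val_data["labels"],
                class_weights,
            )
        log.append(**entry)
    return model, log
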