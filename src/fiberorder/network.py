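"""Regression network mapping a fiber image to its order degree.

The model is a small convolutional network trained by regression (MSE),
not classification: the single logistic output unit predicts a normalized
order degree in (0, 1).  Training images are downsampled to the network
input size, standardized per image, and augmented with random 90-degree
rotations and flips — the order degree is rotation invariant, so the label
is unchanged and the network is pushed toward the same invariance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from ._net import ConvNet, adam_step
from .synth import LabeledDataset

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainingHistory",
    "TrainedModel",
    "EvalMetrics",
    "train",
    "predict",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA_VERSION = 1


def _default_architecture() -> list[dict]:
    # Three oriented-energy conv stages feeding a small dense head.  The
    # first stage starts from a bank of oriented Gabor filters (still
    # trained) and uses the even |z| activation, so early features measure
    # phase-invariant oriented energy - the natural primitive for an
    # orientation-order readout.
    return [
        {"kind": "conv", "filters": 24, "kernel": 7, "stride": 2,
         "activation": "abs", "init": "gabor"},
        {"kind": "pool", "size": 2},
        {"kind": "conv", "filters": 48, "kernel": 3, "stride": 1, "activation": "abs"},
        {"kind": "pool", "size": 2},
        {"kind": "conv", "filters": 48, "kernel": 3, "stride": 1},
        {"kind": "pool", "size": 2},
        {"kind": "dense", "width": 96},
        {"kind": "dense", "width": 1},
    ]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract: input size and ordered layer descriptors.

    The default is two convolution+pool stages followed by two dense
    layers; the single output unit is squashed by a logistic to (0, 1).
    """

    input_size: int = 128
    architecture: tuple = field(default_factory=lambda: tuple(
        tuple(sorted(layer.items())) for layer in _default_architecture()
    ))
    hidden_activation: str = "relu"
    output_activation: str = "logistic"

    def layers(self) -> list[dict]:
        return [dict(items) for items in self.architecture]

    @classmethod
    def from_layers(cls, input_size: int, layers: list[dict]) -> "ModelSpec":
        return cls(
            input_size=input_size,
            architecture=tuple(tuple(sorted(l.items())) for l in layers),
        )


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    loss: str = "mse"
    seed: int = 0
    augment: bool = True
    rotation_augment: bool = False  # continuous-angle rotations, not just 90 deg
    lr_schedule: str = "cosine"  # or "constant"
    lr_decay_epochs: int = 25  # cosine horizon; flat at the floor beyond it
    ema_decay: float = 0.6  # per-epoch Polyak averaging of weights (0 = off)
    plateau_patience: int = 5  # epochs
    plateau_tol: float = 0.01  # relative val-loss improvement

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error training is supported")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float]
    epochs_run: int
    converged_epoch: int | None  # first epoch satisfying the plateau rule (1-based)


@dataclass
class TrainedModel:
    net: ConvNet
    spec: ModelSpec
    config_digest: str
    history: TrainingHistory
    seed: int


@dataclass
class EvalMetrics:
    """Held-out regression metrics.

    Relative errors ``|pred - true| / true`` are fractions (0.06 = 6%) and
    are restricted to labels in [0.3, 0.7], where the denominator is well
    away from zero.  The calibration line is the least-squares fit of
    predictions against true labels over the full split.
    """

    mean_absolute_error: float
    mean_relative_error: float
    max_relative_error: float
    calibration_slope: float
    calibration_intercept: float
    n_images: int
    n_relative: int


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; the learning rate is likely too high."""


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_image(image: np.ndarray, input_size: int) -> np.ndarray:
    """Resize to the network input size and standardize per image."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (input_size, input_size):
        image = resize(image, (input_size, input_size), anti_aliasing=True)
    mu = image.mean()
    sd = image.std()
    return ((image - mu) / (sd + 1e-6)).astype(np.float32)


def _preprocess_stack(images: list[np.ndarray], input_size: int) -> np.ndarray:
    return np.stack([preprocess_image(im, input_size) for im in images])


_AUG_VARIANTS = 8  # 4 rotations x optional flip


def _augment(x: np.ndarray, variant: int) -> np.ndarray:
    """Dihedral-group variant of a (H, W) image; variant 0 is identity."""
    out = np.rot90(x, k=variant % 4)
    if variant >= 4:
        out = out[::-1, :]
    return out


def _rotate_free(x: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate by an arbitrary angle with reflective border fill.

    The order degree is invariant under rotation, so this produces a new
    valid view of the same mat; reflected borders introduce only local
    artifacts.
    """
    from scipy.ndimage import rotate

    return rotate(x, angle_deg, reshape=False, order=1, mode="reflect")


# ---------------------------------------------------------------------------
# training


def train(
    dataset: LabeledDataset,
    spec: ModelSpec | None = None,
    cfg: TrainingConfig | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Fit the regression network on the dataset's training split.

    The held-out split serves as the validation set: its MSE is recorded
    each epoch and drives the plateau stop — training halts at the first
    epoch whose best validation loss over the last ``plateau_patience``
    epochs improves on the previous best by less than ``plateau_tol``
    (relative), or at ``cfg.epochs``.  Deterministic given ``cfg.seed``.
    """
    spec = spec or ModelSpec()
    cfg = cfg or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)

    x_train = _preprocess_stack(
        [dataset.images[i].pixels for i in dataset.train_indices], spec.input_size
    )
    y_train = dataset.labels(dataset.train_indices).astype(np.float32)
    x_val = _preprocess_stack(
        [dataset.images[i].pixels for i in dataset.test_indices], spec.input_size
    )
    y_val = dataset.labels(dataset.test_indices).astype(np.float32)

    net = ConvNet(spec.input_size, spec.layers(), rng)
    state: dict = {}
    n = len(x_train)
    train_losses: list[float] = []
    val_losses: list[float] = []
    converged: int | None = None
    # Polyak-averaged weights: validation, early stopping and the returned
    # model all use the average, which damps epoch-to-epoch SGD noise
    ema: dict[str, np.ndarray] | None = (
        {k: v.copy() for k, v in net.params.items()} if cfg.ema_decay > 0 else None
    )

    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_schedule == "cosine" and cfg.epochs > 1:
            horizon = max(2, min(cfg.lr_decay_epochs, cfg.epochs))
            frac = min(1.0, (epoch - 1) / (horizon - 1))
            lr = cfg.learning_rate * (0.1 + 0.45 * (1.0 + np.cos(np.pi * frac)))
        else:
            lr = cfg.learning_rate
        order = rng.permutation(n)
        variants = (
            rng.integers(0, _AUG_VARIANTS, n) if cfg.augment else np.zeros(n, dtype=int)
        )
        free_angles = (
            rng.uniform(0.0, 90.0, n)
            if (cfg.augment and cfg.rotation_augment)
            else np.zeros(n)
        )
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.stack(
                [
                    _augment(
                        _rotate_free(x_train[j], float(free_angles[j]))
                        if free_angles[j] != 0.0
                        else x_train[j],
                        int(variants[j]),
                    )
                    for j in idx
                ]
            )
            yb = y_train[idx]
            pred, cache = net.forward(xb, want_cache=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"reduce learning_rate (currently {cfg.learning_rate})"
                )
            epoch_loss += loss * len(idx)
            dpred = (2.0 * err / len(idx)).astype(np.float32)
            grads = net.backward(cache, dpred)
            adam_step(net.params, grads, state, lr)
        train_losses.append(epoch_loss / n)
        if ema is not None:
            for k, v in net.params.items():
                ema[k] += (1.0 - cfg.ema_decay) * (v - ema[k])
            raw_params, net.params = net.params, ema
            val_pred = _predict_batch(net, x_val)
            net.params = raw_params
        else:
            val_pred = _predict_batch(net, x_val)
        val_losses.append(float(np.mean((val_pred - y_val) ** 2)))

        if converged is None and epoch > cfg.plateau_patience:
            prev_best = min(val_losses[: epoch - cfg.plateau_patience])
            recent_best = min(val_losses[epoch - cfg.plateau_patience :])
            if (prev_best - recent_best) / prev_best < cfg.plateau_tol:
                converged = epoch
        if converged is not None:
            break

    if ema is not None:
        net.params = ema
    history = TrainingHistory(
        train_loss=train_losses,
        val_loss=val_losses,
        epochs_run=len(val_losses),
        converged_epoch=converged,
    )
    model = TrainedModel(
        net=net, spec=spec, config_digest=cfg.digest(), history=history, seed=cfg.seed
    )
    return model, history


def _predict_batch(net: ConvNet, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    preds = [net.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(preds)


def predict(model: TrainedModel, image: np.ndarray, average_views: bool = True) -> float:
    """Order degree in (0, 1) for one grayscale image in [0, 1].

    With ``average_views`` the prediction is the mean over the 8 exact
    dihedral views of the image (90-degree rotations and flips); the target
    is invariant under these, so averaging only removes estimator noise.
    """
    x = preprocess_image(np.asarray(image, dtype=np.float64), model.spec.input_size)
    if x.shape != (model.spec.input_size, model.spec.input_size):
        raise ValueError(
            f"image resampled to {x.shape}, expected "
            f"({model.spec.input_size}, {model.spec.input_size})"
        )
    if not average_views:
        return float(model.net.forward(x[None])[0])
    views = np.stack([_augment(x, v) for v in range(_AUG_VARIANTS)])
    return float(model.net.forward(views).mean())


def predict_many(
    model: TrainedModel, images: list[np.ndarray], average_views: bool = True
) -> np.ndarray:
    x = _preprocess_stack([np.asarray(im, dtype=np.float64) for im in images],
                          model.spec.input_size)
    if not average_views:
        return _predict_batch(model.net, x)
    acc = np.zeros(len(x))
    for v in range(_AUG_VARIANTS):
        xv = np.stack([_augment(xi, v) for xi in x])
        acc += _predict_batch(model.net, xv)
    return acc / _AUG_VARIANTS


def evaluate(
    model: TrainedModel,
    dataset: LabeledDataset,
    split: str = "test",
    rel_band: tuple[float, float] = (0.3, 0.7),
) -> EvalMetrics:
    """Regression metrics on a dataset split (held-out by default)."""
    if split == "test":
        idx = dataset.test_indices
    elif split == "train":
        idx = dataset.train_indices
    else:
        raise ValueError("split must be 'train' or 'test'")
    if len(idx) == 0:
        raise ValueError(f"{split} split is empty")
    if split == "test" and np.intersect1d(dataset.train_indices, dataset.test_indices).size:
        raise ValueError("train and test splits overlap")
    preds = predict_many(model, [dataset.images[i].pixels for i in idx])
    truth = dataset.labels(idx)
    abs_err = np.abs(preds - truth)
    band = (truth >= rel_band[0]) & (truth <= rel_band[1])
    if band.sum() == 0:
        rel = np.array([np.nan])
    else:
        rel = abs_err[band] / truth[band]
    slope, intercept = np.polyfit(truth, preds, 1)
    return EvalMetrics(
        mean_absolute_error=float(abs_err.mean()),
        mean_relative_error=float(np.mean(rel)),
        max_relative_error=float(np.max(rel)),
        calibration_slope=float(slope),
        calibration_intercept=float(intercept),
        n_images=int(len(idx)),
        n_relative=int(band.sum()),
    )


# ---------------------------------------------------------------------------
# checkpoint serialization: npz parameter container + JSON sidecar


def save_checkpoint(model: TrainedModel, path: str | Path) -> Path:
    """Write parameters to ``<path>.npz`` and metadata to ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    np.savez(base.with_suffix(".npz"), **model.net.params)
    sidecar = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "input_size": model.spec.input_size,
        "architecture": model.spec.layers(),
        "hidden_activation": model.spec.hidden_activation,
        "output_activation": model.spec.output_activation,
        "config_digest": model.config_digest,
        "seed": model.seed,
        "history": {
            "train_loss": model.history.train_loss,
            "val_loss": model.history.val_loss,
            "epochs_run": model.history.epochs_run,
            "converged_epoch": model.history.converged_epoch,
        },
        "preprocessing": {"resize": "anti_aliased", "standardize": "per_image"},
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported checkpoint schema {sidecar.get('schema_version')!r}"
        )
    spec = ModelSpec.from_layers(sidecar["input_size"], sidecar["architecture"])
    net = ConvNet(spec.input_size, spec.layers(), np.random.default_rng(0))
    with np.load(base.with_suffix(".npz")) as data:
        for key in net.params:
            net.params[key] = data[key]
    hist = sidecar["history"]
    history = TrainingHistory(
        train_loss=hist["train_loss"],
        val_loss=hist["val_loss"],
        epochs_run=hist["epochs_run"],
        converged_epoch=hist["converged_epoch"],
    )
    return TrainedModel(
        net=net,
        spec=spec,
        config_digest=sidecar["config_digest"],
        history=history,
        seed=sidecar["seed"],
    )
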