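"""Training protocol for the tissue-segmentation U-Net.

The only image preprocessing besides the studied modifications is
z-score normalization.  One training trial applies a fixed modification
setting to every training *and* validation image, minimizes the mean
per-class cross-entropy with Adam, evaluates the validation loss each
epoch, and keeps the parameters of the epoch with the lowest validation
loss (ties broken by the earliest epoch).  With ``deterministic=True``
(the default; everything is seeded numpy) two identical calls return
bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .modifications import ModificationSetting, apply_setting
from .nn import Adam, UNet, UNetSpec, class_balanced_ce, softmax
from .phantom import SimulatedImage

N_CLASSES = 4


@dataclass(frozen=True)
class ModelConfig:
    """U-Net architecture configuration."""

    input_size: tuple[int, int] = (96, 96)
    depth: int = 3
    base_channels: int = 16
    dropout_rate: float = 0.5
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError("H and W must be divisible by 2^depth")

    def spec(self) -> UNetSpec:
        return UNetSpec(
            in_channels=1,
            n_classes=self.n_classes,
            depth=self.depth,
            base_channels=self.base_channels,
            dropout_rate=self.dropout_rate,
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    learning_rate: float = 1e-4
    batch_size: int = 8
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class TrainedModel:
    """A trained network plus its training provenance."""

    net: UNet
    config: ModelConfig
    train_setting: ModificationSetting
    seed: int
    best_epoch: int
    best_val_loss: float
    log: pd.DataFrame = field(repr=False)


def zscore_normalize(
    image: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Z-score over the foreground; background set to the minimum.

    Foreground is ``mask`` when given, else pixels with intensity > 0.
    Uses the population standard deviation.  Raises on constant
    foreground (zero variance).
    """
    img = np.asarray(image, dtype=float)
    fg = np.asarray(mask, dtype=bool) if mask is not None else img > 0
    vals = img[fg]
    if vals.size == 0:
        raise ValueError("empty foreground")
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant foreground: zero variance")
    out = np.empty_like(img)
    normed = (vals - mu) / sd
    out[fg] = normed
    out[~fg] = normed.min()
    return out


def prepare_input(
    image: SimulatedImage, setting: ModificationSetting
) -> np.ndarray:
    """Modification then z-score, as fed to the network."""
    mask = image.label_map.foreground
    modified = apply_setting(image.intensities, setting, mask=mask)
    return zscore_normalize(modified, mask=mask)


def _stack(
    images: Sequence[SimulatedImage], setting: ModificationSetting
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([prepare_input(im, setting) for im in images])
    ys = np.stack([im.label_map.labels for im in images])
    return xs[:, None, :, :], ys


def train_model(
    train_set: Sequence[SimulatedImage],
    val_set: Sequence[SimulatedImage],
    train_setting: ModificationSetting,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> TrainedModel:
    """One training trial under a fixed train-time modification setting.

    The setting is applied to every training and validation image, the
    mean per-class cross-entropy is minimized with Adam, and the
    checkpoint with the lowest validation loss is returned.
    """
    x_train, y_train = _stack(train_set, train_setting)
    x_val, y_val = _stack(val_set, train_setting)
    rng = np.random.default_rng(train_cfg.seed)
    net = UNet(model_cfg.spec(), rng)
    opt = Adam(net, lr=train_cfg.learning_rate)
    n = len(train_set)
    bs = min(train_cfg.batch_size, n)
    best_state = net.get_state()
    best_val = np.inf
    best_epoch = -1
    rows = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            net.zero_grad()
            logits = net.forward(x_train[idx], train_rng=rng)
            probs = softmax(logits)
            loss, dlogits = class_balanced_ce(
                probs, y_train[idx], model_cfg.n_classes
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_loss = _eval_loss(net, x_val, y_val, model_cfg.n_classes)
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
        })
        if val_loss < best_val:  # strict: ties keep the earliest epoch
            best_val = val_loss
            best_epoch = epoch
            best_state = net.get_state()
    net.set_state(best_state)
    return TrainedModel(
        net=net,
        config=model_cfg,
        train_setting=train_setting,
        seed=train_cfg.seed,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        log=pd.DataFrame(rows),
    )


def _eval_loss(
    net: UNet, x: np.ndarray, y: np.ndarray, n_classes: int
) -> float:
    logits = net.forward(x)  # no dropout at evaluation
    probs = softmax(logits)
    loss, _ = class_balanced_ce(probs, y, n_classes)
    return loss


def save_model(model: TrainedModel, path_prefix: str) -> None:
    """Checkpoint to ``<prefix>.npz`` (parameters) plus a JSON metadata
    sidecar and a CSV training log."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    state = model.net.get_state()
    np.savez(prefix.with_suffix(".npz"),
             **{f"param_{i}": p for i, p in enumerate(state)})
    meta = {
        "config": {
            "input_size": list(model.config.input_size),
            "depth": model.config.depth,
            "base_channels": model.config.base_channels,
            "dropout_rate": model.config.dropout_rate,
            "n_classes": model.config.n_classes,
        },
        "train_setting": {
            "kind": model.train_setting.kind,
            "strength": model.train_setting.strength,
        },
        "seed": model.seed,
        "best_epoch": model.best_epoch,
        "best_val_loss": model.best_val_loss,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    model.log.to_csv(prefix.with_suffix(".log.csv"), index=False)


def load_model(path_prefix: str) -> TrainedModel:
    """Restore a checkpoint written by :func:`save_model`."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    cfg = ModelConfig(
        input_size=tuple(meta["config"]["input_size"]),
        depth=meta["config"]["depth"],
        base_channels=meta["config"]["base_channels"],
        dropout_rate=meta["config"]["dropout_rate"],
        n_classes=meta["config"]["n_classes"],
    )
    net = UNet(cfg.spec(), np.random.default_rng(0))
    with np.load(prefix.with_suffix(".npz")) as data:
        net.set_state([data[f"param_{i}"] for i in range(len(data.files))])
    log = pd.read_csv(prefix.with_suffix(".log.csv"))
    return TrainedModel(
        net=net,
        config=cfg,
        train_setting=ModificationSetting(
            meta["train_setting"]["kind"], meta["train_setting"]["strength"]
        ),
        seed=meta["seed"],
        best_epoch=meta["best_epoch"],
        best_val_loss=meta["best_val_loss"],
        log=log,
    )


def predict_probs(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Per-class probability maps (n_classes, H, W); dropout disabled."""
    x = np.asarray(image, dtype=float)[None, None, :, :]
    logits = model.net.forward(x)
    return softmax(logits)[0]


def predict_labels(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Argmax label map of ``predict_probs``."""
    return predict_probs(model, image).argmax(axis=0)


def class_sum_and_input_grad(
    model: TrainedModel, image: np.ndarray, label: int
) -> tuple[float, np.ndarray]:
    """Sum over output pixels of one class probability, and its input
    gradient.

    Returns ``(sum_mn p_label[m, n], d(sum)/d(image))`` with dropout
    disabled — the quantity Integrated Gradients integrates along the
    baseline-to-input path.
    """
    net = model.net
    x = np.asarray(image, dtype=float)[None, None, :, :]
    logits = net.forward(x)
    probs = softmax(logits)
    p_l = probs[:, label]
    # d(sum p_l)/d(logit_k) = p_l * (delta_lk - p_k), per pixel
    dlogits = -probs * p_l[:, None]
    dlogits[:, label] += p_l
    net.zero_grad()
    dx = net.backward(dlogits)
    return float(p_l.sum()), dx[0, 0]
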