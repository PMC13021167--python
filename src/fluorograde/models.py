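"""Model builders, the augmentation schedule, training with best-epoch
selection, transfer-learning fine-tune, and fold selection.

Three model families are used downstream: a compact two-channel CNN for the
three binary Gleason tasks, a 4-contraction/3-expansion U-Net for
epithelium segmentation on synthetic H&E, and a deeper
6-contraction/5-expansion U-Net for 3-class cancer segmentation.  The
"full" preset carries the published hyperparameters (input 256x256,
batch 32, the printed learning-rate/epoch schedule); the "desk" preset
shrinks input size and filter widths so a full train/evaluate cycle runs in
minutes on one CPU without changing any contract.

Augmentation produces a fixed number of new crops per fold: 1000 flips
(half horizontal, half vertical), 1500 rotations (500 each of 90/180/270
degrees), 500 additive-Gaussian-noise draws with variance ~ U(0, 0.5) on
the z-normalized intensity scale, and 500 Gaussian blurs with
sigma ~ U(0, 5) followed by the same noise — 3500 in total.  Geometric
transforms apply to channels and masks alike; masks are never blurred or
noised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotate import CropRecord
from .errors import ConfigurationError
from .metrics import MetricsReport, TaskSpec
from .nn import LOSSES, Adam, ClassifierCNN, Network, UNet

MODEL_FAMILIES = ("classifier_cnn", "unet_4c3e", "unet_6c5e")


@dataclass
class ModelSpec:
    family: str
    input_shape: tuple[int, int, int]
    base_filters: int = 16
    init: str = "he_normal"
    loss: str = "binary_cross_entropy"
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.loss not in LOSSES:
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        if self.family == "classifier_cnn" and self.input_shape[2] != 2:
            raise ConfigurationError("classifier input must have 2 channels (DRAQ5+Eosin)")
        n_pools = {"classifier_cnn": 4, "unet_4c3e": 3, "unet_6c5e": 5}[self.family]
        div = 2 ** n_pools
        if self.input_shape[0] % div or self.input_shape[1] % div:
            raise ConfigurationError(
                f"{self.family} input dims must be divisible by {div}, got {self.input_shape[:2]}"
            )


#: Full-scale (published-schedule) hyperparameter registry, keyed by role.
FULL_SPECS: dict[str, ModelSpec] = {
    "epithelial_unet": ModelSpec(
        family="unet_4c3e", input_shape=(256, 256, 3), base_filters=16,
        init="he_normal", loss="dice", lr=0.001, epochs=30, batch_size=32,
    ),
    "classifier": ModelSpec(
        family="classifier_cnn", input_shape=(256, 256, 2), base_filters=16,
        init="xavier_uniform", loss="binary_cross_entropy", lr=0.0001,
        epochs=20, batch_size=32,
    ),
    "cancer_unet": ModelSpec(
        family="unet_6c5e", input_shape=(256, 256, 2), base_filters=16,
        init="he_normal", loss="sparse_categorical_cross_entropy", lr=0.02,
        epochs=20, batch_size=32, out_channels=3,
    ),
}

#: Fine-tune defaults for transfer learning onto real D&E data.
FINETUNE_DEFAULTS = {"classifier": (2e-5, 20), "segmentation": (0.01, 10)}

#: Desk-scale presets: same families and losses, smaller inputs/filters.
DESK_SPECS: dict[str, ModelSpec] = {
    "epithelial_unet": replace(
        FULL_SPECS["epithelial_unet"], input_shape=(64, 64, 3), base_filters=8, epochs=10
    ),
    "classifier": replace(
        FULL_SPECS["classifier"], input_shape=(64, 64, 2), base_filters=8,
        epochs=12, lr=0.001,
    ),
    "cancer_unet": replace(
        FULL_SPECS["cancer_unet"], input_shape=(64, 64, 2), base_filters=8,
        epochs=12, lr=0.005, batch_size=16,
    ),
}


@dataclass
class AugmentationSpec:
    """Counts and ranges of the fixed augmentation schedule."""

    n_flip: int = 1000
    n_rot: int = 1500
    n_noise: int = 500
    noise_variance_range: tuple[float, float] = (0.0, 0.5)
    n_blur_noise: int = 500
    blur_sigma_range: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_flip, self.n_rot, self.n_noise, self.n_blur_noise):
            if n < 0:
                raise ValueError("augmentation counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_flip + self.n_rot + self.n_noise + self.n_blur_noise

    def scaled(self, factor: float) -> "AugmentationSpec":
        """Same 2:3:1:1 mix at a smaller total (desk preset)."""
        return replace(
            self,
            n_flip=max(0, round(self.n_flip * factor)),
            n_rot=max(0, round(self.n_rot * factor)),
            n_noise=max(0, round(self.n_noise * factor)),
            n_blur_noise=max(0, round(self.n_blur_noise * factor)),
        )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    selected_epoch: Optional[int] = None
    metrics_at_selection: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec) -> Network:
    """Instantiate an untrained network; parameter count and initial weights
    are pure functions of the spec (identical specs -> identical weights)."""
    cin = spec.input_shape[2]
    if spec.family == "classifier_cnn":
        return ClassifierCNN(
            in_channels=cin, n_blocks=4, base_filters=spec.base_filters,
            init=spec.init, seed=spec.seed,
        )
    n_contraction = 4 if spec.family == "unet_4c3e" else 6
    return UNet(
        in_channels=cin, out_channels=spec.out_channels,
        n_contraction=n_contraction, base_filters=spec.base_filters,
        init=spec.init, seed=spec.seed,
    )


def save_model(model: Network, spec: ModelSpec, path) -> Path:
    """Portable checkpoint: an .npz of weights plus a JSON spec sidecar."""
    path = Path(path)
    np.savez_compressed(path, *model.get_weights())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({**spec.__dict__, "input_shape": list(spec.input_shape)}))
    return path


def load_model(path) -> tuple[Network, ModelSpec]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    meta["input_shape"] = tuple(meta["input_shape"])
    spec = ModelSpec(**meta)
    model = build_model(spec)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.set_weights([z[k] for k in z.files])
    return model, spec


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _transform_record(rec: CropRecord, fn, touch_mask: bool) -> CropRecord:
    task_labels = dict(rec.task_labels)
    if touch_mask and TaskSpec.CANCER_SEG in task_labels:
        seg = task_labels[TaskSpec.CANCER_SEG]
        if isinstance(seg, np.ndarray):
            task_labels[TaskSpec.CANCER_SEG] = fn(seg)
    return CropRecord(
        box=rec.box,
        draq5_crop=fn(rec.draq5_crop),
        eosin_crop=fn(rec.eosin_crop),
        core_id=rec.core_id,
        patient_id=rec.patient_id,
        raw_label=rec.raw_label,
        task_labels=task_labels,
    )


def augment(crops: Sequence[CropRecord], spec: AugmentationSpec | None = None) -> list[CropRecord]:
    """Produce exactly ``spec.total`` new crops drawn uniformly with
    replacement from ``crops``; geometric transforms also move the
    segmentation mask, intensity corruptions never do."""
    if not crops:
        raise ValueError("augment requires a non-empty crop list")
    spec = spec or AugmentationSpec()
    rng = np.random.default_rng(spec.seed)
    out: list[CropRecord] = []

    def pick() -> CropRecord:
        return crops[int(rng.integers(len(crops)))]

    n_h = spec.n_flip // 2
    for i in range(spec.n_flip):
        axis = 1 if i < n_h else 0  # horizontal flip = reverse columns
        out.append(_transform_record(pick(), lambda a, ax=axis: np.flip(a, axis=ax).copy(), True))
    per_rot = spec.n_rot // 3
    for i in range(spec.n_rot):
        k = 1 + min(i // per_rot, 2) if per_rot else 1 + i % 3
        out.append(_transform_record(pick(), lambda a, k=k: np.rot90(a, k=k).copy(), True))
    lo, hi = spec.noise_variance_range
    for _ in range(spec.n_noise):
        var = rng.uniform(lo, hi)
        noise_fn = lambda a, s=np.sqrt(var): a + rng.normal(0.0, s, a.shape)
        out.append(_transform_record(pick(), noise_fn, False))
    blo, bhi = spec.blur_sigma_range
    for _ in range(spec.n_blur_noise):
        sig = rng.uniform(blo, bhi)
        var = rng.uniform(lo, hi)
        def blur_noise(a, sg=sig, s=np.sqrt(var)):
            return gaussian_filter(a, sg) + rng.normal(0.0, s, a.shape)
        out.append(_transform_record(pick(), blur_noise, False))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def records_to_arrays(records: Sequence[CropRecord], task: TaskSpec):
    """Stack crop records into (X, y) arrays for one task, skipping removed
    and excluded records."""
    from .annotate import EXCLUDED

    xs, ys = [], []
    for rec in records:
        if rec.removed:
            continue
        label = rec.task_labels.get(task)
        if label is None or (not isinstance(label, np.ndarray) and label == EXCLUDED):
            continue
        xs.append(np.stack([rec.draq5_crop, rec.eosin_crop], axis=-1))
        ys.append(label)
    if not xs:
        raise ConfigurationError(f"no usable records for task {task}")
    return np.asarray(xs, dtype=np.float64), np.asarray(ys)


def _epoch_loss(model: Network, loss_fn, x, y, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        z = model.forward(xb)
        loss, _ = loss_fn(z, yb)
        total += loss * xb.shape[0]
        n += xb.shape[0]
    return total / max(n, 1)


def train(
    model: Network,
    train_set,
    val_set,
    spec: ModelSpec,
) -> tuple[Network, TrainingHistory]:
    """Adam training with per-epoch validation and best-epoch restoration.

    ``train_set``/``val_set`` are (X, y) tuples.  After every epoch the
    validation loss is recorded; at the end the weights from the epoch with
    the lowest validation loss (earliest on ties) are restored.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ConfigurationError("train and validation sets must be non-empty")
    loss_fn = LOSSES[spec.loss]
    opt = Adam(model.params(), lr=spec.lr)
    rng = np.random.default_rng(spec.seed)
    history = TrainingHistory()
    best_weights = model.get_weights()
    best_val = np.inf

    for epoch in range(spec.epochs):
        order = rng.permutation(x_tr.shape[0])
        running, seen = 0.0, 0
        for i in range(0, order.size, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            z = model.forward(xb)
            loss, dz = loss_fn(z, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch + 1}, step {i // spec.batch_size}"
                )
            model.backward(dz)
            opt.step()
            running += loss * xb.shape[0]
            seen += xb.shape[0]
        history.train_loss.append(running / seen)
        val_loss = _epoch_loss(model, loss_fn, x_va, y_va, spec.batch_size)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()

    history.selected_epoch = int(np.argmin(history.val_loss)) if history.val_loss else None
    model.set_weights(best_weights)
    return model, history


def finetune(
    model: Network,
    train_set,
    val_set,
    lr: float,
    epochs: int,
    base_spec: ModelSpec | None = None,
) -> tuple[Network, TrainingHistory]:
    """Continue training a pretrained model with an overridden schedule;
    ``epochs == 0`` is a no-op (weights untouched)."""
    if epochs == 0:
        return model, TrainingHistory(selected_epoch=None)
    spec = replace(
        base_spec or FULL_SPECS["classifier"], lr=lr, epochs=epochs
    )
    return train(model, train_set, val_set, spec)


def select_fold(
    per_fold_results: Sequence[MetricsReport], criterion: str = "max_kappa"
) -> int:
    """Pick the fold whose held-out metrics maximize the criterion
    (``max_kappa`` for classifiers, ``max_dice_sum`` for segmentation);
    ties go to the lowest fold index."""
    if not per_fold_results:
        raise ValueError("need at least one fold result")
    if criterion == "max_kappa":
        scores = [r.kappa if r.kappa is not None else -np.inf for r in per_fold_results]
    elif criterion == "max_dice_sum":
        scores = [
            sum(r.dice_per_class.values()) if r.dice_per_class else -np.inf
            for r in per_fold_results
        ]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return int(np.argmax(scores))
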