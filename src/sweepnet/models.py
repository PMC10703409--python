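"""Sweep-detection architectures and the training protocol.

Three architectures are provided, all ending in a single sigmoid unit:

* ``mini-CNN`` -- one 2x1 convolution kernel (a vertical difference
  detector across neighbouring haplotype rows), ReLU, flatten, dense(1).
  Variants: a 1x2 (horizontal) kernel, and a ReLU-free linear model.
* ``Imagene-style`` -- three blocks of 32 3x3 convolutions with ReLU and
  2x2 max pooling, then dense(64) + ReLU and dense(1).
* ``DeepSet`` -- two 64-kernel 1x5 row-wise convolutions with ReLU, a mean
  over the haplotype axis (exact row-permutation invariance), flatten, two
  dense(64) + ReLU layers, dense(1).

Training follows a fixed protocol: binary cross-entropy plus L1+L2 weight
penalties (0.005 each), Adam (lr 0.001, beta1 0.9, beta2 0.999), batch 64,
2 epochs, multiple independent restarts; the restart with the best
validation accuracy is kept.  Convolution weights draw from a standard
normal and dense weights from Glorot uniform, except DeepSet which is
Glorot throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "SpecError",
    "TrainingError",
    "build_mini_cnn",
    "build_imagene",
    "build_deepset",
    "build_network",
    "train",
    "predict",
    "extract_mini_cnn_weights",
    "save_model",
    "load_model",
]


class SpecError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | relu | maxpool | mean_rows | flatten | dense | sigmoid
    units: int | None = None
    kernel: tuple[int, int] | None = None
    init: str | None = None
    # L1/L2 penalties attach to convolution kernels (the reference models'
    # convention); dense layers are unpenalized by default
    regularize: bool | None = None


@dataclass(frozen=True)
class ModelSpec:
    name: str
    input_shape: tuple[int, int]  # (height, width)
    layers: tuple[LayerSpec, ...]
    l1: float = 0.005
    l2: float = 0.005

    def param_count(self) -> int:
        return build_network(self, rng=np.random.default_rng(0)).param_count()


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 2
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise SpecError("at least one restart required")


@dataclass
class TrainedModel:
    spec: ModelSpec
    weights: list[np.ndarray]
    val_accuracy: float
    seed: int
    restart_index: int
    history: dict = field(default_factory=dict)

    def network(self) -> nn.Network:
        net = build_network(self.spec, rng=np.random.default_rng(0))
        net.set_weights(self.weights)
        return net


# ---------------------------------------------------------------------------
# Architecture builders
# ---------------------------------------------------------------------------


def build_mini_cnn(
    height: int,
    width: int,
    kernel: tuple[int, int] = (2, 1),
    relu: bool = True,
) -> ModelSpec:
    """Single-kernel CNN: conv(1 kernel) -> [ReLU] -> flatten -> dense(1) ->
    sigmoid.  The default 2x1 kernel differences consecutive rows."""
    if height < 2:
        raise SpecError("mini-CNN needs at least two haplotype rows")
    layers = [LayerSpec("conv", units=1, kernel=kernel, init="standard_normal")]
    if relu:
        layers.append(LayerSpec("relu"))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", units=1, init="glorot_uniform"),
        LayerSpec("sigmoid"),
    ]
    suffix = "" if kernel == (2, 1) else f"_{kernel[0]}x{kernel[1]}"
    name = ("mini_cnn" if relu else "mini_cnn_linear") + suffix
    return ModelSpec(name=name, input_shape=(height, width), layers=tuple(layers))


def build_imagene(
    height: int,
    width: int,
    n_blocks: int = 3,
    filters: int = 32,
    dense_units: int = 64,
) -> ModelSpec:
    """Imagene-style CNN: ``n_blocks`` x [conv(filters, 3x3), ReLU,
    maxpool 2x2], flatten, dense(64) + ReLU, dense(1) + sigmoid.

    Block/filter/unit counts are exposed so the reduction ladder between
    this model and mini-CNN can be walked configurably.
    """
    shape = (height, width)
    layers: list[LayerSpec] = []
    for _ in range(n_blocks):
        if shape[0] < 3 or shape[1] < 3:
            raise SpecError(f"input too small for {n_blocks} conv/pool blocks")
        layers += [
            LayerSpec("conv", units=filters, kernel=(3, 3), init="standard_normal"),
            LayerSpec("relu"),
            LayerSpec("maxpool"),
        ]
        shape = ((shape[0] - 2) // 2, (shape[1] - 2) // 2)
        if shape[0] < 1 or shape[1] < 1:
            raise SpecError("input exhausted by pooling")
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", units=dense_units, init="glorot_uniform"),
        LayerSpec("relu"),
        LayerSpec("dense", units=1, init="glorot_uniform"),
        LayerSpec("sigmoid"),
    ]
    return ModelSpec(name="imagene", input_shape=(height, width), layers=tuple(layers))


def build_deepset(height: int, width: int, filters: int = 64, dense_units: int = 64) -> ModelSpec:
    """Row-permutation-invariant network: two 1x5 row convolutions + ReLU,
    mean over rows, flatten, two dense(64) + ReLU, dense(1) + sigmoid."""
    if width < 9:
        raise SpecError("DeepSet needs width >= 9 for two valid 1x5 convolutions")
    layers = (
        LayerSpec("conv", units=filters, kernel=(1, 5), init="glorot_uniform"),
        LayerSpec("relu"),
        LayerSpec("conv", units=filters, kernel=(1, 5), init="glorot_uniform"),
        LayerSpec("relu"),
        LayerSpec("mean_rows"),
        LayerSpec("flatten"),
        LayerSpec("dense", units=dense_units, init="glorot_uniform"),
        LayerSpec("relu"),
        LayerSpec("dense", units=dense_units, init="glorot_uniform"),
        LayerSpec("relu"),
        LayerSpec("dense", units=1, init="glorot_uniform"),
        LayerSpec("sigmoid"),
    )
    return ModelSpec(name="deepset", input_shape=(height, width), layers=layers)


def build_network(spec: ModelSpec, rng: np.random.Generator | None = None) -> nn.Network:
    layers: list[nn.Layer] = []
    for ls in spec.layers:
        if ls.kind == "conv":
            reg = True if ls.regularize is None else ls.regularize
            layers.append(
                nn.Conv2D(ls.units, ls.kernel, init=ls.init or "standard_normal",
                          regularize=reg)
            )
        elif ls.kind == "relu":
            layers.append(nn.ReLU())
        elif ls.kind == "maxpool":
            layers.append(nn.MaxPool2x2())
        elif ls.kind == "mean_rows":
            layers.append(nn.MeanOverRows())
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
        elif ls.kind == "dense":
            reg = False if ls.regularize is None else ls.regularize
            layers.append(
                nn.Dense(ls.units, init=ls.init or "glorot_uniform", regularize=reg)
            )
        elif ls.kind == "sigmoid":
            layers.append(nn.Sigmoid())
        else:
            raise SpecError(f"unknown layer kind {ls.kind!r}")
    h, w = spec.input_shape
    try:
        net = nn.Network(layers, (h, w, 1), l1=spec.l1, l2=spec.l2)
    except ValueError as err:
        raise SpecError(str(err)) from err
    if rng is not None:
        net.init_params(rng)
    return net


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _accuracy(p: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((p > 0.5).astype(int) == y))


def train(
    spec: ModelSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train ``cfg.restarts`` independently initialized networks and keep
    the restart with the best validation accuracy (ties to the earliest).

    Fully deterministic given ``cfg.seed``: restart ``i`` draws its
    initializer and shuffling streams from ``seed + i``.
    """
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    for name, y in (("train", y_train), ("val", y_val)):
        if len(np.unique(y)) < 2:
            raise TrainingError(f"{name} split must contain both classes")
    if x_train.shape[1:3] != tuple(spec.input_shape):
        raise TrainingError(
            f"images {x_train.shape[1:3]} do not match model input {spec.input_shape}"
        )

    best: TrainedModel | None = None
    histories = []
    for restart in range(cfg.restarts):
        restart_seed = cfg.seed + restart
        rng = np.random.default_rng(restart_seed)
        net = build_network(spec, rng=rng)
        opt = nn.Adam(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
        losses = []
        n = len(x_train)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                losses.append(net.train_step(x_train[idx], y_train[idx], opt))
        val_acc = _accuracy(net.predict(x_val), y_val)
        histories.append({"restart": restart, "val_accuracy": val_acc, "final_loss": losses[-1] if losses else None})
        if best is None or val_acc > best.val_accuracy:
            best = TrainedModel(
                spec=spec,
                weights=net.get_weights(),
                val_accuracy=val_acc,
                seed=cfg.seed,
                restart_index=restart,
            )
    best.history = {"restarts": histories, "config": dataclasses.asdict(cfg)}
    return best


def predict(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per image, in batch order."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:3] != tuple(model.spec.input_shape):
        raise TrainingError(
            f"images {images.shape[1:3]} do not match model input {model.spec.input_shape}"
        )
    return model.network().predict(images)


def extract_mini_cnn_weights(model: TrainedModel) -> tuple[np.ndarray, np.ndarray]:
    """Return the 2x1 (or 1x2) convolution kernel and the dense weights
    reshaped onto the post-convolution image grid for visualization."""
    kinds = [ls.kind for ls in model.spec.layers]
    if kinds not in (["conv", "relu", "flatten", "dense", "sigmoid"],
                     ["conv", "flatten", "dense", "sigmoid"]):
        raise TypeError("not a mini-CNN architecture")
    conv_spec = model.spec.layers[0]
    kh, kw = conv_spec.kernel
    kernel = model.weights[0].reshape(kh, kw)
    h, w = model.spec.input_shape
    grid_shape = (h - kh + 1, w - kw + 1)
    dense_w = model.weights[2].reshape(grid_shape)
    return kernel, dense_w


# ---------------------------------------------------------------------------
# Serialization (architecture JSON + weight arrays)
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec_doc = {
        "name": model.spec.name,
        "input_shape": list(model.spec.input_shape),
        "l1": model.spec.l1,
        "l2": model.spec.l2,
        "layers": [dataclasses.asdict(ls) for ls in model.spec.layers],
        "val_accuracy": model.val_accuracy,
        "seed": model.seed,
        "restart_index": model.restart_index,
    }
    (directory / "spec.json").write_text(json.dumps(spec_doc, indent=2))
    np.savez(directory / "weights.npz", **{f"w{i}": w for i, w in enumerate(model.weights)})
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    doc = json.loads((directory / "spec.json").read_text())
    layers = tuple(
        LayerSpec(
            kind=d["kind"],
            units=d["units"],
            kernel=tuple(d["kernel"]) if d["kernel"] else None,
            init=d["init"],
            regularize=d.get("regularize"),
        )
        for d in doc["layers"]
    )
    spec = ModelSpec(
        name=doc["name"],
        input_shape=tuple(doc["input_shape"]),
        layers=layers,
        l1=doc["l1"],
        l2=doc["l2"],
    )
    with np.load(directory / "weights.npz") as data:
        weights = [data[f"w{i}"] for i in range(len(data.files))]
    return TrainedModel(
        spec=spec,
        weights=weights,
        val_accuracy=doc["val_accuracy"],
        seed=doc["seed"],
        restart_index=doc["restart_index"],
    )
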