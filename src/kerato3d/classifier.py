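"""3D CNN classification of corneal volumes into four severity classes.

Architecture: four blocks of (3x3x3 valid convolution -> ReLU -> 2x2x2 max
pool) with 96, 128, 256 and 512 kernels, two fully connected layers of width
1000, and a softmax output over the four classes
``(normal, mild, moderate, severe)``.  Training is plain stochastic gradient
descent on cross-entropy with batch size 32 and learning rate 0.01 for up to
30 epochs (all configurable).

The input edge length is configurable; the default is 64 voxels, a
desk-scale setting that preserves the layer topology while keeping memory
and time within a single-CPU budget (the same stack accepts any edge length
that survives four conv/pool halvings).

Preprocessing normalizes any volume to the network's input space: tight ROI
crop around the cornea (10% padding), isotropic trilinear resampling into
the input cube (zero-padded; the cornea's height-to-width ratio carries the
severity signal and is preserved), 3D Gaussian filtering (sigma = 1 voxel),
and intensity scaling to [0, 1].
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .errors import ConfigurationError, Kerato3dError
from .io import Volume3D
from .nn import Conv3d, Flatten, Linear, MaxPool3d, ReLU, Sequential, cross_entropy_with_grad, softmax
from .phantom import STAGES

__all__ = ["CnnConfig", "KeratoconusCNN", "preprocess_volume", "build_model",
           "train", "predict", "save_model", "load_model"]


@dataclass
class CnnConfig:
    """Hyperparameters of the volumetric classifier."""

    input_edge: int = 64
    conv_channels: tuple[int, int, int, int] = (96, 128, 256, 512)
    fc_width: int = 1000
    n_classes: int = 4
    batch_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 30
    seed: int = 0
    #: stop once the epoch training accuracy reaches this value (the training
    #: set is memorized and plain SGD has met its objective); None disables.
    early_stop_accuracy: float | None = 1.0
    #: plain SGD at a fixed rate oscillates once the set is nearly
    #: memorized; training keeps a checkpoint of the best-accuracy epoch
    #: (ties: lower loss), restores it at the end, and stops early when the
    #: best has not improved for this many epochs.  None disables.
    early_stop_patience: int | None = 5
    #: samples processed per forward/backward chunk; gradients are averaged
    #: over the full batch regardless, so this only bounds peak memory.
    accumulation_chunk: int = 2
    #: variance-calibrate the initialization on the training data (LSUV
    #: style) before the first epoch.  Plain SGD at a fixed learning rate
    #: needs well-scaled activations from the first step; see train().
    calibrate_init: bool = True

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 4:
            raise ConfigurationError("exactly four convolutional blocks are expected")
        self.layer_edges()  # validates input_edge

    def layer_edges(self) -> list[int]:
        """Spatial edge after each conv/pool block; raises if the cascade
        collapses before the fourth block."""
        e = self.input_edge
        edges = []
        for i in range(4):
            if e < 3:
                raise ConfigurationError(
                    f"input_edge {self.input_edge} collapses before conv block {i + 1}"
                )
            e = e - 2
            if e < 2:
                raise ConfigurationError(
                    f"input_edge {self.input_edge} collapses before pool block {i + 1}"
                )
            e = e // 2
            edges.append(e)
        if e < 1:
            raise ConfigurationError("no spatial extent left after the fourth block")
        return edges


class KeratoconusCNN:
    """The network plus its config and class encoding."""

    def __init__(self, cfg: CnnConfig) -> None:
        self.cfg = cfg
        edges = cfg.layer_edges()
        rng = np.random.default_rng(cfg.seed)
        c = cfg.conv_channels
        layers = [
            Conv3d(1, c[0], rng, need_input_grad=False), ReLU(), MaxPool3d(),
            Conv3d(c[0], c[1], rng), ReLU(), MaxPool3d(),
            Conv3d(c[1], c[2], rng), ReLU(), MaxPool3d(),
            Conv3d(c[2], c[3], rng), ReLU(), MaxPool3d(),
            Flatten(),
            Linear(c[3] * edges[-1] ** 3, cfg.fc_width, rng), ReLU(),
            Linear(cfg.fc_width, cfg.fc_width, rng), ReLU(),
            Linear(cfg.fc_width, cfg.n_classes, rng, relu_gain=False),
        ]
        self.net = Sequential(layers)
        self.classes = STAGES[: cfg.n_classes]
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        # input standardization constants, set from the training set by
        # ``train`` and applied to every input (few dozen SGD updates demand
        # well-scaled activations from the first step)
        self.input_mean: float = 0.0
        self.input_std: float = 1.0

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def _to_batch(self, volumes: np.ndarray) -> np.ndarray:
        # (B, E, E, E) -> internal (C=1, B, D, H, W)
        return np.ascontiguousarray(volumes[None], dtype=np.float32)

    def logits(self, volumes: np.ndarray) -> np.ndarray:
        """(B, E, E, E) -> (classes, B) raw scores."""
        e = self.cfg.input_edge
        if volumes.ndim == 3:
            volumes = volumes[None]
        if volumes.shape[1:] != (e, e, e):
            raise Kerato3dError(
                f"expected {e}^3 input volumes, got {volumes.shape[1:]}"
            )
        volumes = (volumes - self.input_mean) / self.input_std
        return self.net.forward(self._to_batch(volumes.astype(np.float32)))

    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        """(B, E, E, E) -> (B, classes) softmax probabilities."""
        return softmax(self.logits(volumes)).T


def build_model(cfg: CnnConfig) -> KeratoconusCNN:
    """Instantiate the network; identical config + seed gives identical
    initial parameters."""
    return KeratoconusCNN(cfg)


def preprocess_volume(v: Volume3D, cfg: CnnConfig) -> Volume3D:
    """ROI crop + resample + 3D Gaussian filter + [0, 1] intensity scaling.

    The ROI is the tight bounding box of supra-threshold voxels (5% of max),
    padded by 10% per side; output shape is exactly ``input_edge^3``.
    Constant volumes pass through unchanged in value (DC gain 1).
    """
    vox = v.voxels.astype(np.float32)
    if vox.size == 0:
        raise Kerato3dError("empty volume")
    vmax = float(vox.max())
    mask = vox > 0.05 * vmax if vmax > 0 else np.ones_like(vox, dtype=bool)
    if not mask.any():
        raise Kerato3dError("empty ROI: no supra-threshold voxels")
    roi_slices = []
    for ax in range(3):
        axes = tuple(a for a in range(3) if a != ax)
        occ = np.nonzero(mask.any(axis=axes))[0]
        lo, hi = int(occ[0]), int(occ[-1]) + 1
        pad = max(1, int(round(0.1 * (hi - lo))))
        roi_slices.append(slice(max(0, lo - pad), min(vox.shape[ax], hi + pad)))
    roi = vox[tuple(roi_slices)]
    e = cfg.input_edge
    # isotropic resample (largest ROI axis fills the cube) + centered zero
    # padding: preserves the cornea's height-to-width ratio, which carries
    # the severity signal
    factor = e / max(roi.shape)
    scaled = zoom(roi, factor, order=1)
    scaled = scaled[tuple(slice(0, e) for _ in range(3))]
    out = np.zeros((e, e, e), dtype=np.float32)
    offs = [(e - s) // 2 for s in scaled.shape]
    out[offs[0]: offs[0] + scaled.shape[0],
        offs[1]: offs[1] + scaled.shape[1],
        offs[2]: offs[2] + scaled.shape[2]] = scaled
    out = gaussian_filter(out, sigma=1.0)
    span = float(out.max() - out.min())
    if span > 0:
        out = (out - out.min()) / span
    return Volume3D(out.astype(np.float32), spacing=v.spacing)


#: target *between-sample* standard deviation of the last hidden (feature)
#: layer.  With a zero-initialized softmax layer, the first SGD step moves
#: the class logits by roughly lr * |p - y| * ||h_disc||^2, where h_disc is
#: the discriminative (batch-centered) feature component; for lr = 0.01 and
#: 1000 features, a between-sample std of ~0.15 makes that O(0.1-1) per
#: step - fast but stable.  The batch-common feature component cancels in
#: the softmax for class-balanced batches.
_FEATURE_BETWEEN_STD = 0.4


def _calibrate_init(model: KeratoconusCNN, probe: np.ndarray) -> None:
    """Variance-calibrated (LSUV-style) initialization.

    Forward a probe batch (spanning the classes) layer by layer; rescale
    each convolutional and hidden fully connected layer so its output
    standard deviation is 1; rescale the last hidden layer so the
    *between-sample* std of the feature vector is ``_FEATURE_BETWEEN_STD``;
    zero the softmax layer so initial logits vanish (initial loss =
    ln n_classes).  Deterministic given the model seed and the probe.
    """
    from .nn import Conv3d, Linear

    linear_layers = [l for l in model.net.layers if isinstance(l, Linear)]
    out_layer = linear_layers[-1]
    last_hidden = linear_layers[-2]
    a = model._to_batch(probe.astype(np.float32))
    for layer in model.net.layers:
        if layer is out_layer:
            layer.params["W"][:] = 0.0
            layer.params["b"][:] = 0.0
        if isinstance(layer, (Conv3d, Linear)) and layer is not out_layer:
            out = layer.forward(a)
            if layer is last_hidden and out.shape[1] > 1:
                # out: (features, batch); center per feature over the batch
                centered = out - out.mean(axis=1, keepdims=True)
                std = float(centered.std())
                target = _FEATURE_BETWEEN_STD
            else:
                std = float(out.std())
                target = 1.0
            if std > 0:
                gain = target / std
                layer.params["W"] *= gain
                layer.params["b"] *= gain
                out *= gain
            a = out
        else:
            a = layer.forward(a)


def _encode_labels(labels: list[str], classes: tuple[str, ...]) -> np.ndarray:
    try:
        return np.array([classes.index(lb) for lb in labels], dtype=np.intp)
    except ValueError as exc:
        raise Kerato3dError(f"unknown class label: {exc}") from exc


def train(
    model: KeratoconusCNN,
    volumes: list[Volume3D] | np.ndarray,
    labels: list[str],
    cfg: CnnConfig | None = None,
) -> KeratoconusCNN:
    """Train with SGD on cross-entropy; returns the model with its history.

    Volumes must already be preprocessed to ``input_edge^3``.  All classes
    must be present (stratified evaluation downstream assumes it).  The
    per-epoch history records the running training loss and accuracy over the
    epoch's batches (measured before each update, as the batches stream by).
    """
    cfg = cfg or model.cfg
    x = np.stack(
        [v.voxels if isinstance(v, Volume3D) else np.asarray(v) for v in volumes]
    ).astype(np.float32)
    y = _encode_labels(list(labels), model.classes)
    if len(x) < 8:
        raise Kerato3dError("need at least 8 labeled volumes")
    present = set(int(c) for c in np.unique(y))
    if present != set(range(model.cfg.n_classes)):
        raise Kerato3dError("every class must be present in the training set")

    # standardize inputs on training-set statistics (stored for inference)
    mu, sd = float(x.mean()), float(x.std())
    model.input_mean = mu
    model.input_std = sd if sd > 0 else 1.0
    x = ((x - model.input_mean) / model.input_std).astype(np.float32)

    if cfg.calibrate_init and not model.history["loss"]:
        # probe spans the label range (inputs are grouped by class in the
        # cohorts this trains on; a strided pick covers all of them)
        stride = max(1, len(x) // 4)
        probe_idx = np.arange(0, len(x), stride)[:4]
        _calibrate_init(model, x[probe_idx])

    rng = np.random.default_rng(cfg.seed + 1)
    n = len(x)
    chunk = max(1, int(cfg.accumulation_chunk))
    best: tuple[float, float] | None = None  # (accuracy, -loss) of checkpoint
    best_params: dict[str, np.ndarray] | None = None
    best_epoch = -1
    for epoch in range(cfg.epochs):
        if cfg.early_stop_patience is not None:
            # an epoch's running metrics describe (up to intra-epoch drift)
            # the parameters it STARTED from, so that is what gets
            # checkpointed if this epoch turns out to be the best
            pre_epoch_params = {
                k: v.copy() for k, v in model.net.parameters().items()
            }
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bsz = len(idx)
            acc = model.net.zero_grad_accumulators()
            for cstart in range(0, bsz, chunk):
                cidx = idx[cstart : cstart + chunk]
                logits = model.net.forward(model._to_batch(x[cidx]))
                loss, dlogits, probs = cross_entropy_with_grad(logits, y[cidx])
                epoch_loss += loss * len(cidx)
                epoch_hits += int(np.sum(probs.argmax(axis=0) == y[cidx]))
                # dlogits is averaged over the chunk; reweight to the batch
                model.net.backward(dlogits * (len(cidx) / bsz))
                model.net.accumulate_grads(acc, 1.0)
            model.net.sgd_step(acc, cfg.learning_rate)
        epoch_acc = epoch_hits / n
        model.history["loss"].append(epoch_loss / n)
        model.history["accuracy"].append(epoch_acc)
        score = (epoch_acc, -epoch_loss / n)
        if cfg.early_stop_patience is not None:
            if best is None or score > best:
                best = score
                best_epoch = epoch
                best_params = pre_epoch_params
            if (
                cfg.early_stop_accuracy is not None
                and epoch_acc >= cfg.early_stop_accuracy
            ):
                break
            if epoch - best_epoch >= cfg.early_stop_patience:
                break
        elif (
            cfg.early_stop_accuracy is not None
            and epoch_acc >= cfg.early_stop_accuracy
        ):
            break
    if best_params is not None:
        model.net.load_parameters(best_params)
        model.history["best_epoch"] = [best_epoch]
        model.history["best_accuracy"] = [best[0]]
    return model


def predict(model: KeratoconusCNN, volume: Volume3D | np.ndarray) -> tuple[np.ndarray, str]:
    """Class probabilities and the arg-max label for one preprocessed volume.

    Ties break toward the lower class index (normal < mild < moderate <
    severe).
    """
    vox = volume.voxels if isinstance(volume, Volume3D) else np.asarray(volume)
    probs = model.predict_proba(vox.astype(np.float32)[None])[0]
    return probs, model.classes[int(np.argmax(probs))]


def save_model(model: KeratoconusCNN, path: str | Path) -> None:
    """Single-file archive: parameters + embedded config + history."""
    meta = json.dumps(
        {"config": asdict(model.cfg), "history": model.history,
         "input_mean": model.input_mean, "input_std": model.input_std}
    )
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **model.net.parameters())


def load_model(path: str | Path) -> KeratoconusCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        model = KeratoconusCNN(CnnConfig(**cfg_dict))
        model.net.load_parameters(
            {k: data[k] for k in data.files if k != "__meta__"}
        )
        model.history = meta["history"]
        model.input_mean = meta.get("input_mean", 0.0)
        model.input_std = meta.get("input_std", 1.0)
    return model
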