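"""Fast-Unet++ segmentation network: configuration, builder, FLOPs, training.

The architecture is a fully convolutional encoder/decoder with *no pooling
layers*: the encoder downsamples with 5x5 convolutions at stride 2 (leaky
ReLU 0.2, batch norm), decoding upsamples with 5x5 transposed convolutions
at stride 2.  The nested (``++``) variant inserts a triangular grid of
nodes X[i][j] between encoder and output: a j=1 node fuses the same-level
encoder feature with an up-convolved copy of the next deeper level; a
j>=2 node additionally receives the previous node of its own level.  Each
node is an up-convolution + ReLU + batch norm on the deeper input, with
the same-resolution inputs merged by concatenation and a learned 1x1
fusion convolution.  With deep supervision every top-level node output is
concatenated into the final up-convolution that produces the
single-channel sigmoid probability map at input resolution.

Analytic cost accounting uses ``FLOPs = 2 K^2 C_in C_out N`` per
convolutional layer, with N the number of output spatial positions.  The
default filter widths (14, 28, 56, 112, 224) are frozen so that the total
for a 320x480 single-channel input is ~1.5e10 FLOPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .types import ScanImage

DEFAULT_FILTERS = (14, 28, 56, 112, 224)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters."""

    depth: int = 5
    filters_per_level: Tuple[int, ...] = DEFAULT_FILTERS
    kernel_size: int = 5
    encoder_stride: int = 2
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5
    input_shape: Tuple[int, int, int] = (320, 480, 1)
    nested: bool = True
    deep_supervision: bool = True

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.filters_per_level) != self.depth:
            raise ValueError(
                f"filters_per_level must have {self.depth} entries, "
                f"got {len(self.filters_per_level)}"
            )
        if any(f < 1 for f in self.filters_per_level):
            raise ValueError("all filter counts must be >= 1")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        rows, cols, ch = self.input_shape
        div = self.encoder_stride**self.depth
        if rows % div or cols % div:
            raise ValueError(
                f"input rows and cols must be divisible by "
                f"{self.encoder_stride}^{self.depth} = {div}; got {rows}x{cols}"
            )
        if ch != 1:
            raise ValueError("grayscale (single-channel) input required")


@dataclass
class TrainConfig:
    """Training hyperparameters: Adam, batch 32, 47 epochs, N(0, 0.02) init."""

    batch_size: int = 32
    max_steps: int = 47
    learning_rate: float = 1e-4
    init_std: float = 0.02
    loss: str = "dice"
    seed: int = 0
    validation_fraction: float = 0.2
    shuffle_each_epoch: bool = True

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.loss != "dice":
            raise ValueError(f"unknown loss {self.loss!r}")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class FlopsReport:
    """Per-convolution FLOPs via 2*K^2*C_in*C_out*N and their sum."""

    per_layer: List[tuple] = field(default_factory=list)  # (name, K, C_in, C_out, N, flops)
    total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_layer, columns=["layer", "K", "C_in", "C_out", "N", "flops"]
        )


# ---------------------------------------------------------------------------
# architecture plan: one declarative walk shared by the builder and FLOPs
# ---------------------------------------------------------------------------


def layer_plan(config: NetworkConfig) -> List[dict]:
    """Declarative layer list: dicts with op, name, inputs, out, and conv geometry."""
    config.validate()
    rows, cols, _ = config.input_shape
    d = config.depth
    f = list(config.filters_per_level)
    k = config.kernel_size
    s = config.encoder_stride
    hw = [(rows // s ** (i + 1), cols // s ** (i + 1)) for i in range(d)]
    steps: List[dict] = []

    def conv(name, inp, c_in, c_out, kk, stride, out_hw, out):
        steps.append(
            dict(op="conv", name=name, inputs=[inp], out=out, k=kk, c_in=c_in,
                 c_out=c_out, stride=stride, out_hw=out_hw)
        )

    def convT(name, inp, c_in, c_out, out_hw, out):
        steps.append(
            dict(op="convT", name=name, inputs=[inp], out=out, k=k, c_in=c_in,
                 c_out=c_out, stride=s, out_hw=out_hw)
        )

    def simple(op, name, inp, out, **extra):
        steps.append(dict(op=op, name=name, inputs=[inp], out=out, **extra))

    # encoder: depth strided convolutions, no pooling anywhere
    prev, c_prev = "input", 1
    for i in range(d):
        conv(f"enc{i}", prev, c_prev, f[i], k, s, hw[i], f"enc{i}_raw")
        simple("lrelu", f"enc{i}_act", f"enc{i}_raw", f"enc{i}_a", slope=config.leaky_slope)
        simple("bn", f"enc{i}_bn", f"enc{i}_a", f"x{i}_0", channels=f[i])
        prev, c_prev = f"x{i}_0", f[i]

    if config.nested:
        # nested grid X[i][j]: up-convolve the deeper node, ReLU+BN, then
        # concatenate the same-level inputs and fuse with a 1x1 convolution
        for j in range(1, d):
            for i in range(0, d - j):
                up_in = f"x{i + 1}_{j - 1}"
                convT(f"n{i}_{j}_up", up_in, f[i + 1], f[i], hw[i], f"n{i}_{j}_upr")
                simple("relu", f"n{i}_{j}_act", f"n{i}_{j}_upr", f"n{i}_{j}_a")
                simple("bn", f"n{i}_{j}_bn", f"n{i}_{j}_a", f"n{i}_{j}_b", channels=f[i])
                merge = [f"n{i}_{j}_b"]
                if j >= 2:
                    merge.append(f"x{i}_{j - 1}")
                merge.append(f"x{i}_0")
                steps.append(dict(op="concat", name=f"n{i}_{j}_cat", inputs=merge,
                                  out=f"n{i}_{j}_c"))
                conv(f"n{i}_{j}_fuse", f"n{i}_{j}_c", len(merge) * f[i], f[i], 1, 1,
                     hw[i], f"x{i}_{j}")
        tops = [f"x0_{j}" for j in range(1, d)] if config.deep_supervision else [f"x0_{d - 1}"]
        if len(tops) > 1:
            steps.append(dict(op="concat", name="head_cat", inputs=tops, out="head_c"))
            head_in, head_cin = "head_c", len(tops) * f[0]
        else:
            head_in, head_cin = tops[0], f[0]
    else:
        # plain Fast-Unet decoder: up-convolution, ReLU, dropout, batch norm,
        # then a direct skip concatenation with the same-level encoder output
        cur, c_cur = f"x{d - 1}_0", f[d - 1]
        for i in range(d - 2, -1, -1):
            convT(f"dec{i}_up", cur, c_cur, f[i], hw[i], f"dec{i}_raw")
            simple("relu", f"dec{i}_act", f"dec{i}_raw", f"dec{i}_a")
            simple("dropout", f"dec{i}_drop", f"dec{i}_a", f"dec{i}_d",
                   rate=config.dropout_rate)
            simple("bn", f"dec{i}_bn", f"dec{i}_d", f"dec{i}_b", channels=f[i])
            steps.append(dict(op="concat", name=f"dec{i}_cat",
                              inputs=[f"dec{i}_b", f"x{i}_0"], out=f"dec{i}_c"))
            cur, c_cur = f"dec{i}_c", 2 * f[i]
        head_in, head_cin = cur, c_cur

    convT("head_up", head_in, head_cin, f[0], (rows, cols), "head_raw")
    simple("relu", "head_act", "head_raw", "head_a")
    conv("head_out", "head_a", f[0], 1, 1, 1, (rows, cols), "logits")
    simple("sigmoid", "head_sig", "logits", "output")
    return steps


def count_flops(config: NetworkConfig) -> FlopsReport:
    """Analytic FLOPs of every convolutional layer; no model instantiation."""
    report = FlopsReport()
    for step in layer_plan(config):
        if step["op"] not in ("conv", "convT"):
            continue
        n = step["out_hw"][0] * step["out_hw"][1]
        flops = 2 * step["k"] ** 2 * step["c_in"] * step["c_out"] * n
        report.per_layer.append(
            (step["name"], step["k"], step["c_in"], step["c_out"], n, flops)
        )
        report.total += flops
    return report


class SegmentationModel:
    """Executable DAG of layers built from a layer plan."""

    def __init__(self, config: NetworkConfig, init_std: float = 0.02, seed: int = 0):
        config.validate()
        self.config = config
        self.plan = layer_plan(config)
        rng = np.random.default_rng(seed)
        self.layers = {}
        for step in self.plan:
            op = step["op"]
            if op == "conv":
                layer = nn.Conv2D(step["c_in"], step["c_out"], step["k"],
                                  step["stride"], init_std, rng)
            elif op == "convT":
                layer = nn.ConvTranspose2D(step["c_in"], step["c_out"], step["k"],
                                           step["stride"], init_std, rng)
            elif op == "bn":
                layer = nn.BatchNorm2D(step["channels"])
            elif op == "lrelu":
                layer = nn.LeakyReLU(step["slope"])
            elif op == "relu":
                layer = nn.ReLU()
            elif op == "dropout":
                layer = nn.Dropout(step["rate"])
            elif op == "concat":
                layer = nn.Concat()
            elif op == "sigmoid":
                layer = nn.Sigmoid()
            else:  # pragma: no cover
                raise ValueError(f"unknown op {op}")
            self.layers[step["name"]] = layer

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list:
        out = []
        for step in self.plan:
            out.extend(self.layers[step["name"]].params())
        return out

    def gradients(self) -> list:
        out = []
        for step in self.plan:
            out.extend(self.layers[step["name"]].grads())
        return out

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def get_weights(self) -> list:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def save_weights(self, path) -> None:
        np.savez_compressed(path, *self.parameters())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """x: (N, H, W) or (N, 1, H, W) float in [0, 1] -> probabilities."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        values = {"input": np.ascontiguousarray(x, dtype=np.float32)}
        rng = rng or np.random.default_rng(0)
        for step in self.plan:
            xs = [values[name] for name in step["inputs"]]
            values[step["out"]] = self.layers[step["name"]].forward(xs, training, rng)
        self._values = values
        return values["output"]

    def backward(self, gout: np.ndarray) -> None:
        grads = {"output": gout}
        for step in reversed(self.plan):
            g = grads.pop(step["out"], None)
            if g is None:
                continue
            gxs = self.layers[step["name"]].backward(g)
            for name, gx in zip(step["inputs"], gxs):
                if name in grads:
                    grads[name] = grads[name] + gx
                else:
                    grads[name] = gx

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)


def build_model(config: NetworkConfig, init_std: float = 0.02, seed: int = 0) -> SegmentationModel:
    """Instantiate a Fast-Unet++ (nested) or Fast-Unet (plain) model."""
    return SegmentationModel(config, init_std=init_std, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _as_xy(dataset):
    if isinstance(dataset, tuple) and len(dataset) == 2:
        x, y = dataset
    else:
        pairs = list(dataset)
        if not pairs:
            raise ValueError("empty dataset")
        x = np.stack([p[0] for p in pairs])
        y = np.stack([p[1] for p in pairs])
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    if len(x) == 0:
        raise ValueError("empty dataset")
    if x.shape != y.shape:
        raise ValueError(f"image/mask shape mismatch: {x.shape} vs {y.shape}")
    if not np.isin(np.unique(y), [0, 1]).all():
        raise ValueError("masks must be binary")
    return x, y.astype(np.float32)


def train(model: SegmentationModel, dataset, tc: TrainConfig):
    """Train with dice loss and Adam; returns (model, history DataFrame).

    One step is one pass over the training split.  The weights with the
    best validation DSC are kept and restored at the end; the history has
    one row per completed step with the mean training loss and the
    validation DSC.
    """
    tc.validate()
    x, y = _as_xy(dataset)
    rng = np.random.default_rng(tc.seed)
    n = len(x)
    idx = rng.permutation(n)
    n_val = int(round(tc.validation_fraction * n))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples after validation split")
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    history = []
    best = (-1.0, None)
    order = np.arange(len(xt))
    for step in range(1, tc.max_steps + 1):
        if tc.shuffle_each_epoch:
            order = rng.permutation(len(xt))
        losses = []
        for b0 in range(0, len(xt), tc.batch_size):
            bidx = order[b0 : b0 + tc.batch_size]
            model.zero_grad()
            p = model.forward(xt[bidx], training=True, rng=rng)
            loss, gp = nn.dice_loss_and_grad(p, yt[bidx][:, None])
            model.backward(gp)
            opt.step(model.gradients())
            losses.append(loss)
        val_dsc = _validation_dsc(model, xv, yv) if len(xv) else float("nan")
        history.append({"step": step, "loss": float(np.mean(losses)), "val_dsc": val_dsc})
        if len(xv) and val_dsc > best[0]:
            best = (val_dsc, model.get_weights())
    if best[1] is not None:
        model.set_weights(best[1])
    return model, pd.DataFrame(history)


def _validation_dsc(model, xv, yv, batch: int = 8) -> float:
    scores = []
    for b0 in range(0, len(xv), batch):
        p = model.forward(xv[b0 : b0 + batch], training=False)
        for pi, yi in zip(p[:, 0], yv[b0 : b0 + batch]):
            scores.append(nn.dice_coefficient(pi > 0.5, yi > 0.5))
    return float(np.mean(scores))


def postprocess_probability(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise at 0.5, keep the largest 8-connected component, fill holes."""
    binary = prob > threshold
    if not binary.any():
        return binary
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        binary = labels == (int(np.argmax(counts)) + 1)
    return ndimage.binary_fill_holes(binary)


def predict_mask(model: SegmentationModel, image) -> Tuple[np.ndarray, np.ndarray]:
    """Probability map and post-processed binary mask in the image frame.

    Images whose size differs from the model input are resized for
    inference and the probability map is mapped back to the original
    frame before thresholding.
    """
    pixels = image.pixels if isinstance(image, ScanImage) else np.asarray(image)
    if pixels.ndim != 2:
        raise ValueError("a 2-D grayscale image is required")
    pixels = pixels.astype(np.float32)
    if pixels.max() > 1.0:
        pixels = pixels / 255.0
    rows, cols, _ = model.config.input_shape
    orig_shape = pixels.shape
    net_in = pixels
    if orig_shape != (rows, cols):
        net_in = resize(pixels, (rows, cols), order=1, preserve_range=True,
                        anti_aliasing=True).astype(np.float32)
    prob = model.forward(net_in[None], training=False)[0, 0]
    if orig_shape != (rows, cols):
        prob = resize(prob, orig_shape, order=1, preserve_range=True)
    mask = postprocess_probability(prob)
    return prob, mask


def grid_search(grid: dict, train_fn: Callable, eval_fn: Callable):
    """Exhaustive hyperparameter search maximising mean validation DSC.

    ``grid`` maps parameter names to value lists; every combination is
    trained with ``train_fn(params_dict)`` and scored with
    ``eval_fn(trained)``.  Ties keep the first combination in iteration
    order.  Returns (best_params, best_score, results).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    keys = list(grid.keys())
    best_params, best_score = None, -np.inf
    results = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        trained = train_fn(params)
        score = float(eval_fn(trained))
        results.append({**params, "mean_dsc": score})
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score, pd.DataFrame(results)


# ---------------------------------------------------------------------------
# scikit-learn style estimator facade
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class FastUnetSegmenter(BaseEstimator):
    """Scikit-learn style estimator wrapping Fast-Unet(++) training.

    Parameters mirror NetworkConfig / TrainConfig; ``fit(X, y)`` expects
    ``X`` of shape (n, rows, cols) with values in [0, 1] and binary ``y``
    of the same shape.  Fitted attributes: ``model_``, ``history_``,
    ``config_``.
    """

    def __init__(self, nested=True, depth=5, filters_per_level=None, base_filters=14,
                 kernel_size=5, deep_supervision=True, dropout_rate=0.5,
                 leaky_slope=0.2, learning_rate=1e-4, batch_size=32, max_steps=47,
                 validation_fraction=0.2, init_std=0.02, shuffle_each_epoch=True,
                 random_state=0):
        self.nested = nested
        self.depth = depth
        self.filters_per_level = filters_per_level
        self.base_filters = base_filters
        self.kernel_size = kernel_size
        self.deep_supervision = deep_supervision
        self.dropout_rate = dropout_rate
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.validation_fraction = validation_fraction
        self.init_std = init_std
        self.shuffle_each_epoch = shuffle_each_epoch
        self.random_state = random_state

    def _make_config(self, rows, cols) -> NetworkConfig:
        filters = self.filters_per_level
        if filters is None:
            filters = tuple(self.base_filters * 2**i for i in range(self.depth))
        return NetworkConfig(
            depth=self.depth,
            filters_per_level=tuple(filters),
            kernel_size=self.kernel_size,
            leaky_slope=self.leaky_slope,
            dropout_rate=self.dropout_rate,
            input_shape=(rows, cols, 1),
            nested=self.nested,
            deep_supervision=self.deep_supervision,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_samples, rows, cols)")
        self.config_ = self._make_config(X.shape[1], X.shape[2])
        tc = TrainConfig(
            batch_size=self.batch_size,
            max_steps=self.max_steps,
            learning_rate=self.learning_rate,
            init_std=self.init_std,
            seed=self.random_state,
            validation_fraction=self.validation_fraction,
            shuffle_each_epoch=self.shuffle_each_epoch,
        )
        model = build_model(self.config_, init_std=self.init_std, seed=self.random_state)
        self.model_, self.history_ = train(model, (X, y), tc)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        out = []
        for b0 in range(0, len(X), 8):
            out.append(self.model_.forward(X[b0 : b0 + 8], training=False)[:, 0])
        return np.concatenate(out)

    def predict(self, X):
        prob = self.predict_proba(X)
        return np.stack([postprocess_probability(p) for p in prob])

    def score(self, X, y):
        """Mean DSC over the provided samples."""
        masks = self.predict(X)
        return float(np.mean([nn.dice_coefficient(m, t > 0.5) for m, t in zip(masks, np.asarray(y))]))
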