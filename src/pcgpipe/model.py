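"""Binary PCG image classifier: convolutional backbone + trainable head.

The classifier follows the transfer-learning pattern: a convolutional
feature-extraction stack, then a six-layer head — GlobalAveragePooling,
three fully connected ReLU layers (256/128/64), one BatchNormalization
layer, and a single sigmoid output unit giving P(abnormal).  Training uses
stochastic gradient descent (batch size 5, 30 epochs, learning rate 1e-4,
momentum 0.9) with binary cross-entropy loss.

Everything is implemented in numpy.  The backbone registry carries the 17
classic ImageNet architectures by name as *randomly initialized* stand-in
conv stacks (no pretrained weight zoo is bundled; building one logs a
warning), plus ``tinycnn``, a small three-block stack intended for
desk-scale experiments and tests.  By default the backbone is frozen and
only the head trains; ``freeze_backbone=False`` backpropagates through the
conv stack as well.

Numerical conventions: GAP features are standardized with training-set
mean/scale before the dense stack, and the final output layer is
zero-initialized so optimization starts as a linear probe on the head's
penultimate features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "HeadSpec",
    "TrainConfig",
    "BACKBONE_REGISTRY",
    "build_model",
    "train",
    "predict",
    "PcgClassifier",
]

logger = logging.getLogger(__name__)

_EPS = 1e-5


@dataclass(frozen=True)
class HeadSpec:
    dense_sizes: tuple[int, int, int] = (256, 128, 64)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 5
    epochs: int = 30
    learning_rate: float = 1e-4
    momentum: float = 0.9
    input_size: tuple[int, int] = (640, 480)  # (width, height)
    backbone: str = "tinycnn"
    freeze_backbone: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("batch_size must be positive and epochs nonnegative")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass(frozen=True)
class BackboneSpec:
    channels: tuple[int, ...]
    downsample: int  # input average-pool factor before the conv stack
    pretrained_available: bool = False


# tinycnn is the tested desk-scale stack; the named entries mirror the depth
# ordering of the classic ImageNet families but carry no pretrained weights.
BACKBONE_REGISTRY: dict[str, BackboneSpec] = {
    "tinycnn": BackboneSpec(channels=(32, 64, 128), downsample=8),
    "VGG16": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "VGG19": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "Xception": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "ResNet50": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "ResNet50V2": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "ResNet101": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "ResNet101V2": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "ResNet152": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "ResNet152V2": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "InceptionV3": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "InceptionResNetV2": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "MobileNet": BackboneSpec(channels=(16, 32, 64), downsample=4),
    "MobileNetV2": BackboneSpec(channels=(16, 32, 64), downsample=4),
    "NASNetMobile": BackboneSpec(channels=(16, 32, 64), downsample=4),
    "DenseNet121": BackboneSpec(channels=(16, 32, 64, 128), downsample=4),
    "DenseNet169": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
    "DenseNet201": BackboneSpec(channels=(16, 32, 64, 128, 128), downsample=4),
}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(H, W, C) -> (H*W, k*k*C) patch matrix with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (H, W, C, k, k)
    h, w = x.shape[0], x.shape[1]
    return win.transpose(0, 1, 3, 4, 2).reshape(h * w, k * k * x.shape[2])


def _col2im(grad_col: np.ndarray, shape: tuple[int, int, int], k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    h, w, c = shape
    p = k // 2
    grad_pad = np.zeros((h + 2 * p, w + 2 * p, c))
    g = grad_col.reshape(h, w, k, k, c)
    for di in range(k):
        for dj in range(k):
            grad_pad[di : di + h, dj : dj + w, :] += g[:, :, di, dj, :]
    return grad_pad[p : p + h, p : p + w, :]


class _ConvBlock:
    """3x3 same conv -> ReLU -> 2x2 max pool."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = 9 * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(9 * c_in, c_out))
        self.b = np.zeros(c_out)
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        h, w, _ = x.shape
        col = _im2col(x)
        pre = (col @ self.W + self.b).reshape(h, w, self.c_out)
        act = np.maximum(pre, 0.0)
        he, we = (h // 2) * 2, (w // 2) * 2
        pooled_view = act[:he, :we].reshape(h // 2, 2, w // 2, 2, self.c_out)
        out = pooled_view.max(axis=(1, 3))
        if keep_cache:
            self._cache = (x.shape, col, pre, act, out)
        return out

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (grad_x, grad_W, grad_b); requires a cached forward."""
        x_shape, col, pre, act, out = self._cache
        h, w, _ = x_shape
        he, we = (h // 2) * 2, (w // 2) * 2
        grad_act = np.zeros_like(act)
        window = act[:he, :we].reshape(h // 2, 2, w // 2, 2, self.c_out)
        mask = window == out[:, None, :, None, :]
        # split ties evenly so the adjoint stays exact
        mask = mask / np.maximum(mask.sum(axis=(1, 3), keepdims=True), 1)
        grad_act[:he, :we] = (mask * grad_out[:, None, :, None, :]).reshape(he, we, self.c_out)
        grad_pre = grad_act * (pre > 0)
        grad_flat = grad_pre.reshape(h * w, self.c_out)
        grad_W = col.T @ grad_flat
        grad_b = grad_flat.sum(axis=0)
        grad_x = _col2im(grad_flat @ self.W.T, x_shape)
        return grad_x, grad_W, grad_b


class Backbone:
    """Average-pool downsampling followed by a stack of conv blocks."""

    def __init__(self, name: str, seed: int):
        if name not in BACKBONE_REGISTRY:
            raise ValueError(
                f"unknown backbone {name!r}; registry: {sorted(BACKBONE_REGISTRY)}"
            )
        spec = BACKBONE_REGISTRY[name]
        if not spec.pretrained_available and name != "tinycnn":
            logger.warning(
                "backbone %s has no bundled pretrained weights; using random init", name
            )
        rng = np.random.default_rng(seed)
        self.name = name
        self.downsample = spec.downsample
        self.blocks: list[_ConvBlock] = []
        # CoordConv-style extra channel: spectrogram rows are absolute
        # frequency positions, which translation-invariant convs + GAP would
        # otherwise erase, so the input carries a normalized row coordinate.
        c_in = 4
        for c_out in spec.channels:
            self.blocks.append(_ConvBlock(c_in, c_out, rng))
            c_in = c_out
        self.n_features = c_in
        self._down_shape = None

    def _downsample(self, img: np.ndarray) -> np.ndarray:
        f = self.downsample
        h = (img.shape[0] // f) * f
        w = (img.shape[1] // f) * f
        x = img[:h, :w].reshape(h // f, f, w // f, f, img.shape[2]).mean(axis=(1, 3))
        rows = np.linspace(0.0, 1.0, x.shape[0])[:, None, None]
        coord = np.broadcast_to(rows, (x.shape[0], x.shape[1], 1))
        return np.concatenate([x, coord], axis=2)

    def forward(self, img: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Image (H, W, 3) in [0, 1] -> spatial feature map (h', w', C)."""
        x = self._downsample(np.asarray(img, dtype=np.float64))
        if keep_cache:
            self._down_shape = (img.shape, x.shape)
        for block in self.blocks:
            x = block.forward(x, keep_cache=keep_cache)
        return x

    def backward(self, grad_map: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        grads = []
        g = grad_map
        for block in reversed(self.blocks):
            g, gW, gb = block.backward(g)
            grads.append((gW, gb))
        return list(reversed(grads))

    def parameters(self) -> list[np.ndarray]:
        out = []
        for b in self.blocks:
            out.extend([b.W, b.b])
        return out


class PcgClassifier:
    """Backbone + head with SGD training; probabilities are P(abnormal)."""

    def __init__(self, backbone_name: str, head: HeadSpec, cfg: TrainConfig):
        self.cfg = cfg
        self.head_spec = head
        self.backbone = Backbone(backbone_name, seed=cfg.seed)
        rng = np.random.default_rng(cfg.seed + 1)
        sizes = (self.backbone.n_features, *head.dense_sizes)
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            self.params[f"W{i + 1}"] = rng.normal(
                0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1])
            )
            self.params[f"b{i + 1}"] = np.zeros(sizes[i + 1])
        last = head.dense_sizes[-1]
        self.params["gamma"] = np.ones(last)
        self.params["beta"] = np.zeros(last)
        self.params["W4"] = np.zeros((last, 1))  # linear-probe start
        self.params["b4"] = np.zeros(1)
        self.bn_running_mean = np.zeros(last)
        self.bn_running_var = np.ones(last)
        self.feat_mean = np.zeros(self.backbone.n_features)
        self.feat_scale = np.ones(self.backbone.n_features)
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # ---- feature extraction -------------------------------------------------

    def extract_features(self, images, keep_cache: bool = False) -> np.ndarray:
        """GAP feature vectors, one row per image."""
        feats = []
        for img in images:
            arr = _image_array(img)
            fmap = self.backbone.forward(arr, keep_cache=keep_cache)
            feats.append(fmap.mean(axis=(0, 1)))
        return np.asarray(feats)

    # ---- head forward / backward -------------------------------------------

    def _head_forward(self, F: np.ndarray, training: bool):
        z = (F - self.feat_mean) / self.feat_scale
        cache = {"z": z}
        h = z
        for i in range(3):
            pre = h @ self.params[f"W{i + 1}"] + self.params[f"b{i + 1}"]
            h = np.maximum(pre, 0.0)
            cache[f"pre{i + 1}"] = pre
            cache[f"h{i + 1}"] = h
        if training:
            mean = h.mean(axis=0)
            var = h.var(axis=0)
            self.bn_running_mean = 0.9 * self.bn_running_mean + 0.1 * mean
            self.bn_running_var = 0.9 * self.bn_running_var + 0.1 * var
        else:
            mean, var = self.bn_running_mean, self.bn_running_var
        inv_std = 1.0 / np.sqrt(var + _EPS)
        xhat = (h - mean) * inv_std
        y = self.params["gamma"] * xhat + self.params["beta"]
        logit = (y @ self.params["W4"] + self.params["b4"]).ravel()
        prob = _sigmoid(logit)
        cache.update({"xhat": xhat, "inv_std": inv_std, "y": y, "prob": prob, "hbn": h})
        return prob, cache

    def _head_backward(self, cache: dict, targets: np.ndarray) -> dict[str, np.ndarray]:
        B = len(targets)
        grads: dict[str, np.ndarray] = {}
        dlogit = (cache["prob"] - targets)[:, None] / B  # BCE through sigmoid
        grads["W4"] = cache["y"].T @ dlogit
        grads["b4"] = dlogit.sum(axis=0)
        dy = dlogit @ self.params["W4"].T
        grads["gamma"] = (dy * cache["xhat"]).sum(axis=0)
        grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        inv_std = cache["inv_std"]
        h = cache["hbn"]
        mean = h.mean(axis=0)
        dvar = np.sum(dxhat * (h - mean), axis=0) * -0.5 * inv_std**3
        dmean = -np.sum(dxhat, axis=0) * inv_std + dvar * -2.0 * np.mean(h - mean, axis=0)
        dh = dxhat * inv_std + dvar * 2.0 * (h - mean) / B + dmean / B
        for i in range(3, 0, -1):
            dpre = dh * (cache[f"pre{i}"] > 0)
            prev = cache["z"] if i == 1 else cache[f"h{i - 1}"]
            grads[f"W{i}"] = prev.T @ dpre
            grads[f"b{i}"] = dpre.sum(axis=0)
            dh = dpre @ self.params[f"W{i}"].T
        grads["_dz"] = dh  # gradient w.r.t. standardized features
        return grads

    # ---- training -----------------------------------------------------------

    def fit(self, images, labels, verbose: bool = False) -> "PcgClassifier":
        cfg = self.cfg
        targets = _targets(labels)
        if len(set(targets.tolist())) < 2:
            raise ValueError("training requires at least one example of each class")
        rng = np.random.default_rng(cfg.seed + 2)
        images = list(images)
        frozen = cfg.freeze_backbone
        if frozen:
            F_all = self.extract_features(images)
        else:
            F_all = self.extract_features(images)  # stats only
        self.feat_mean = F_all.mean(axis=0)
        scale = F_all.std(axis=0)
        scale[scale == 0] = 1.0
        self.feat_scale = scale

        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        bb_params = self.backbone.parameters()
        bb_velocity = [np.zeros_like(p) for p in bb_params]
        n = len(images)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                y = targets[batch]
                if frozen:
                    F = F_all[batch]
                else:
                    F = self.extract_features([images[i] for i in batch], keep_cache=True)
                prob, cache = self._head_forward(F, training=True)
                p = np.clip(prob, 1e-12, 1.0 - 1e-12)
                loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
                epoch_loss += loss * len(batch)
                epoch_correct += int(np.sum((prob >= 0.5) == (y == 1)))
                grads = self._head_backward(cache, y)
                dz = grads.pop("_dz")
                for k, g in grads.items():
                    velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * g
                    self.params[k] += velocity[k]
                if not frozen:
                    dF = dz / self.feat_scale
                    self._backbone_update(batch, images, dF, bb_params, bb_velocity)
            self.history["loss"].append(epoch_loss / n)
            self.history["accuracy"].append(epoch_correct / n)
            if verbose:
                logger.info(
                    "epoch %d: loss=%.4f acc=%.3f",
                    len(self.history["loss"]),
                    self.history["loss"][-1],
                    self.history["accuracy"][-1],
                )
        return self

    def _backbone_update(self, batch, images, dF, bb_params, bb_velocity) -> None:
        cfg = self.cfg
        accum = [np.zeros_like(p) for p in bb_params]
        for j, idx in enumerate(batch):
            arr = _image_array(images[idx])
            fmap = self.backbone.forward(arr, keep_cache=True)
            grad_map = np.broadcast_to(
                dF[j] / (fmap.shape[0] * fmap.shape[1]), fmap.shape
            )
            grads = self.backbone.backward(np.ascontiguousarray(grad_map))
            flat = [g for pair in grads for g in pair]
            for a, g in zip(accum, flat):
                a += g
        for p, v, g in zip(bb_params, bb_velocity, accum):
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            p += v

    def predict_proba(self, images) -> np.ndarray:
        F = self.extract_features(images)
        prob, _ = self._head_forward(F, training=False)
        return prob

    def predict_label(self, images, threshold: float = 0.5) -> list[str]:
        return ["abnormal" if p >= threshold else "normal" for p in self.predict_proba(images)]

    def parameter_checksum(self) -> float:
        total = sum(float(np.abs(p).sum()) for p in self.params.values())
        total += sum(float(np.abs(p).sum()) for p in self.backbone.parameters())
        return total

    def backbone_checksum(self) -> float:
        return sum(float(np.abs(p).sum()) for p in self.backbone.parameters())


def _image_array(img) -> np.ndarray:
    """Accept SpectrogramImage, uint8 array, or float array in [0, 1]."""
    pixels = getattr(img, "pixels", img)
    arr = np.asarray(pixels)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


def _targets(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in ("normal", "abnormal"):
                raise ValueError(f"unknown label {lab!r}")
            out.append(1.0 if lab == "abnormal" else 0.0)
        else:
            out.append(float(lab))
    return np.asarray(out)


def build_model(
    backbone_name: str, head: HeadSpec | None = None, cfg: TrainConfig | None = None
) -> PcgClassifier:
    """Assemble backbone + head; architecture and init are seed-deterministic."""
    cfg = cfg or TrainConfig()
    if cfg.backbone != backbone_name:
        cfg = replace(cfg, backbone=backbone_name)
    return PcgClassifier(backbone_name, head or HeadSpec(), cfg)


def train(model: PcgClassifier, images, labels, cfg: TrainConfig | None = None) -> PcgClassifier:
    """Functional wrapper over :meth:`PcgClassifier.fit`."""
    if cfg is not None:
        model.cfg = cfg
    return model.fit(images, labels)


def predict(model: PcgClassifier, images) -> np.ndarray:
    return model.predict_proba(images)
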