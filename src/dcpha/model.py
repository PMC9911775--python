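"""Asymmetric hash auto-encoder with semantics-preserving attention branches.

One encoder per modality (pseudo-Siamese: identical architecture, unshared
weights) extracts a D-dimensional feature from a Z-dimensional sample; a
single *shared* lightweight fully-connected decoder maps features to relaxed
hash codes in (−1, 1) through a tanh; two linear multi-layer classification
heads (SPAB_E on features, SPAB_D on codes) predict the class so that both
features and codes stay semantically consistent.  Binarization is the sign
function with sign(0) = +1.

Backbones: ``mlp`` (flat input, default at desk scale), ``tiny_cnn`` (three
convolutions on a 2-D slice) and ``alexnet_like`` (a deeper five-convolution
stack of the same family, scaled to CPU use).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigError, DimensionError
from .similarity import CodeMatrix

BACKBONES = ("mlp", "tiny_cnn", "alexnet_like")


@dataclass
class ModelConfig:
    n_modalities: int = 2
    input_dim_or_shape: int | tuple[int, int] = 64
    feature_dim: int = 16
    code_bits: int = 16
    n_classes: int = 3
    backbone: str = "mlp"
    seed: int = 0
    hidden_dim: int = 64  # hidden width of the mlp encoder

    def __post_init__(self):
        if isinstance(self.input_dim_or_shape, list):
            self.input_dim_or_shape = tuple(self.input_dim_or_shape)
        if self.backbone not in BACKBONES:
            raise ConfigError(f"backbone must be one of {BACKBONES}, got {self.backbone!r}")
        if self.backbone != "mlp" and not isinstance(self.input_dim_or_shape, tuple):
            raise ConfigError("convolutional backbones require a 2-D input shape")
        if self.n_modalities < 1:
            raise ConfigError("need at least one modality")
        if self.code_bits < 1:
            raise ConfigError("code_bits must be >= 1")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.feature_dim >= self.flat_input_dim:
            raise ConfigError(
                f"feature_dim D={self.feature_dim} must be < input dim "
                f"Z={self.flat_input_dim} (the encoder compresses)")

    @property
    def flat_input_dim(self) -> int:
        if isinstance(self.input_dim_or_shape, tuple):
            return int(np.prod(self.input_dim_or_shape))
        return int(self.input_dim_or_shape)


@dataclass
class ForwardOutput:
    """Stacked per-modality outputs of one forward pass (plain arrays)."""

    features: np.ndarray       # (M, N, D)
    relaxed_codes: np.ndarray  # (M, N, K), entries in (−1, 1)
    y_preds: np.ndarray        # (M, N, C), rows sum to 1
    r_preds: np.ndarray        # (M, N, C)


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------

def _linear(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    scale = np.sqrt(2.0 / (n_in + n_out))
    w = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return w, b


def _conv(rng: np.random.Generator, c_in: int, c_out: int, k: int) -> tuple[Tensor, Tensor]:
    fan_in = c_in * k * k
    scale = np.sqrt(2.0 / fan_in)
    w = Tensor(rng.normal(0.0, scale, size=(c_out, fan_in)), requires_grad=True)
    b = Tensor(np.zeros(c_out), requires_grad=True)
    return w, b


_CNN_PLANS = {
    # (out_channels, ksize, stride) per layer
    "tiny_cnn": [(8, 3, 1), (16, 3, 1), (16, 3, 2)],
    "alexnet_like": [(16, 3, 2), (32, 3, 1), (32, 3, 1), (32, 3, 1), (32, 3, 1)],
}


def _conv_out_hw(h: int, w: int, plan) -> tuple[int, int]:
    for _, k, s in plan:
        h = (h - k) // s + 1
        w = (w - k) // s + 1
        if h < 1 or w < 1:
            raise ConfigError("input slice too small for the chosen conv backbone")
    return h, w


class DCPHAModel:
    """Parameter container + forward passes.

    Parameters are autodiff leaf tensors keyed by name; ``*_parameters``
    accessors return the groups the three training stages optimize.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        c = config
        for m in range(c.n_modalities):
            p = f"enc{m}."
            if c.backbone == "mlp":
                self.params[p + "w1"], self.params[p + "b1"] = _linear(rng, c.flat_input_dim, c.hidden_dim)
                self.params[p + "w2"], self.params[p + "b2"] = _linear(rng, c.hidden_dim, c.feature_dim)
            else:
                plan = _CNN_PLANS[c.backbone]
                h, w = c.input_dim_or_shape
                oh, ow = _conv_out_hw(h, w, plan)
                c_in = 1
                for li, (c_out, k, _s) in enumerate(plan):
                    self.params[f"{p}conv{li}.w"], self.params[f"{p}conv{li}.b"] = _conv(rng, c_in, c_out, k)
                    c_in = c_out
                flat = c_in * oh * ow
                if c.backbone == "alexnet_like":
                    self.params[p + "fc1.w"], self.params[p + "fc1.b"] = _linear(rng, flat, 128)
                    self.params[p + "fc2.w"], self.params[p + "fc2.b"] = _linear(rng, 128, c.feature_dim)
                else:
                    self.params[p + "fc.w"], self.params[p + "fc.b"] = _linear(rng, flat, c.feature_dim)
        # shared light decoder: single affine map into tanh
        self.params["dec.w"], self.params["dec.b"] = _linear(rng, c.feature_dim, c.code_bits)
        # linear multi-layer heads (two stacked affine maps, no nonlinearity)
        self.params["spab_e.w1"], self.params["spab_e.b1"] = _linear(rng, c.feature_dim, c.feature_dim)
        self.params["spab_e.w2"], self.params["spab_e.b2"] = _linear(rng, c.feature_dim, c.n_classes)
        self.params["spab_d.w1"], self.params["spab_d.b1"] = _linear(rng, c.code_bits, c.code_bits)
        self.params["spab_d.w2"], self.params["spab_d.b2"] = _linear(rng, c.code_bits, c.n_classes)

    # -- parameter groups -----------------------------------------------------
    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k.startswith(prefix)}

    def encoder_parameters(self, modality: int | None = None) -> dict[str, Tensor]:
        if modality is None:
            return {k: v for k, v in self.params.items() if k.startswith("enc")}
        return self.parameters(f"enc{modality}.")

    def decoder_parameters(self) -> dict[str, Tensor]:
        return self.parameters("dec.")

    def spab_parameters(self, branch: str) -> dict[str, Tensor]:
        if branch not in ("encoder_stage", "decoder_stage"):
            raise DimensionError(f"unknown branch {branch!r}")
        return self.parameters("spab_e." if branch == "encoder_stage" else "spab_d.")

    def n_parameters(self, prefix: str = "") -> int:
        return sum(v.data.size for v in self.parameters(prefix).values())

    # -- forward pieces (return Tensors bound to the parameter graph) ---------
    def _encode_one(self, modality: int, x: np.ndarray) -> Tensor:
        c = self.config
        p = f"enc{modality}."
        if c.backbone == "mlp":
            h = ad.relu(Tensor(x) @ self.params[p + "w1"] + self.params[p + "b1"])
            return ad.tanh(h @ self.params[p + "w2"] + self.params[p + "b2"])
        plan = _CNN_PLANS[c.backbone]
        hgt, wdt = c.input_dim_or_shape
        n = x.shape[0]
        t = Tensor(x.reshape(n, 1, hgt, wdt))
        for li, (c_out, k, s) in enumerate(plan):
            w = self.params[f"{p}conv{li}.w"]
            b = self.params[f"{p}conv{li}.b"]
            cols = ad.im2col(t, k, s)                      # (n, c_in*k*k, P)
            n_pos = cols.shape[2]
            oh = (t.shape[2] - k) // s + 1
            ow = (t.shape[3] - k) // s + 1
            flat = cols.permute((0, 2, 1)).reshape(n * n_pos, cols.shape[1])
            out = flat @ w.T + b                           # (n*P, c_out)
            t = ad.relu(out.reshape(n, n_pos, c_out).permute((0, 2, 1)).reshape(n, c_out, oh, ow))
        t = t.reshape(n, t.shape[1] * t.shape[2] * t.shape[3])
        if c.backbone == "alexnet_like":
            t = ad.relu(t @ self.params[p + "fc1.w"] + self.params[p + "fc1.b"])
            return ad.tanh(t @ self.params[p + "fc2.w"] + self.params[p + "fc2.b"])
        return ad.tanh(t @ self.params[p + "fc.w"] + self.params[p + "fc.b"])

    def _decode(self, features: Tensor | np.ndarray) -> Tensor:
        f = features if isinstance(features, Tensor) else Tensor(features)
        return ad.tanh(f @ self.params["dec.w"] + self.params["dec.b"])

    def _spab(self, branch: str, x: Tensor | np.ndarray) -> Tensor:
        key = "spab_e." if branch == "encoder_stage" else "spab_d."
        t = x if isinstance(x, Tensor) else Tensor(x)
        h = t @ self.params[key + "w1"] + self.params[key + "b1"]
        logits = h @ self.params[key + "w2"] + self.params[key + "b2"]
        return ad.softmax(logits, axis=-1)

    def forward_graph(self, batch: np.ndarray):
        """Per-modality lists of (features, relaxed codes, y, r) Tensors."""
        batch = self._check_batch(batch)
        feats, codes, ys, rs = [], [], [], []
        for m in range(self.config.n_modalities):
            f = self._encode_one(m, batch[m])
            h = self._decode(f)
            feats.append(f)
            codes.append(h)
            ys.append(self._spab("encoder_stage", f))
            rs.append(self._spab("decoder_stage", h))
        return feats, codes, ys, rs

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 4 and self.config.backbone != "mlp":
            batch = batch.reshape(batch.shape[0], batch.shape[1], -1)
        if batch.ndim != 3:
            raise DimensionError("batch must have shape (M, N, Z)")
        if batch.shape[0] != self.config.n_modalities:
            raise DimensionError(
                f"batch has {batch.shape[0]} modalities, model expects "
                f"{self.config.n_modalities}")
        if batch.shape[2] != self.config.flat_input_dim:
            raise DimensionError(
                f"batch sample dim {batch.shape[2]} != Z={self.config.flat_input_dim}")
        return batch


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig) -> DCPHAModel:
    """Construct the model; parameter initialisation is deterministic in
    ``config.seed``."""
    return DCPHAModel(config)


def encode(model: DCPHAModel, batch: np.ndarray) -> np.ndarray:
    """Map an (M, N, Z) batch to (M, N, D) features; modality m passes
    through encoder m only."""
    batch = model._check_batch(batch)
    return np.stack([model._encode_one(m, batch[m]).data
                     for m in range(model.config.n_modalities)])


def decode(model: DCPHAModel, features: np.ndarray) -> np.ndarray:
    """Map (M, N, D) features to (M, N, K) relaxed codes in (−1, 1) through
    the shared decoder."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.shape[2] != model.config.feature_dim:
        raise DimensionError(
            f"features must be (M, N, D={model.config.feature_dim})")
    return np.stack([model._decode(features[m]).data for m in range(features.shape[0])])


def spab_predict(model: DCPHAModel, branch: str, x: np.ndarray) -> np.ndarray:
    """Class distributions from one attention branch: ``encoder_stage``
    expects D-dim features, ``decoder_stage`` K-dim codes."""
    if branch not in ("encoder_stage", "decoder_stage"):
        raise DimensionError(f"unknown branch {branch!r}")
    x = np.asarray(x, dtype=np.float64)
    want = model.config.feature_dim if branch == "encoder_stage" else model.config.code_bits
    if x.shape[-1] != want:
        raise DimensionError(f"{branch} expects last dim {want}, got {x.shape[-1]}")
    if x.ndim == 2:
        return model._spab(branch, x).data
    return np.stack([model._spab(branch, x[m]).data for m in range(x.shape[0])])


def binarize(relaxed):
    """Sign binarization with the tie rule sign(0) = +1 (idempotent)."""
    if isinstance(relaxed, CodeMatrix):
        return CodeMatrix(np.where(relaxed.values >= 0.0, 1.0, -1.0),
                          modality_index=relaxed.modality_index, is_binary=True)
    arr = np.asarray(relaxed, dtype=np.float64)
    return np.where(arr >= 0.0, 1.0, -1.0)


def forward_batch(model: DCPHAModel, batch: np.ndarray) -> ForwardOutput:
    """encode → decode → both attention branches, stacked as plain arrays."""
    feats, codes, ys, rs = model.forward_graph(batch)
    return ForwardOutput(
        features=np.stack([f.data for f in feats]),
        relaxed_codes=np.stack([h.data for h in codes]),
        y_preds=np.stack([y.data for y in ys]),
        r_preds=np.stack([r.data for r in rs]),
    )


# ---------------------------------------------------------------------------
# Checkpointing: parameters in an .npz, config as an embedded JSON snapshot
# ---------------------------------------------------------------------------

def save_checkpoint(model: DCPHAModel, path) -> None:
    arrays = {k: v.data for k, v in model.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> DCPHAModel:
    with np.load(path) as npz:
        cfg = json.loads(bytes(npz["__config__"].tobytes()).decode())
        model = DCPHAModel(ModelConfig(**cfg))
        for k in model.params:
            model.params[k] = Tensor(npz[k], requires_grad=True)
    return model
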