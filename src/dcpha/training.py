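"""Three-stage optimization of the hash auto-encoder.

Training proceeds in the order (1) pre-train the encoders together with the
encoder-stage attention branch on the ‖y−ℓ‖ classification term, (2)
pre-train the shared decoder and decoder-stage branch on ‖r−ℓ‖ plus the
quantization regularizer with the encoders frozen, and (3) fine-tune every
parameter jointly on the total objective α·J1 + β·J2 + regularizer, all with
Adam.  Batches hold the same subject indices across every modality (strong
pairing), drawn without replacement per epoch from a seeded generator, so a
fixed seed reproduces histories and final parameters bit for bit on one CPU
thread.

Presets: ``desk`` is the CPU-scale recipe the synthetic experiments use
(lr 1e-3, mean-reduced losses, magnitude quantization); ``adni2`` and
``oasis3`` carry the published hyper-parameters (batch 20, 500 iterations,
initial lr 1e-6, α = 0.3 / 0.1, β = 1.0, sum-reduced losses with the literal
all-ones regularizer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigError, DataError
from .losses import (
    manifold_preserving_kernel,
    quantization_kernel,
    semantic_consistency_kernel,
)
from .model import DCPHAModel

logger = logging.getLogger("dcpha")

STAGES = ("pretrain_encoder", "pretrain_decoder", "finetune")


@dataclass
class TrainConfig:
    batch_size: int = 20
    iterations: int = 100              # fine-tuning steps
    pretrain_encoder_iters: int = 50
    pretrain_decoder_iters: int = 50
    learning_rate: float = 1e-3
    finetune_learning_rate: float | None = None  # default: learning_rate / 100
    alpha: float = 0.3
    beta: float = 1.0
    tau: float = 1.0
    seed: int = 0
    reduction: str = "mean"            # "sum" follows the printed equations
    quantization_variant: str = "magnitude"
    count_multiplicity: bool = True
    include_self_pairs: bool = True
    swap_distance_branches: bool = False
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if min(self.iterations, self.pretrain_encoder_iters,
               self.pretrain_decoder_iters, self.batch_size) < 0:
            raise ConfigError("iteration counts and batch size must be non-negative")
        if self.batch_size < 1:
            raise ConfigError("batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be positive")
        if self.alpha < 0 or self.beta < 0 or self.tau <= 0:
            raise ConfigError("alpha, beta must be >= 0 and tau > 0")
        if self.reduction not in ("sum", "mean"):
            raise ConfigError("reduction must be 'sum' or 'mean'")


PRESETS: dict[str, dict] = {
    "desk": {},
    "adni2": dict(iterations=500, learning_rate=1e-6, finetune_learning_rate=1e-6,
                  alpha=0.3, beta=1.0, reduction="sum",
                  quantization_variant="literal"),
    "oasis3": dict(iterations=500, learning_rate=1e-6, finetune_learning_rate=1e-6,
                   alpha=0.1, beta=1.0, reduction="sum",
                   quantization_variant="literal"),
}


def preset(name: str, **overrides) -> TrainConfig:
    """Named hyper-parameter presets; keyword overrides win."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@dataclass
class TrainHistory:
    """Per-optimizer-step loss records across the three stages."""

    records: list = field(default_factory=list)

    def append(self, iteration: int, stage: str, j1: float, j2: float,
               reg: float, total: float) -> None:
        self.records.append(dict(iteration=iteration, stage=stage, j1=j1,
                                 j2=j2, reg=reg, total=total))

    def stage(self, tag: str) -> list:
        return [r for r in self.records if r["stage"] == tag]

    def totals(self, tag: str | None = None) -> np.ndarray:
        recs = self.records if tag is None else self.stage(tag)
        return np.array([r["total"] for r in recs])

    def to_tsv(self, path) -> None:
        from .io import atomic_write_text

        lines = ["iteration\tstage\tJ1\tJ2\treg\ttotal"]
        for r in self.records:
            lines.append(f"{r['iteration']}\t{r['stage']}\t{r['j1']:.10g}"
                         f"\t{r['j2']:.10g}\t{r['reg']:.10g}\t{r['total']:.10g}")
        atomic_write_text(path, "\n".join(lines) + "\n")


class Adam:
    """Adam with the standard defaults (the optimizer the method trains with)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = dict(sorted(params.items()))  # deterministic order
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _BatchSampler:
    """Epoch-wise shuffled batches of subject indices (strong pairing: the
    same indices are used for every modality)."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._queue: list[np.ndarray] = []

    def next(self) -> np.ndarray:
        if not self._queue:
            order = self.rng.permutation(self.n)
            nb = self.n // self.batch_size
            self._queue = [order[i * self.batch_size:(i + 1) * self.batch_size]
                           for i in range(max(nb, 1))]
        return self._queue.pop(0)


def _check_dataset(dataset) -> None:
    if dataset.samples.shape[1] == 0:
        raise DataError("dataset is empty")


def _j1_terms(model: DCPHAModel, ys, rs, onehot_batch, reduction,
              use_y=True, use_r=True, use_yr=True):
    """Semantic-consistency terms from per-modality prediction Tensors."""
    m_mod = len(ys)
    n = onehot_batch.shape[0]
    lab = np.tile(onehot_batch.astype(np.float64), (m_mod, 1))
    total = 0.0
    ycat = ad.concatenate(ys, axis=0) if use_y or use_yr else None
    rcat = ad.concatenate(rs, axis=0) if use_r or use_yr else None
    if use_y:
        total = total + ad.tsum(ad.sqrt(ad.tsum((ycat - lab) ** 2, axis=1) + 1e-12))
    if use_r:
        total = total + ad.tsum(ad.sqrt(ad.tsum((rcat - lab) ** 2, axis=1) + 1e-12))
    if use_yr:
        total = total + ad.tsum(ad.sqrt(ad.tsum((ycat - rcat) ** 2, axis=1) + 1e-12))
    if reduction == "mean":
        total = total / float(m_mod * n)
    return total


def _run_stage(model: DCPHAModel, dataset, config: TrainConfig, stage: str,
               iters: int, history: TrainHistory, rng: np.random.Generator) -> None:
    if iters == 0:
        return
    _check_dataset(dataset)
    n = dataset.samples.shape[1]
    sampler = _BatchSampler(n, config.batch_size, rng)

    if stage == "pretrain_encoder":
        opt_params = {**model.encoder_parameters(),
                      **model.spab_parameters("encoder_stage")}
    elif stage == "pretrain_decoder":
        opt_params = {**model.decoder_parameters(),
                      **model.spab_parameters("decoder_stage")}
    else:
        opt_params = model.params
    if stage == "finetune":
        # fine-tuning is a refinement stage: run it two orders of magnitude
        # gentler than pre-training unless the config says otherwise, so the
        # joint objective adjusts the pre-trained solution instead of
        # re-solving (and collapsing) it
        lr = (config.finetune_learning_rate
              if config.finetune_learning_rate is not None
              else config.learning_rate / 100.0)
    else:
        lr = config.learning_rate
    opt = Adam(opt_params, lr,
               config.adam_beta1, config.adam_beta2, config.adam_eps)

    for it in range(iters):
        idx = sampler.next()
        batch = dataset.samples[:, idx, :]
        onehot = dataset.labels.onehot[idx]
        same_mask = dataset.labels.same_label_matrix()[np.ix_(idx, idx)]

        j1 = j2 = reg = 0.0
        if stage == "pretrain_encoder":
            feats = [model._encode_one(m, batch[m])
                     for m in range(model.config.n_modalities)]
            ys = [model._spab("encoder_stage", f) for f in feats]
            loss = _j1_terms(model, ys, ys, onehot, config.reduction,
                             use_y=True, use_r=False, use_yr=False)
            j1 = loss.item()
        elif stage == "pretrain_decoder":
            # encoders frozen: features enter the graph as constants
            feats = [model._encode_one(m, batch[m]).data
                     for m in range(model.config.n_modalities)]
            codes = [model._decode(f) for f in feats]
            rs = [model._spab("decoder_stage", h) for h in codes]
            loss_r = _j1_terms(model, rs, rs, onehot, config.reduction,
                               use_y=False, use_r=True, use_yr=False)
            loss_q = quantization_kernel(codes, config.quantization_variant,
                                         config.reduction, config.count_multiplicity)
            loss = loss_r + loss_q
            j1, reg = loss_r.item(), loss_q.item()
        else:  # finetune: the full objective
            feats, codes, ys, rs = model.forward_graph(batch)
            loss = 0.0
            if config.alpha != 0.0:
                l1 = _j1_terms(model, ys, rs, onehot, config.reduction)
                j1 = l1.item()
                loss = loss + config.alpha * l1
            if config.beta != 0.0:
                l2 = manifold_preserving_kernel(
                    codes, same_mask, config.tau, config.reduction,
                    config.include_self_pairs, config.swap_distance_branches)
                j2 = l2.item()
                loss = loss + config.beta * l2
            lq = quantization_kernel(codes, config.quantization_variant,
                                     config.reduction, config.count_multiplicity)
            reg = lq.item()
            loss = loss + lq

        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(it, stage, j1, j2, reg, loss.item())


def pretrain_encoder(model: DCPHAModel, dataset, config: TrainConfig,
                     history: TrainHistory | None = None,
                     rng: np.random.Generator | None = None) -> TrainHistory:
    """Stage 1: encoders + encoder-stage branch on the ‖y−ℓ‖ term."""
    history = history if history is not None else TrainHistory()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _run_stage(model, dataset, config, "pretrain_encoder",
               config.pretrain_encoder_iters, history, rng)
    return history


def pretrain_decoder(model: DCPHAModel, dataset, config: TrainConfig,
                     history: TrainHistory | None = None,
                     rng: np.random.Generator | None = None) -> TrainHistory:
    """Stage 2: decoder + decoder-stage branch on ‖r−ℓ‖ + regularizer,
    encoders frozen."""
    history = history if history is not None else TrainHistory()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _run_stage(model, dataset, config, "pretrain_decoder",
               config.pretrain_decoder_iters, history, rng)
    return history


def finetune(model: DCPHAModel, dataset, config: TrainConfig,
             history: TrainHistory | None = None,
             rng: np.random.Generator | None = None) -> TrainHistory:
    """Stage 3: all parameters jointly on the total objective."""
    history = history if history is not None else TrainHistory()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _run_stage(model, dataset, config, "finetune", config.iterations, history, rng)
    return history


def train(dataset, model_config, train_config: TrainConfig,
          log_path=None) -> tuple[DCPHAModel, TrainHistory]:
    """Run the three stages in order on a freshly built model."""
    from .model import build_model

    logger.info("training config: %s", asdict(train_config))
    model = build_model(model_config)
    history = TrainHistory()
    rng = np.random.default_rng(train_config.seed)
    pretrain_encoder(model, dataset, train_config, history, rng)
    pretrain_decoder(model, dataset, train_config, history, rng)
    finetune(model, dataset, train_config, history, rng)
    if log_path is not None:
        history.to_tsv(log_path)
    return model, history
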