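"""Parameter-efficient supervised adaptation recipe.

Implements the fine-tuning protocol around an abstract trainable-encoder
contract: low-rank adapter (LoRA) injection into named frozen projection
modules, AdamW with decoupled weight decay, a linear-warmup/cosine-decay
learning-rate schedule, gradient clipping, two stochastic forward passes per
batch (feeding the R-Drop term of the composite objective), per-epoch
validation macro-F1, and early stopping with best-state restoration.

A deterministic desk-scale fixture encoder ships with the package: a hashed
bag-of-tokens featurizer feeding frozen random projection modules named
after the canonical attention/feed-forward projections (query, key, value,
ffn_in, ffn_out), LoRA adapters on any subset of them, dropout on the pooled
representation, and a trainable linear classifier head.  It exists so the
whole recipe — loss, schedule, stopping, MC-dropout decoding — runs and is
testable in seconds on a CPU; it makes no claim to transformer-scale
behaviour, and absolute scores of real pretrained backbones are out of its
scope.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import N_CLASSES, Corpus, SplitBundle
from .evaluation import confusion_matrix, macro_metrics
from .losses import ClassStats, LossConfig, total_loss_and_grads, DualPassLogits

__all__ = [
    "LoraSpec",
    "TrainConfig",
    "TrainState",
    "resolve_target_modules",
    "lr_at_step",
    "early_stopping_update",
    "FixtureEncoder",
    "fit",
    "predict_logits",
]


@dataclass
class LoraSpec:
    """Low-rank adapter hyperparameters (defaults are the published benchmark's)."""

    rank: int = 8
    alpha: float = 16.0
    dropout: float = 0.05
    target_modules: list[str] = field(
        default_factory=lambda: ["query", "key", "value", "ffn_in", "ffn_out"]
    )

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if not self.target_modules:
            raise ValueError("target_modules must be non-empty")

    @property
    def scaling(self) -> float:
        return self.alpha / self.rank


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the published benchmark's values).

    The learning rate applies to the classifier head and the LoRA parameters
    alike; the base weights stay frozen.
    """

    learning_rate: float = 2e-4
    weight_decay: float = 0.03
    warmup_ratio: float = 0.06
    grad_clip: float = 1.0
    batch_size: int = 16
    max_epochs: int = 10
    patience: int = 2
    min_delta: float = 5e-4
    max_length: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "learning_rate": self.learning_rate,
            "grad_clip": self.grad_clip,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "min_delta": self.min_delta,
            "max_length": self.max_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.warmup_ratio < 1.0:
            raise ValueError(f"warmup_ratio must be in [0, 1), got {self.warmup_ratio}")
        if self.weight_decay < 0:
            raise ValueError(f"weight_decay must be >= 0, got {self.weight_decay}")


@dataclass
class TrainState:
    """Early-stopping bookkeeping and per-epoch history."""

    epoch: int = 0
    best_val_macro_f1: float = -math.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    stopped: bool = False
    history: list[tuple[int, float, float]] = field(default_factory=list)
    # history rows: (epoch, train loss, val macro-F1)


_DEBERTA_TARGETS = ["query_proj", "key_proj", "value_proj", "dense"]
_GENERIC_TARGETS = ["query", "key", "value", "ffn_in", "ffn_out"]
_GENERIC_FAMILIES = (
    "roberta",
    "bertweet",
    "bert",
    "mpnet",
    "albert",
    "xlm",
    "fixture",
)


def resolve_target_modules(family: str) -> list[str]:
    """Map an encoder family name to its LoRA attachment points.

    DeBERTa variants expose ``*_proj`` attention projections plus the
    attention output ``dense``; the other supported encoder families use the
    canonical query/key/value and feed-forward projection names.
    """
    lowered = family.lower()
    if "deberta" in lowered:
        return list(_DEBERTA_TARGETS)
    if any(fam in lowered for fam in _GENERIC_FAMILIES):
        return list(_GENERIC_TARGETS)
    raise ValueError(
        f"unknown encoder family {family!r}; known families: deberta, "
        + ", ".join(_GENERIC_FAMILIES)
    )


def lr_at_step(step: int, total_steps: int, config: TrainConfig) -> float:
    """Linear warmup to the peak rate, then cosine decay to zero."""
    if total_steps < 1:
        raise ValueError(f"total_steps must be >= 1, got {total_steps}")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    warmup_steps = math.ceil(config.warmup_ratio * total_steps)
    if step < warmup_steps:
        return config.learning_rate * step / warmup_steps
    if total_steps == warmup_steps:
        return config.learning_rate
    progress = (step - warmup_steps) / (total_steps - warmup_steps)
    return config.learning_rate * 0.5 * (1.0 + math.cos(math.pi * progress))


def early_stopping_update(
    state: TrainState, val_macro_f1: float, config: TrainConfig
) -> TrainState:
    """One early-stopping bookkeeping step after an epoch's validation pass.

    Improvement means the new value beats the best by at least `min_delta`;
    otherwise the patience counter advances and stopping fires when it
    reaches `patience`.
    """
    if not 0.0 <= val_macro_f1 <= 1.0:
        raise ValueError(f"macro-F1 must be in [0, 1], got {val_macro_f1}")
    new = replace(state, epoch=state.epoch + 1, history=list(state.history))
    if val_macro_f1 >= state.best_val_macro_f1 + config.min_delta or (
        state.best_val_macro_f1 == -math.inf
    ):
        new.best_val_macro_f1 = val_macro_f1
        new.best_epoch = new.epoch
        new.epochs_since_improvement = 0
    else:
        new.epochs_since_improvement = state.epochs_since_improvement + 1
        if new.epochs_since_improvement >= config.patience:
            new.stopped = True
    return new


# --------------------------------------------------------------------------
# Fixture encoder: hashed features -> frozen projections (+LoRA) -> head
# --------------------------------------------------------------------------


class _LoraLinear:
    """A frozen linear map with an optional trainable low-rank update.

    Effective weight is W + (alpha/rank) * B @ A with A initialised to small
    random values and B to zero, so the adapter starts as a no-op.
    """

    def __init__(self, name: str, w: np.ndarray) -> None:
        self.name = name
        self.w = w  # (out, in), frozen
        self.a: np.ndarray | None = None  # (rank, in)
        self.b: np.ndarray | None = None  # (out, rank)
        self.scaling = 0.0

    def inject(self, spec: LoraSpec, rng: np.random.Generator) -> None:
        out_dim, in_dim = self.w.shape
        self.a = rng.standard_normal((spec.rank, in_dim)) * 0.01
        self.b = np.zeros((out_dim, spec.rank))
        self.scaling = spec.scaling

    @property
    def trainable(self) -> bool:
        return self.a is not None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.w.T
        if self.trainable:
            y = y + self.scaling * (x @ self.a.T) @ self.b.T
        return y

    def backward(
        self, x: np.ndarray, grad_out: np.ndarray, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        """Accumulate adapter gradients; return gradient w.r.t. the input."""
        grad_in = grad_out @ self.w
        if self.trainable:
            gb = grad_out @ self.b  # (batch, rank)
            grads[f"{self.name}.a"] += self.scaling * gb.T @ x
            grads[f"{self.name}.b"] += self.scaling * grad_out.T @ (x @ self.a.T)
            grad_in = grad_in + self.scaling * gb @ self.a
        return grad_in


class FixtureEncoder:
    """Deterministic desk-scale implementation of the trainable-encoder contract.

    Texts are whitespace-tokenized, head-truncated to `max_length` tokens,
    and hashed into a fixed-width bag-of-tokens feature vector.  The frozen
    "backbone" applies the named projection modules
    h1 = (query(x) + key(x) + value(x)) / 3 and
    h = h1 + ffn_out(ffn_in(h1)); dropout on h feeds a trainable linear
    classifier head.  LoRA adapters may be injected at any named module.
    """

    family = "fixture"

    def __init__(
        self,
        feature_dim: int = 512,
        hidden_dim: int = 64,
        seed: int = 0,
        dropout: float = 0.05,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        scale_in = 1.0 / math.sqrt(feature_dim)
        scale_h = 1.0 / math.sqrt(hidden_dim)
        self.modules: dict[str, _LoraLinear] = {
            name: _LoraLinear(
                name, rng.standard_normal((hidden_dim, feature_dim)) * scale_in
            )
            for name in ("query", "key", "value")
        }
        self.modules["ffn_in"] = _LoraLinear(
            "ffn_in", rng.standard_normal((hidden_dim, hidden_dim)) * scale_h
        )
        self.modules["ffn_out"] = _LoraLinear(
            "ffn_out", rng.standard_normal((hidden_dim, hidden_dim)) * scale_h
        )
        self.head_w = np.zeros((N_CLASSES, hidden_dim))
        self.head_b = np.zeros(N_CLASSES)
        self._lora_spec: LoraSpec | None = None

    # -- featurization ----------------------------------------------------

    def featurize(self, texts: Sequence[str], max_length: int = 160) -> np.ndarray:
        """Hashed bag-of-tokens features, head-truncated to max_length tokens."""
        x = np.zeros((len(texts), self.feature_dim))
        for i, text in enumerate(texts):
            tokens = text.split()[:max_length]
            for tok in tokens:
                x[i, zlib.crc32(tok.encode("utf-8")) % self.feature_dim] += 1.0
            if tokens:
                x[i] /= math.sqrt(len(tokens))
        return x

    # -- parameters --------------------------------------------------------

    def inject_lora(self, spec: LoraSpec, rng: np.random.Generator) -> None:
        for name in spec.target_modules:
            if name not in self.modules:
                raise ValueError(
                    f"module {name!r} not in fixture encoder; "
                    f"available: {sorted(self.modules)}"
                )
            self.modules[name].inject(spec, rng)
        self._lora_spec = spec

    def trainable_params(self) -> dict[str, np.ndarray]:
        params = {"head.w": self.head_w, "head.b": self.head_b}
        for mod in self.modules.values():
            if mod.trainable:
                params[f"{mod.name}.a"] = mod.a
                params[f"{mod.name}.b"] = mod.b
        return params

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.head_w = params["head.w"].copy()
        self.head_b = params["head.b"].copy()
        for mod in self.modules.values():
            if mod.trainable:
                mod.a = params[f"{mod.name}.a"].copy()
                mod.b = params[f"{mod.name}.b"].copy()

    def num_trainable(self) -> int:
        return sum(p.size for p in self.trainable_params().values())

    def num_frozen(self) -> int:
        return sum(mod.w.size for mod in self.modules.values())

    # -- forward / backward ------------------------------------------------

    def forward(
        self, x: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """One forward pass; a provided rng activates dropout (training mode)."""
        h1 = (
            self.modules["query"].forward(x)
            + self.modules["key"].forward(x)
            + self.modules["value"].forward(x)
        ) / 3.0
        f = self.modules["ffn_in"].forward(h1)
        h = h1 + self.modules["ffn_out"].forward(f)
        if rng is not None and self.dropout > 0.0:
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h)
        hd = h * mask
        logits = hd @ self.head_w.T + self.head_b
        cache = {"x": x, "h1": h1, "f": f, "hd": hd, "mask": mask}
        return logits, cache

    def backward(
        self, cache: dict, grad_logits: np.ndarray, grads: dict[str, np.ndarray]
    ) -> None:
        """Accumulate gradients of the trainable parameters into `grads`."""
        grads["head.w"] += grad_logits.T @ cache["hd"]
        grads["head.b"] += grad_logits.sum(axis=0)
        dh = (grad_logits @ self.head_w) * cache["mask"]
        df = self.modules["ffn_out"].backward(cache["f"], dh, grads)
        dh1 = dh + self.modules["ffn_in"].backward(cache["h1"], df, grads)
        dup = dh1 / 3.0
        for name in ("query", "key", "value"):
            self.modules[name].backward(cache["x"], dup, grads)


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------


class _AdamW:
    """AdamW with decoupled weight decay over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float) -> None:
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.weight_decay = weight_decay

    def step(
        self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float
    ) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            p -= lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p)


def _clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _val_macro_f1(encoder: FixtureEncoder, corpus: Corpus, max_length: int) -> float:
    logits = predict_logits(encoder, corpus, mc_dropout_passes=1, max_length=max_length)
    from .corpus import LABEL_ORDER

    preds = [LABEL_ORDER[i] for i in np.argmax(logits, axis=1)]
    return macro_metrics(confusion_matrix(corpus.labels(), preds)).macro_f1


def fit(
    encoder: FixtureEncoder,
    splits: SplitBundle,
    lora: LoraSpec | None = None,
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
) -> tuple[FixtureEncoder, TrainState]:
    """Train the encoder with the composite objective and early stopping.

    Class statistics (weights and margins) come from the training split
    only.  Each batch runs two stochastic forward passes with distinct
    dropout masks; when the encoder's dropout rate is zero the passes
    coincide and the consistency term vanishes identically.  The state at
    the best validation epoch is restored before returning.  Deterministic
    given the config seed.
    """
    lora = lora or LoraSpec(target_modules=resolve_target_modules(encoder.family))
    train_config = train_config or TrainConfig()
    loss_config = loss_config or LossConfig()

    rng = np.random.default_rng(train_config.seed)
    encoder.inject_lora(lora, rng)

    from .corpus import class_counts

    counts = class_counts(splits.train)
    if np.any(counts == 0):
        raise ValueError("training split must contain every class")
    stats = ClassStats.from_counts(counts, loss_config)

    x_train = encoder.featurize(splits.train.texts(), train_config.max_length)
    y_train = splits.train.labels()
    n = len(y_train)
    steps_per_epoch = math.ceil(n / train_config.batch_size)
    total_steps = steps_per_epoch * train_config.max_epochs

    params = encoder.trainable_params()
    optimizer = _AdamW(params, train_config.weight_decay)
    state = TrainState()
    best_params = {k: v.copy() for k, v in params.items()}
    step = 0

    for _epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb = x_train[idx]
            z1, cache1 = encoder.forward(xb, rng=rng)
            z2, cache2 = encoder.forward(xb, rng=rng)
            batch = [
                DualPassLogits(z1[i], z2[i], y_train[j])
                for i, j in enumerate(idx)
            ]
            loss, g1, g2 = total_loss_and_grads(batch, stats, loss_config)
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            encoder.backward(cache1, g1, grads)
            encoder.backward(cache2, g2, grads)
            _clip_gradients(grads, train_config.grad_clip)
            lr = lr_at_step(step, total_steps, train_config)
            optimizer.step(params, grads, lr)
            epoch_loss += loss * len(idx)
            step += 1
        epoch_loss /= n

        val_f1 = _val_macro_f1(encoder, splits.validation, train_config.max_length)
        improved_before = state.best_val_macro_f1
        state = early_stopping_update(state, val_f1, train_config)
        state.history.append((state.epoch, epoch_loss, val_f1))
        if state.best_epoch == state.epoch and state.best_val_macro_f1 != improved_before:
            best_params = {k: v.copy() for k, v in params.items()}
        if state.stopped:
            break

    encoder.set_params(best_params)
    return encoder, state


def predict_logits(
    encoder: FixtureEncoder,
    corpus: Corpus,
    mc_dropout_passes: int = 1,
    max_length: int = 160,
    seed: int = 0,
) -> np.ndarray:
    """Per-example logits: one deterministic pass, or the mean of several
    stochastic (dropout-active) passes when MC-dropout averaging is on."""
    if mc_dropout_passes < 1:
        raise ValueError(f"mc_dropout_passes must be >= 1, got {mc_dropout_passes}")
    x = encoder.featurize(corpus.texts(), max_length)
    if mc_dropout_passes == 1:
        logits, _ = encoder.forward(x, rng=None)
        return logits
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(corpus), N_CLASSES))
    for _ in range(mc_dropout_passes):
        logits, _ = encoder.forward(x, rng=rng)
        acc += logits
    return acc / mc_dropout_passes
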