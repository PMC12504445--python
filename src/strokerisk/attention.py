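"""Tabular attention classifier with a Lion-trained MLP head.

Architecture (19 explicit trainable layers under the counting convention
"one per attention map or linear map"):

* Embed — one linear map taking the standardised numeric stream to
  ``embed_dim``, plus learned lookup embeddings per categorical column
  (1 layer).
* Self-attention stack — 4 Pre-LN residual blocks over the categorical
  tokens, each a multi-head attention followed by a 2-linear FFN with GELU
  and inner width ``4 x embed_dim`` (3 layers per block = 12).
* Cross-attention — numeric-stream queries attend over the contextual
  categorical tokens, followed by one FFN (3 layers).
* Global MLP head — mean-pooled tokens concatenated with the (cross-
  attended) numeric stream, then Linear-GELU-Linear-GELU-Linear with
  softmax over the two classes (3 layers).

Regularisation: Dropout 0.1 inside blocks and head, DropPath 0.2 on each
residual branch (per-sample, survival-scaled, training only).  Training
uses cross-entropy and the Lion sign-momentum optimizer, stopping when all
six validation metrics clear their preset thresholds or the epoch budget
runs out; the checkpoint with the best validation AUC is returned.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .focal import DecisionRule


@dataclass(frozen=True)
class ArchitectureConfig:
    embed_dim: int = 32
    n_heads: int = 4
    n_self_blocks: int = 4
    ffn_multiplier: int = 4
    dropout: float = 0.1
    droppath: float = 0.2
    head_hidden: tuple[int, int] = (64, 32)
    n_classes: int = 2
    cross_attention: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_self_blocks < 0:
            raise ValueError("n_self_blocks must be >= 0")


def count_layers(config: ArchitectureConfig) -> int:
    """Trainable-layer count: 1 (embed) + 3 per self block + 3 (cross, if
    present) + 3 (head)."""
    return 1 + 3 * config.n_self_blocks + (3 if config.cross_attention else 0) + 3


@dataclass(frozen=True)
class StoppingThresholds:
    """Validation thresholds that end training once all are met."""

    accuracy: float = 0.95
    precision: float = 0.92
    recall: float = 0.91
    specificity: float = 0.93
    f1: float = 0.91
    auc: float = 0.93
    max_epochs: int = 100

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "specificity", "f1", "auc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"threshold {name} must lie in [0, 1]")


# --------------------------------------------------------------------------
# Lion optimizer
# --------------------------------------------------------------------------


def lion_step(
    w: np.ndarray,
    g: np.ndarray,
    m: np.ndarray,
    lr: float = 1e-4,
    beta1: float = 0.9,
    beta2: float = 0.99,
    weight_decay: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """One Lion update.  c = b1 m + (1-b1) g;  w -= lr (sign(c) + wd w);
    the momentum is refreshed *after* the parameter step:
    m <- b2 m + (1-b2) g."""
    if not np.isfinite(g).all():
        raise FloatingPointError("non-finite gradient in Lion step")
    c = beta1 * m + (1 - beta1) * g
    w_new = w - lr * (np.sign(c) + weight_decay * w)
    m_new = beta2 * m + (1 - beta2) * g
    return w_new, m_new


class Lion:
    """Sign-momentum optimizer over a dict of named Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.99, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.beta1, self.beta2, self.weight_decay = lr, beta1, beta2, weight_decay
        self.momentum = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for name, p in self.params.items():
            if p.grad is None:
                continue
            p.data, self.momentum[name] = lion_step(
                p.data, p.grad, self.momentum[name],
                self.lr, self.beta1, self.beta2, self.weight_decay,
            )

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


def _linear_init(rng, fan_in, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))


class AttentionClassifier:
    """The model, parameterised by a dict of named Tensors.

    ``cat_cardinalities`` gives the vocabulary size per categorical column;
    each embedding table carries one extra row for unseen/Unknown codes.
    """

    def __init__(
        self,
        n_numeric: int,
        cat_cardinalities: list[int],
        config: ArchitectureConfig | None = None,
        seed: int = 0,
    ):
        self.config = config if config is not None else ArchitectureConfig()
        self.n_numeric = int(n_numeric)
        self.cat_cardinalities = list(cat_cardinalities)
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self._build()
        self.last_attention: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------- building
    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self.params[name] = t
        return t

    def _build(self) -> None:
        cfg, rng = self.config, self.rng
        d = cfg.embed_dim
        if self.n_numeric > 0:
            self._param("embed.num.W", _linear_init(rng, self.n_numeric, d))
            self._param("embed.num.b", np.zeros(d))
        for ci, card in enumerate(self.cat_cardinalities):
            self._param(f"embed.cat{ci}", rng.normal(0, 0.02, size=(card + 1, d)))
        for b in range(cfg.n_self_blocks):
            self._attn_params(f"self{b}", rng)
            self._ffn_params(f"self{b}", rng)
        if cfg.cross_attention and self.cat_cardinalities:
            self._attn_params("cross", rng, extra_ln=True)
            self._ffn_params("cross", rng)
        pooled = d if self.cat_cardinalities else 0
        head_in = pooled + (d if self.n_numeric > 0 else 0)
        h1, h2 = cfg.head_hidden
        self._param("head.W1", _linear_init(rng, head_in, h1))
        self._param("head.b1", np.zeros(h1))
        self._param("head.W2", _linear_init(rng, h1, h2))
        self._param("head.b2", np.zeros(h2))
        self._param("head.W3", _linear_init(rng, h2, cfg.n_classes))
        self._param("head.b3", np.zeros(cfg.n_classes))

    def _attn_params(self, prefix: str, rng, extra_ln: bool = False) -> None:
        d = self.config.embed_dim
        for w in ("Wq", "Wk", "Wv", "Wo"):
            self._param(f"{prefix}.attn.{w}", _linear_init(rng, d, d))
        self._param(f"{prefix}.attn.bo", np.zeros(d))
        self._param(f"{prefix}.ln1.g", np.ones(d))
        self._param(f"{prefix}.ln1.b", np.zeros(d))
        if extra_ln:  # context stream gets its own Pre-LN in cross-attention
            self._param(f"{prefix}.lnc.g", np.ones(d))
            self._param(f"{prefix}.lnc.b", np.zeros(d))

    def _ffn_params(self, prefix: str, rng) -> None:
        d = self.config.embed_dim
        inner = self.config.ffn_multiplier * d
        self._param(f"{prefix}.ffn.W1", _linear_init(rng, d, inner))
        self._param(f"{prefix}.ffn.b1", np.zeros(inner))
        self._param(f"{prefix}.ffn.W2", _linear_init(rng, inner, d))
        self._param(f"{prefix}.ffn.b2", np.zeros(d))
        self._param(f"{prefix}.ln2.g", np.ones(d))
        self._param(f"{prefix}.ln2.b", np.zeros(d))

    # ------------------------------------------------------------- forwards
    def _dropout(self, x: Tensor, training: bool, rng) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0:
            return x
        mask = (rng.uniform(size=x.shape) >= p) / (1.0 - p)
        return ad.mul(x, mask)

    def _droppath_mask(self, batch: int, ndim: int, training: bool, rng):
        """Per-sample survival mask for a residual branch (None = keep all)."""
        p = self.config.droppath
        if not training or p <= 0:
            return None
        keep = (rng.uniform(size=batch) >= p) / (1.0 - p)
        return keep.reshape((batch,) + (1,) * (ndim - 1))

    def embed_features(self, x_num: np.ndarray, x_cat: np.ndarray) -> tuple[Tensor | None, Tensor | None]:
        """(numeric stream (B, D), token embeddings (B, C, D)).

        The numeric embed is a bare linear map (no activation); categorical
        codes out of range map to the per-column Unknown row.
        """
        num_stream = None
        if self.n_numeric > 0:
            x = np.asarray(x_num, dtype=float)
            num_stream = ad.add(
                ad.matmul(Tensor(x), self.params["embed.num.W"]),
                self.params["embed.num.b"],
            )
        tokens = None
        if self.cat_cardinalities:
            x_cat = np.asarray(x_cat, dtype=int)
            cols = []
            for ci, card in enumerate(self.cat_cardinalities):
                codes = np.clip(x_cat[:, ci], 0, card)  # card == Unknown row
                emb = ad.gather_rows(self.params[f"embed.cat{ci}"], codes)
                cols.append(ad.reshape(emb, (emb.shape[0], 1, emb.shape[1])))
            tokens = ad.concat(cols, axis=1)
        return num_stream, tokens

    def _mha(self, prefix: str, query: Tensor, context: Tensor,
             training: bool, rng) -> Tensor:
        cfg = self.config
        d, h = cfg.embed_dim, cfg.n_heads
        dh = d // h
        b, tq = query.shape[0], query.shape[1]
        tk = context.shape[1]
        p = self.params

        def split_heads(t: Tensor, tlen: int) -> Tensor:
            return ad.transpose(ad.reshape(t, (b, tlen, h, dh)), (0, 2, 1, 3))

        q = split_heads(ad.matmul(query, p[f"{prefix}.attn.Wq"]), tq)
        k = split_heads(ad.matmul(context, p[f"{prefix}.attn.Wk"]), tk)
        v = split_heads(ad.matmul(context, p[f"{prefix}.attn.Wv"]), tk)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)
        self.last_attention[prefix] = attn.data
        attn = self._dropout(attn, training, rng)
        ctx = ad.matmul(attn, v)  # (B, H, Tq, dh)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, tq, d))
        out = ad.add(ad.matmul(ctx, p[f"{prefix}.attn.Wo"]), p[f"{prefix}.attn.bo"])
        return out

    def _ffn(self, prefix: str, x: Tensor, training: bool, rng) -> Tensor:
        p = self.params
        h = ad.gelu(ad.add(ad.matmul(x, p[f"{prefix}.ffn.W1"]), p[f"{prefix}.ffn.b1"]))
        h = self._dropout(h, training, rng)
        return ad.add(ad.matmul(h, p[f"{prefix}.ffn.W2"]), p[f"{prefix}.ffn.b2"])

    def _residual(self, x: Tensor, branch: Tensor, training: bool, rng) -> Tensor:
        mask = self._droppath_mask(x.shape[0], len(x.shape), training, rng)
        if mask is not None:
            branch = ad.mul(branch, mask)
        return ad.add(x, branch)

    def self_attention_block(self, index: int, tokens: Tensor,
                             training: bool = False, rng=None) -> Tensor:
        """Pre-LN residual MHA followed by Pre-LN residual FFN."""
        rng = rng if rng is not None else self.rng
        p, prefix = self.params, f"self{index}"
        normed = ad.layer_norm(tokens, p[f"{prefix}.ln1.g"], p[f"{prefix}.ln1.b"])
        attn_out = self._mha(prefix, normed, normed, training, rng)
        tokens = self._residual(tokens, self._dropout(attn_out, training, rng), training, rng)
        normed = ad.layer_norm(tokens, p[f"{prefix}.ln2.g"], p[f"{prefix}.ln2.b"])
        tokens = self._residual(tokens, self._ffn(prefix, normed, training, rng), training, rng)
        return tokens

    def cross_attention_block(self, query_stream: Tensor, context: Tensor | None,
                              training: bool = False, rng=None) -> Tensor:
        """Numeric-stream queries attend over the categorical context.

        ``query_stream`` is (B, D); an empty context passes it through with
        a warning.  Output shape equals the query-stream shape.
        """
        rng = rng if rng is not None else self.rng
        if context is None or context.shape[1] == 0 or "cross.attn.Wq" not in self.params:
            warnings.warn("empty cross-attention context: pass-through")
            return query_stream
        p = self.params
        b, d = query_stream.shape
        q3 = ad.reshape(query_stream, (b, 1, d))
        qn = ad.layer_norm(q3, p["cross.ln1.g"], p["cross.ln1.b"])
        cn = ad.layer_norm(context, p["cross.lnc.g"], p["cross.lnc.b"])
        attn_out = self._mha("cross", qn, cn, training, rng)
        q3 = self._residual(q3, self._dropout(attn_out, training, rng), training, rng)
        normed = ad.layer_norm(q3, p["cross.ln2.g"], p["cross.ln2.b"])
        q3 = self._residual(q3, self._ffn("cross", normed, training, rng), training, rng)
        return ad.reshape(q3, (b, d))

    def fuse_and_head(self, tokens: Tensor | None, num_stream: Tensor | None,
                      training: bool = False, rng=None) -> Tensor:
        """Mean-pool tokens, concatenate the numeric stream, 3-linear MLP,
        softmax over the classes."""
        rng = rng if rng is not None else self.rng
        parts = []
        if tokens is not None and tokens.shape[1] > 0:
            parts.append(ad.tmean(tokens, axis=1))
        if num_stream is not None:
            parts.append(num_stream)
        fused = parts[0] if len(parts) == 1 else ad.concat(parts, axis=-1)
        p = self.params
        h = ad.gelu(ad.add(ad.matmul(fused, p["head.W1"]), p["head.b1"]))
        h = self._dropout(h, training, rng)
        h = ad.gelu(ad.add(ad.matmul(h, p["head.W2"]), p["head.b2"]))
        h = self._dropout(h, training, rng)
        logits = ad.add(ad.matmul(h, p["head.W3"]), p["head.b3"])
        return ad.softmax(logits, axis=-1)

    def forward(self, x_num, x_cat, training: bool = False, rng=None) -> Tensor:
        rng = rng if rng is not None else self.rng
        num_stream, tokens = self.embed_features(x_num, x_cat)
        if tokens is not None:
            for b in range(self.config.n_self_blocks):
                tokens = self.self_attention_block(b, tokens, training, rng)
        if self.config.cross_attention and num_stream is not None and tokens is not None:
            num_stream = self.cross_attention_block(num_stream, tokens, training, rng)
        return self.fuse_and_head(tokens, num_stream, training, rng)

    def predict_proba(self, x_num, x_cat) -> np.ndarray:
        """Deterministic evaluation-mode class probabilities (B, 2)."""
        return self.forward(x_num, x_cat, training=False).data

    # --------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=float).copy()

    def save(self, path) -> None:
        meta = {
            "n_numeric": self.n_numeric,
            "cat_cardinalities": self.cat_cardinalities,
            "config": self.config.__dict__,
            "seed": self.seed,
        }
        np.savez(path, __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "AttentionClassifier":
        import ast

        data = np.load(path)
        meta = ast.literal_eval(bytes(data["__meta__"]).decode())
        cfg = ArchitectureConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in meta["config"].items()})
        model = cls(meta["n_numeric"], meta["cat_cardinalities"], cfg, meta["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def cross_entropy(probs: Tensor, y: np.ndarray) -> Tensor:
    onehot = np.eye(probs.shape[1])[np.asarray(y, dtype=int)]
    logp = ad.log(ad.add(probs, 1e-12))
    return ad.mul(ad.tsum(ad.mul(logp, onehot)), -1.0 / probs.shape[0])


@dataclass
class TrainResult:
    model: AttentionClassifier
    history: list[dict] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1


def train_model(
    model: AttentionClassifier,
    x_num_train, x_cat_train, y_train,
    x_num_val, x_cat_val, y_val,
    thresholds: StoppingThresholds | None = None,
    rule: DecisionRule | None = None,
    lr: float = 1e-3,
    weight_decay: float = 0.01,
    batch_size: int = 128,
    seed: int = 0,
) -> TrainResult:
    """Cross-entropy + Lion training with the six-metric stopping rule.

    After every epoch the six validation metrics are computed (decisions via
    ``rule``); training stops when all clear their thresholds or
    ``max_epochs`` is reached.  The checkpoint with the best validation AUC
    is restored into ``model`` before returning.
    """
    from .metrics import evaluate_scores

    thresholds = thresholds if thresholds is not None else StoppingThresholds()
    rule = rule if rule is not None else DecisionRule()
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    opt = Lion(model.params, lr=lr, weight_decay=weight_decay)
    n = len(y_train)
    history: list[dict] = []
    best_auc, best_state, best_epoch = -np.inf, None, -1
    stopped = False

    for epoch in range(thresholds.max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            xb_num = x_num_train[idx] if x_num_train is not None else None
            xb_cat = x_cat_train[idx] if x_cat_train is not None else None
            probs = model.forward(xb_num, xb_cat, training=True, rng=rng)
            loss = cross_entropy(probs, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()

        val_probs = model.predict_proba(x_num_val, x_cat_val)[:, 1]
        report = evaluate_scores(y_val, val_probs, rule=rule)
        record = {"epoch": epoch, **report.as_dict()}
        history.append(record)
        auc = report.auc if report.auc is not None else -np.inf
        if auc > best_auc:
            best_auc, best_state, best_epoch = auc, model.state_dict(), epoch
        met = all(
            (getattr(report, k) or 0.0) >= getattr(thresholds, k)
            for k in ("accuracy", "precision", "recall", "specificity", "f1", "auc")
        )
        if met:
            stopped = True
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, stopped_early=stopped,
                       best_epoch=best_epoch)
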