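"""Intra-sentence CNN relation classifier (numpy, manual backpropagation).

The network scores one chemical–disease mention pair.  Token indices are
embedded through a learned table T (the ``<PAD>`` column is frozen at zero).
Dependency-path windows are stacked into a matrix X0 of shape (v*d0, 3l) and
convolved::

    Z = W1 X0 + b1            (convolution over all window positions)
    m_i = max_j Z[i, j]       (max-over-time pooling; PAD-centered columns
                               are excluded from the max by default)
    d = tanh(m)               (dependency feature vector, length n1)

The contextual feature vector c (mention means, window contexts, in-between
verbs) is concatenated with d into k = [c, d], then::

    r = tanh(W2 k + b2)
    h = r ∘ m / (1-p)         (inverted dropout, training only)
    o = W3 h + b3             (softmax scores over relation labels)

Training minimizes the L2-regularized mean negative log-likelihood

    J(θ) = -(1/m) Σ log p(y_i | x_i, θ) + λ ||θ||²

over θ = {T, W1, b1, W2, b2, W3, b3} with mini-batch AdaGrad.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .features import EncodedInstance, Vocabulary, n_context_slots

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "cidre-cnn-1"

NEGATIVE_LABEL = 0
POSITIVE_LABEL = 1


@dataclass
class CnnHyperparameters:
    """Architecture and optimizer settings.

    Defaults follow the reference configuration: contextual window w=5, path
    window v=9, n1=300 convolution filters, n2=1500 hidden units, binary
    output, λ=1e-4, dropout 0.3, AdaGrad learning rate 0.002, mini-batch 64,
    300-dimensional embeddings.
    """

    d0: int = 300
    w: int = 5
    v: int = 9
    n1: int = 300
    n2: int = 1500
    n3: int = 2
    lam: float = 1e-4
    p_drop: float = 0.3
    lr: float = 0.002
    batch: int = 64
    epochs: int = 15
    v_max: int = 5
    l_max: int = 40
    seed: int = 0
    pool_include_pad: bool = False  # pool over PAD-centered columns too
    pool_per_path: bool = False  # pool each of R2C/R2D/C2D separately
    adagrad_eps: float = 1e-8
    init_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 1")
        if self.v < 1 or self.v % 2 == 0:
            raise ValueError("v must be odd and >= 1")
        if not (0.0 <= self.p_drop < 1.0):
            raise ValueError("p_drop must be in [0, 1)")

    @property
    def context_dim(self) -> int:
        return self.d0 * n_context_slots(self.w, self.v_max)

    @property
    def pooled_dim(self) -> int:
        return self.n1 * (3 if self.pool_per_path else 1)

    @property
    def nf(self) -> int:
        return self.pooled_dim + self.context_dim


@dataclass
class CnnParameters:
    """θ = {T, W1, b1, W2, b2, W3, b3}; T columns are per-token embeddings."""

    T: np.ndarray  # (d0, |V|)
    W1: np.ndarray  # (n1, v*d0)
    b1: np.ndarray  # (n1,)
    W2: np.ndarray  # (n2, nf)
    b2: np.ndarray  # (n2,)
    W3: np.ndarray  # (n3, n2)
    b3: np.ndarray  # (n3,)

    def names(self) -> tuple[str, ...]:
        return ("T", "W1", "b1", "W2", "b2", "W3", "b3")

    def copy(self) -> "CnnParameters":
        return CnnParameters(**{n: getattr(self, n).copy() for n in self.names()})


def init_parameters(
    vocab: Vocabulary,
    hyper: CnnHyperparameters,
    rng: np.random.Generator,
    init_vectors: Mapping[str, Sequence[float]] | None = None,
) -> CnnParameters:
    """Uniform(-s, s) initialization; supplied word vectors override columns.

    Tokens found in ``init_vectors`` (e.g. pretrained embeddings) keep their
    vector; every other token gets a random substitute.  The ``<PAD>`` column
    is zero and stays zero throughout training.
    """
    s = hyper.init_scale
    nv = len(vocab)
    T = rng.uniform(-s, s, size=(hyper.d0, nv))
    if init_vectors:
        for token, idx in vocab.to_dict().items():
            vec = init_vectors.get(token)
            if vec is not None:
                if len(vec) != hyper.d0:
                    raise ValueError(
                        f"init vector for {token!r} has dimension {len(vec)}, "
                        f"expected {hyper.d0}"
                    )
                T[:, idx] = vec
    T[:, vocab.pad_id] = 0.0
    return CnnParameters(
        T=T,
        W1=rng.uniform(-s, s, size=(hyper.n1, hyper.v * hyper.d0)),
        b1=rng.uniform(-s, s, size=hyper.n1),
        W2=rng.uniform(-s, s, size=(hyper.n2, hyper.nf)),
        b2=rng.uniform(-s, s, size=hyper.n2),
        W3=rng.uniform(-s, s, size=(hyper.n3, hyper.n2)),
        b3=rng.uniform(-s, s, size=hyper.n3),
    )


# ---------------------------------------------------------------------------
# Forward pieces


def lookup(T: np.ndarray, ids: Sequence[int]) -> np.ndarray:
    """Embed a token-index sequence as a d0 x n matrix (one column per token)."""
    if len(ids) == 0:
        raise ValueError("empty token sequence")
    return T[:, np.asarray(ids, dtype=np.intp)]


def mention_embedding(T: np.ndarray, ids: Sequence[int]) -> np.ndarray:
    """Mean of the token embeddings of a (multi-token) mention."""
    return lookup(T, ids).mean(axis=1)


def window_ids(path_ids: np.ndarray, v: int, pad_id: int) -> np.ndarray:
    """(3*L, v) token ids: for every path position, its centered v-window."""
    n_paths, length = path_ids.shape
    half = (v - 1) // 2
    padded = np.full((n_paths, length + 2 * half), pad_id, dtype=np.intp)
    padded[:, half : half + length] = path_ids
    cols = np.arange(length)[:, None] + np.arange(v)[None, :]
    out = padded[:, cols]  # (3, L, v)
    return out.reshape(n_paths * length, v)


def build_x0(
    T: np.ndarray, path_ids: np.ndarray, v: int, pad_id: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack window embeddings into X0 (v*d0, 3L); also return ids and mask.

    The mask marks columns whose *center* token is a real (non-PAD) token;
    the default pooling maximizes over those columns only.
    """
    wids = window_ids(path_ids, v, pad_id)  # (3L, v)
    d0 = T.shape[0]
    ncol = wids.shape[0]
    emb = T[:, wids.reshape(-1)]  # (d0, 3L*v), col-major over windows
    X0 = emb.reshape(d0, ncol, v).transpose(2, 0, 1).reshape(v * d0, ncol)
    mask = path_ids.reshape(-1) != pad_id
    return X0, wids, mask


def conv_pool(
    X0: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    pad_mask: np.ndarray | None = None,
    blocks: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convolve, max-pool and squash: d = tanh(max_j (W1 X0 + b1)[:, j]).

    ``pad_mask`` (length = #columns) excludes PAD-centered columns from the
    max; if every column of a block is masked the max falls back to all
    columns, with a warning.  ``blocks`` pools each (start, stop) column range
    separately and concatenates (per-path pooling); default is one block over
    all columns.  Returns (d, pooled m, argmax column per output coordinate).
    """
    Z = W1 @ X0 + b1[:, None]
    ncol = Z.shape[1]
    if pad_mask is None:
        pad_mask = np.ones(ncol, dtype=bool)
    if blocks is None:
        blocks = [(0, ncol)]
    pooled = []
    arg = []
    for start, stop in blocks:
        mask = pad_mask[start:stop]
        zb = Z[:, start:stop]
        if not mask.any():
            logger.warning("conv_pool: all columns masked; pooling over all")
            mask = np.ones(stop - start, dtype=bool)
        zm = np.where(mask[None, :], zb, -np.inf)
        idx = np.argmax(zm, axis=1)
        pooled.append(zm[np.arange(zb.shape[0]), idx])
        arg.append(idx + start)
    m = np.concatenate(pooled)
    d = np.tanh(m)
    return d, m, np.concatenate(arg)


def softmax(o: np.ndarray) -> np.ndarray:
    e = np.exp(o - o.max())
    return e / e.sum()


@dataclass
class ForwardCache:
    """Intermediate quantities of one forward pass, kept for backprop."""

    X0: np.ndarray
    wids: np.ndarray
    mask: np.ndarray
    blocks: list[tuple[int, int]]
    argmax: np.ndarray
    c: np.ndarray
    d: np.ndarray
    k: np.ndarray
    r: np.ndarray
    drop_mask: np.ndarray | None
    h: np.ndarray
    probs: np.ndarray


def context_vector(T: np.ndarray, slots: Sequence[Sequence[int]]) -> np.ndarray:
    return np.concatenate([mention_embedding(T, s) for s in slots])


def forward(
    enc: EncodedInstance,
    params: CnnParameters,
    hyper: CnnHyperparameters,
    pad_id: int,
    train: bool = False,
    rng: np.random.Generator | None = None,
    drop_mask: np.ndarray | None = None,
) -> ForwardCache:
    """One forward pass; in train mode dropout is applied (inverted scaling).

    ``drop_mask`` overrides the random mask (used by the gradient checker to
    freeze the dropout pattern).
    """
    X0, wids, mask = build_x0(params.T, enc.path_ids, hyper.v, pad_id)
    if hyper.pool_include_pad:
        mask = np.ones_like(mask)
    l = enc.path_ids.shape[1]
    blocks = (
        [(i * l, (i + 1) * l) for i in range(enc.path_ids.shape[0])]
        if hyper.pool_per_path
        else [(0, X0.shape[1])]
    )
    d, _, argmax = conv_pool(X0, params.W1, params.b1, mask, blocks)
    c = context_vector(params.T, enc.context_slots)
    k = np.concatenate([c, d])
    r = np.tanh(params.W2 @ k + params.b2)
    if train and hyper.p_drop > 0.0:
        if drop_mask is None:
            if rng is None:
                raise ValueError("train-mode forward needs an rng or drop_mask")
            drop_mask = (rng.random(hyper.n2) >= hyper.p_drop).astype(float)
        h = r * drop_mask / (1.0 - hyper.p_drop)
    else:
        drop_mask = None
        h = r
    o = params.W3 @ h + params.b3
    if not np.all(np.isfinite(o)):
        raise FloatingPointError("non-finite activations (training diverged?)")
    probs = softmax(o)
    return ForwardCache(X0, wids, mask, blocks, argmax, c, d, k, r, drop_mask, h, probs)


def _backward(
    enc: EncodedInstance,
    cache: ForwardCache,
    params: CnnParameters,
    hyper: CnnHyperparameters,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate dJ_i/dθ for one instance into ``grads`` (data term only)."""
    y = enc.label
    do = cache.probs.copy()
    do[y] -= 1.0  # softmax cross-entropy gradient

    grads["W3"] += np.outer(do, cache.h)
    grads["b3"] += do
    dh = params.W3.T @ do
    if cache.drop_mask is not None:
        dr = dh * cache.drop_mask / (1.0 - hyper.p_drop)
    else:
        dr = dh
    dpre2 = dr * (1.0 - cache.r**2)
    grads["W2"] += np.outer(dpre2, cache.k)
    grads["b2"] += dpre2
    dk = params.W2.T @ dpre2

    ctx_dim = hyper.context_dim
    dc = dk[:ctx_dim]
    dd = dk[ctx_dim:]
    dm = dd * (1.0 - cache.d**2)

    # pooled max: route each coordinate's gradient to its argmax column
    n1 = hyper.n1
    dT = grads["T"]
    d0 = hyper.d0
    for b, (start, stop) in enumerate(cache.blocks):
        rows = np.arange(n1)
        cols = cache.argmax[b * n1 : (b + 1) * n1]
        dmb = dm[b * n1 : (b + 1) * n1]
        # dZ is nonzero only at (row, argmax[row]) within this block
        sub = np.zeros((n1, stop - start))
        sub[rows, cols - start] = dmb
        grads["W1"] += sub @ cache.X0[:, start:stop].T
        grads["b1"] += dmb
        dX0 = params.W1.T @ sub  # (v*d0, block width)
        # scatter into T through the window token ids
        dcols = dX0.reshape(hyper.v, d0, stop - start).transpose(1, 2, 0)
        flat = cache.wids[start:stop].reshape(-1)
        np.add.at(dT.T, flat, dcols.reshape(d0, -1).T)

    # contextual slots: mean over slot token ids
    for s, slot in enumerate(enc.context_slots):
        g = dc[s * d0 : (s + 1) * d0] / len(slot)
        for tid in slot:
            dT[:, tid] += g


def loss_and_gradients(
    batch: Sequence[EncodedInstance],
    params: CnnParameters,
    hyper: CnnHyperparameters,
    pad_id: int,
    rng: np.random.Generator | None = None,
    train: bool = True,
    drop_masks: Sequence[np.ndarray] | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean NLL over the batch plus λ||θ||², with analytic gradients.

    The ``<PAD>`` embedding column is excluded from the penalty and its
    gradient is zeroed (it is a structural constant, not a parameter).
    """
    if not batch:
        raise ValueError("empty batch")
    grads = {n: np.zeros_like(getattr(params, n)) for n in params.names()}
    nll = 0.0
    for i, enc in enumerate(batch):
        dm = drop_masks[i] if drop_masks is not None else None
        cache = forward(
            enc, params, hyper, pad_id, train=train, rng=rng, drop_mask=dm
        )
        nll -= np.log(max(cache.probs[enc.label], 1e-300))
        _backward(enc, cache, params, hyper, grads)
    m = len(batch)
    for n in grads:
        grads[n] /= m
    reg = 0.0
    for n in params.names():
        p = getattr(params, n)
        reg += float((p**2).sum())
        grads[n] += 2.0 * hyper.lam * p
    # the PAD column is a structural constant: no penalty, no gradient
    reg -= float((params.T[:, pad_id] ** 2).sum())
    grads["T"][:, pad_id] = 0.0
    J = nll / m + hyper.lam * reg
    return float(J), grads


# ---------------------------------------------------------------------------
# Training, prediction, checkpointing


@dataclass
class CnnModel:
    """A trained intra-sentence classifier: parameters + vocab + settings."""

    hyper: CnnHyperparameters
    vocab: Vocabulary
    params: CnnParameters
    loss_trace: list[float] = field(default_factory=list)

    def predict(
        self, instances: Sequence[EncodedInstance]
    ) -> list[tuple[int, float]]:
        """(label, confidence) per instance; deterministic (no dropout).

        The label is the argmax of the softmax scores; an exact tie resolves
        to the negative label.
        """
        out = []
        for enc in instances:
            cache = forward(enc, self.params, self.hyper, self.vocab.pad_id)
            label = int(np.argmax(cache.probs))
            out.append((label, float(cache.probs[label])))
        return out


def train_cnn(
    instances: Sequence[EncodedInstance],
    hyper: CnnHyperparameters,
    vocab: Vocabulary,
    init_vectors: Mapping[str, Sequence[float]] | None = None,
    seed: int | None = None,
) -> CnnModel:
    """Mini-batch AdaGrad training of the full network.

    Per-coordinate accumulators G grow with squared gradients and each update
    is lr * g / sqrt(G + eps).  All randomness (init, shuffling, dropout)
    derives from ``seed`` (default ``hyper.seed``); two runs with the same
    seed produce bit-identical parameters.
    """
    for enc in instances:
        if enc.label is None or not (0 <= enc.label < hyper.n3):
            raise ValueError("every training instance needs a label in [0, n3)")
    rng = np.random.default_rng(hyper.seed if seed is None else seed)
    params = init_parameters(vocab, hyper, rng, init_vectors)
    accum = {n: np.zeros_like(getattr(params, n)) for n in params.names()}
    order = np.arange(len(instances))
    trace: list[float] = []
    for epoch in range(hyper.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), hyper.batch):
            batch = [instances[i] for i in order[start : start + hyper.batch]]
            J, grads = loss_and_gradients(
                batch, params, hyper, vocab.pad_id, rng=rng, train=True
            )
            if not np.isfinite(J):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: J={J}"
                )
            epoch_losses.append(J)
            for n in params.names():
                g = grads[n]
                G = accum[n]
                G += g**2
                getattr(params, n)[...] -= (
                    hyper.lr * g / np.sqrt(G + hyper.adagrad_eps)
                )
        params.T[:, vocab.pad_id] = 0.0
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else float("nan")
        trace.append(mean_loss)
        logger.info("epoch %d: mean batch loss %.6f", epoch, mean_loss)
    return CnnModel(hyper=hyper, vocab=vocab, params=params, loss_trace=trace)


def save_checkpoint(model: CnnModel, path) -> None:
    """Single-archive checkpoint: hyperparameters, vocabulary, parameters."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "hyper": asdict(model.hyper),
        "vocab": model.vocab.to_dict(),
        "loss_trace": model.loss_trace,
    }
    arrays = {n: getattr(model.params, n) for n in model.params.names()}
    with open(path, "wb") as fh:
        np.savez(fh, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> CnnModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format: {meta.get('format')}")
        hyper = CnnHyperparameters(**meta["hyper"])
        vocab = Vocabulary.from_dict(meta["vocab"])
        params = CnnParameters(
            **{n: data[n] for n in ("T", "W1", "b1", "W2", "b2", "W3", "b3")}
        )
    return CnnModel(
        hyper=hyper, vocab=vocab, params=params, loss_trace=meta["loss_trace"]
    )
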