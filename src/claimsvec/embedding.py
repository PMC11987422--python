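"""Skip-gram negative-sampling (SGNS) embeddings over the code vocabulary.

The trainer maximises, for each observed (center, context) code pair and
``negative`` noise codes drawn from the unigram^0.75 distribution,

    log sigma(w . c)  +  sum_neg log sigma(-w . c_neg)

by sequential stochastic gradient descent with a linearly decaying learning
rate — the classic word2vec objective, applied to unordered code documents
whose token order is re-randomised every epoch.  Training is single-threaded
and bit-reproducible given (corpus, config, seed).

Only the input ("word") matrix is released; the context matrix is an
internal training artifact, kept in memory for objective evaluation but
discarded on save.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numba
import numpy as np
import pandas as pd

from .corpus import CodeDocument

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """SGNS hyperparameters.

    ``k`` defaults to 200, the dimensionality used for the released claims
    weight table.  ``window`` caps the sliding-window radius; documents are
    unordered, so after per-epoch shuffling the window simply samples random
    co-occurring codes.  ``subsample`` is the word2vec frequent-token
    threshold t (keep probability ``sqrt(t/f) + t/f`` for corpus frequency
    f); 0 disables it.
    """

    k: int = 200
    window: int = 8
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    min_count: int = 5
    subsample: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


class EmbeddingTable:
    """Token -> k-vector weight table plus training metadata."""

    def __init__(
        self,
        tokens: Sequence[str],
        vectors: np.ndarray,
        metadata: dict | None = None,
        context_vectors: np.ndarray | None = None,
    ):
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
            raise ValueError("vectors must be a (n_tokens, k) matrix")
        if not np.isfinite(vectors).all():
            raise ValueError("all embedding entries must be finite")
        self.tokens = list(tokens)
        self.vectors = vectors
        self.metadata = dict(metadata or {})
        self.context_vectors = context_vectors
        self._row = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self._row) != len(self.tokens):
            raise ValueError("duplicate tokens in embedding table")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._row

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._row[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in embedding table") from None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.vectors, columns=[f"w{i + 1}" for i in range(self.k)]
        )
        frame.insert(0, "token", self.tokens)
        return frame


@numba.njit(cache=True)
def _sgns_sgd(W, C, centers, contexts, negatives, alpha0, alpha_min, step0, total_steps):  # pragma: no cover - jit
    n_pairs = centers.shape[0]
    k = W.shape[1]
    n_neg = negatives.shape[1]
    grad = np.empty(k, dtype=np.float32)
    for i in range(n_pairs):
        alpha = alpha0 * (1.0 - (step0 + i) / total_steps)
        if alpha < alpha_min:
            alpha = alpha_min
        c_idx = centers[i]
        ctx = contexts[i]
        for d in range(k):
            grad[d] = 0.0
        for j in range(n_neg + 1):
            if j == 0:
                t_idx = ctx
                label = 1.0
            else:
                t_idx = negatives[i, j - 1]
                if t_idx == ctx:
                    continue
                label = 0.0
            dot = 0.0
            for d in range(k):
                dot += W[c_idx, d] * C[t_idx, d]
            if dot > 8.0:
                pred = 1.0
            elif dot < -8.0:
                pred = 0.0
            else:
                pred = 1.0 / (1.0 + math.exp(-dot))
            g = np.float32((label - pred) * alpha)
            for d in range(k):
                grad[d] += g * C[t_idx, d]
                C[t_idx, d] += g * W[c_idx, d]
        for d in range(k):
            W[c_idx, d] += grad[d]


def sgns_loss(
    W: np.ndarray,
    C: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    negatives: np.ndarray,
) -> float:
    """Mean negative-sampling loss (negated objective) on fixed pairs."""

    def log_sigmoid(x):
        return -np.logaddexp(0.0, -x)

    w = W[centers].astype(np.float64)
    pos = np.einsum("ij,ij->i", w, C[contexts].astype(np.float64))
    neg = np.einsum("ij,inj->in", w, C[negatives].astype(np.float64))
    loss = -log_sigmoid(pos) - log_sigmoid(-neg).sum(axis=1)
    return float(loss.mean())


def _epoch_pairs(
    docs_idx: list[np.ndarray],
    keep_prob: np.ndarray,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle, subsample, and emit (center, context) index pairs."""
    order = rng.permutation(len(docs_idx))
    kept: list[np.ndarray] = []
    for di in order:
        t = docs_idx[di]
        t = t[rng.random(t.size) < keep_prob[t]]
        if t.size >= 2:
            kept.append(t[rng.permutation(t.size)])
    if not kept:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    flat = np.concatenate(kept)
    doc_ids = np.repeat(np.arange(len(kept)), [t.size for t in kept])
    centers, contexts = [], []
    for d in range(1, window + 1):
        if d >= flat.size:
            break
        same = doc_ids[d:] == doc_ids[:-d]
        a, b = flat[:-d][same], flat[d:][same]
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    cen = np.concatenate(centers).astype(np.int32)
    ctx = np.concatenate(contexts).astype(np.int32)
    perm = rng.permutation(cen.size)
    return cen[perm], ctx[perm]


def _draw_negatives(
    noise_cdf: np.ndarray, n_pairs: int, n_neg: int, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random((n_pairs, n_neg))
    return np.searchsorted(noise_cdf, u, side="right").astype(np.int32)


def train_embeddings(
    corpus: Sequence[CodeDocument], config: TrainingConfig
) -> EmbeddingTable:
    """Train SGNS embeddings; deterministic given (corpus, config).

    The vocabulary is rebuilt from the corpus with ``config.min_count``;
    metadata records the hyperparameters and the negative-sampling loss on a
    fixed evaluation set before and after training.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for doc in corpus:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    tokens = sorted(
        (t for t, c in counts.items() if c >= config.min_count),
        key=lambda t: (-counts[t], t),
    )
    if len(tokens) < 2:
        raise ValueError(
            "vocabulary must contain >= 2 tokens for negative sampling "
            f"(got {len(tokens)} with min_count={config.min_count})"
        )
    row = {t: i for i, t in enumerate(tokens)}
    freq = np.array([counts[t] for t in tokens], dtype=np.float64)
    total = freq.sum()

    docs_idx = []
    for doc in corpus:
        idx = np.array([row[t] for t in doc.tokens if t in row], dtype=np.int32)
        if idx.size >= 2:
            docs_idx.append(idx)
    if not docs_idx:
        raise ValueError("no document retains >= 2 in-vocabulary tokens")

    if config.subsample > 0:
        f = freq / total
        keep_prob = np.minimum(
            1.0, np.sqrt(config.subsample / f) + config.subsample / f
        )
    else:
        keep_prob = np.ones(len(tokens))

    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    V, k = len(tokens), config.k
    rng_init = np.random.default_rng([config.seed, 11])
    W = rng_init.uniform(-0.5 / k, 0.5 / k, (V, k)).astype(np.float32)
    C = np.zeros((V, k), dtype=np.float32)

    epoch_data = []
    rng0 = np.random.default_rng([config.seed, 101, 0])
    cen0, ctx0 = _epoch_pairs(docs_idx, keep_prob, config.window, rng0)
    if cen0.size == 0:
        raise ValueError("subsampling removed all co-occurrence pairs")
    neg0 = _draw_negatives(noise_cdf, cen0.size, config.negative, rng0)
    epoch_data.append((cen0, ctx0, neg0))

    n_eval = min(50_000, cen0.size)
    eval_set = (cen0[:n_eval].copy(), ctx0[:n_eval].copy(), neg0[:n_eval].copy())
    loss_initial = sgns_loss(W, C, *eval_set)

    total_steps = max(1, cen0.size * config.epochs)
    step = 0
    for epoch in range(config.epochs):
        if epoch < len(epoch_data):
            cen, ctx, neg = epoch_data[epoch]
        else:
            rng_e = np.random.default_rng([config.seed, 101, epoch])
            cen, ctx = _epoch_pairs(docs_idx, keep_prob, config.window, rng_e)
            neg = _draw_negatives(noise_cdf, cen.size, config.negative, rng_e)
        if cen.size == 0:
            continue
        _sgns_sgd(
            W, C, cen, ctx, neg,
            float(config.alpha), float(config.min_alpha),
            step, total_steps,
        )
        step += cen.size
    loss_final = sgns_loss(W, C, *eval_set)
    logger.info(
        "trained %d-dim embeddings for %d tokens (%d pairs/epoch); "
        "eval loss %.4f -> %.4f",
        k, V, cen0.size, loss_initial, loss_final,
    )
    metadata = {
        "k": k,
        "window": config.window,
        "negative": config.negative,
        "epochs": config.epochs,
        "alpha": config.alpha,
        "min_count": config.min_count,
        "subsample": config.subsample,
        "seed": config.seed,
        "n_documents": len(docs_idx),
        "pairs_per_epoch": int(cen0.size),
        "loss_initial": loss_initial,
        "loss_final": loss_final,
    }
    return EmbeddingTable(tokens, W, metadata, context_vectors=C)


def save_weights(table: EmbeddingTable, path: str | Path, sep: str | None = None) -> None:
    """Write the weight table as delimited text, header ``token,w1..wk``.

    Floats are written with 9 significant digits, which round-trips float32
    exactly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.9g")


def load_weights(path: str | Path, sep: str | None = None) -> EmbeddingTable:
    """Load a weight table written by :func:`save_weights`."""
    path = Path(path)
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype={"token": str})
    if frame.columns[0] != "token":
        raise ValueError("weight file must start with a 'token' column")
    mat = frame.iloc[:, 1:].to_numpy()
    bad = ~np.isfinite(mat).all(axis=1)
    if bad.any():
        tok = frame["token"].iloc[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"ragged or non-numeric weight row for token {tok!r}")
    return EmbeddingTable(frame["token"].tolist(), mat.astype(np.float32))


def nearest_codes(
    table: EmbeddingTable, token: str, n: int = 10
) -> list[tuple[str, float]]:
    """Top-``n`` tokens by cosine similarity to ``token`` (query excluded).

    Ties are broken by token lexicographic order; zero vectors have cosine 0
    with everything.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if token not in table:
        raise KeyError(f"token {token!r} not in embedding table")
    norms = np.linalg.norm(table.vectors, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = table.vectors / safe[:, None]
    q = unit[table._row[token]]
    sims = unit @ q
    ranked = sorted(
        (
            (tok, float(sims[i]))
            for i, tok in enumerate(table.tokens)
            if tok != token
        ),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:n]
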