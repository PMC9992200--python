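"""Unsupervised report classification via skip-gram word vectors.

Trains skip-gram embeddings (negative sampling, seeded numpy SGD) on the
report corpus, embeds reference phrases by token averaging, and labels a
report by the maximum cosine similarity of its sliding token windows
against positive vs negative reference phrases.

The trainer is intentionally self-contained: it runs single-threaded on
numpy only, so identical (corpus, config) pairs give bit-identical
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from cxrnlp.lexicon import Lexicon, TokenSequence, tokenize

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "ReferencePhrases",
    "train_skipgram",
    "embed_phrase",
    "cosine_similarity",
    "classify_by_embedding",
    "default_reference_phrases",
    "save_word2vec_text",
    "load_word2vec_text",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Skip-gram training configuration.

    ``window`` and ``dim`` follow the reference setup (10 and 100); the
    remaining knobs are implementation defaults, all exposed here.
    """

    window: int = 10
    dim: int = 100
    min_count: int = 2
    epochs: int = 5
    seed: int = 0
    objective: str = "negative_sampling"
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    batch_size: int = 1024
    subsample: float = 1e-3  # frequent-token downsampling threshold (0 disables)
    max_update: float = 0.5  # element-wise clip on accumulated batch updates

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.objective != "negative_sampling":
            raise NotImplementedError("only the negative_sampling objective is implemented")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")


@dataclass
class EmbeddingModel:
    """token -> fixed-dimension vector map with its training config."""

    vocabulary: dict  # token -> row index
    vectors: np.ndarray  # (V, dim)
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("vectors must be (V, dim) aligned with the vocabulary")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocabulary[token]]


@dataclass(frozen=True)
class ReferencePhrases:
    """Positive and negative anchor phrases for the cosine rule."""

    positive: tuple[TokenSequence, ...]
    negative: tuple[TokenSequence, ...]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("both positive and negative reference phrase lists must be non-empty")


def default_reference_phrases(lexicon: Lexicon) -> ReferencePhrases:
    """Anchor phrases derived from lexicon polarities (hedged excluded)."""
    pos = tuple(tokenize(e.phrase) for e in lexicon.entries if e.polarity == "indicates_pneumonia")
    neg = tuple(tokenize(e.phrase) for e in lexicon.entries if e.polarity == "indicates_no_pneumonia")
    return ReferencePhrases(positive=pos, negative=neg)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_skipgram(corpus: Iterable[TokenSequence], config: EmbeddingConfig = EmbeddingConfig()) -> EmbeddingModel:
    """Train skip-gram vectors with negative sampling.

    Vocabulary keeps tokens with frequency >= min_count, ordered by
    descending frequency (ties lexicographic) for determinism. Context
    pairs use the standard shrunk-window weighting: a pair at distance d
    within the maximum window is kept with probability
    (window - d + 1) / window each epoch. Negatives are drawn from the
    unigram^0.75 distribution. The learning rate decays linearly over all
    processed pairs.
    """
    sentences = [tuple(s.tokens) if isinstance(s, TokenSequence) else tuple(s) for s in corpus]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("corpus is empty")

    counts: dict[str, int] = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab_tokens = sorted(
        (t for t, c in counts.items() if c >= config.min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab_tokens:
        raise ValueError(f"no token reaches min_count={config.min_count}")
    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    V = len(vocab)

    rng = np.random.default_rng(config.seed)

    total = sum(counts[t] for t in vocab_tokens)
    keep_prob = np.ones(V)
    if config.subsample > 0:
        f = np.array([counts[t] / total for t in vocab_tokens])
        keep_prob = np.minimum(1.0, np.sqrt(config.subsample / f) + config.subsample / f)

    encoded = []
    for s in sentences:
        rows = np.array([vocab[t] for t in s if t in vocab], dtype=np.int64)
        if rows.size and config.subsample > 0:
            rows = rows[rng.random(rows.size) < keep_prob[rows]]
        if rows.size >= 2:
            encoded.append(rows)

    # all in-window (center, context, distance) candidates, built once
    cs, os_, ds = [], [], []
    for s in encoded:
        L = s.size
        for d in range(1, min(config.window, L - 1) + 1):
            cs.append(s[:-d])
            os_.append(s[d:])
            ds.append(np.full(L - d, d, dtype=np.int64))
    if not cs:
        raise ValueError("corpus has no co-occurring token pairs within the window")
    centers_all = np.concatenate(cs + os_)  # both directions of each pair
    contexts_all = np.concatenate(os_ + cs)
    dists_all = np.concatenate(ds + ds)

    W_in = (rng.random((V, config.dim)) - 0.5) / config.dim
    W_out = np.zeros((V, config.dim))

    freq = np.array([counts[t] for t in vocab_tokens], dtype=np.float64)
    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    keep_p = (config.window - dists_all + 1) / config.window
    total_expected = max(1.0, float(keep_p.sum()) * config.epochs)
    processed = 0.0
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    K = config.negative

    for _ in range(config.epochs):
        keep = rng.random(keep_p.size) < keep_p
        c_ep = centers_all[keep]
        o_ep = contexts_all[keep]
        order = rng.permutation(c_ep.size)
        c_ep, o_ep = c_ep[order], o_ep[order]
        for start in range(0, c_ep.size, config.batch_size):
            c = c_ep[start : start + config.batch_size]
            o = o_ep[start : start + config.batch_size]
            B = c.size
            lr = max(lr_min, lr0 * (1.0 - processed / total_expected))
            negs = np.searchsorted(noise_cdf, rng.random((B, K)))

            h = W_in[c]  # (B, d)
            out_pos = W_out[o]  # (B, d)
            out_neg = W_out[negs]  # (B, K, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", h, out_pos)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", h, out_neg))  # (B, K)

            # accumulate, clip, then apply: duplicated indices within a batch
            # can otherwise compound into runaway updates on tiny vocabularies
            clip = config.max_update
            grad_in = g_pos[:, None] * out_pos + np.einsum("bk,bkd->bd", g_neg, out_neg)
            upd_in = np.zeros_like(W_in)
            np.add.at(upd_in, c, lr * grad_in)
            upd_out = np.zeros_like(W_out)
            np.add.at(upd_out, o, lr * (g_pos[:, None] * h))
            np.add.at(
                upd_out,
                negs.ravel(),
                lr * (g_neg[:, :, None] * h[:, None, :]).reshape(B * K, config.dim),
            )
            W_in -= np.clip(upd_in, -clip, clip)
            W_out -= np.clip(upd_out, -clip, clip)
            processed += B

    if not np.isfinite(W_in).all():
        raise ArithmeticError("training diverged: non-finite vectors")
    return EmbeddingModel(vocabulary=vocab, vectors=W_in, config=config)


def embed_phrase(phrase: TokenSequence, model: EmbeddingModel) -> np.ndarray:
    """Element-wise mean of the in-vocabulary token vectors of a phrase.

    Out-of-vocabulary tokens are skipped (not zero-imputed); a phrase
    with no in-vocabulary token at all is an error.
    """
    tokens = phrase.tokens if isinstance(phrase, TokenSequence) else tuple(phrase)
    rows = [model.vocabulary[t] for t in tokens if t in model.vocabulary]
    if not rows:
        raise ValueError(f"phrase {' '.join(tokens)!r} has no in-vocabulary tokens")
    return model.vectors[rows].mean(axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _window_means(rows: np.ndarray, model: EmbeddingModel, window: int) -> np.ndarray:
    """Mean vector of every contiguous window of `window` in-vocab-masked
    tokens; windows without any in-vocab token are dropped."""
    n = rows.size
    width = min(window, n)
    vecs = np.zeros((n, model.dim))
    mask = rows >= 0
    vecs[mask] = model.vectors[rows[mask]]
    csum = np.vstack([np.zeros(model.dim), np.cumsum(vecs, axis=0)])
    ccnt = np.concatenate([[0], np.cumsum(mask)])
    starts = np.arange(n - width + 1)
    sums = csum[starts + width] - csum[starts]
    cnts = ccnt[starts + width] - ccnt[starts]
    valid = cnts > 0
    return sums[valid] / cnts[valid, None]


def classify_by_embedding(
    report: TokenSequence,
    model: EmbeddingModel,
    refs: ReferencePhrases,
    window: Optional[int] = None,
) -> tuple[int, dict]:
    """Label a report by max window-vs-reference cosine similarity.

    Every contiguous window of ``window`` tokens (the whole report if
    shorter) is embedded by token averaging and scored against each
    reference phrase; the report is called positive iff the best positive
    score strictly exceeds the best negative score (ties -> negative).
    Returns the label and both best scores.
    """
    if window is None:
        window = model.config.window
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens = report.tokens if isinstance(report, TokenSequence) else tuple(report)
    rows = np.array([model.vocabulary.get(t, -1) for t in tokens], dtype=np.int64)
    if rows.size == 0 or (rows < 0).all():
        raise ValueError("report has no in-vocabulary tokens")

    W = _window_means(rows, model, window)
    W = W / np.linalg.norm(W, axis=1, keepdims=True)

    def _best(phrases: Sequence[TokenSequence]) -> float:
        R = np.vstack([embed_phrase(p, model) for p in phrases])
        R = R / np.linalg.norm(R, axis=1, keepdims=True)
        return float(np.max(W @ R.T))

    score_pos = _best(refs.positive)
    score_neg = _best(refs.negative)
    label = int(score_pos > score_neg)
    return label, {"score_pos": score_pos, "score_neg": score_neg, "n_windows": int(W.shape[0])}


def save_word2vec_text(model: EmbeddingModel, path) -> None:
    """Plain-text word2vec format: header "V dim", then one token per line."""
    inv = sorted(model.vocabulary, key=model.vocabulary.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(inv)} {model.dim}\n")
        for tok in inv:
            vals = " ".join(repr(float(x)) for x in model.vector(tok))
            fh.write(f"{tok} {vals}\n")


def load_word2vec_text(path, config: Optional[EmbeddingConfig] = None) -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed word2vec text header")
        v, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.zeros((v, dim))
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"malformed vector line {i + 2}")
            vocab[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1:]]
    if len(vocab) != v:
        raise ValueError("vocabulary size does not match header")
    return EmbeddingModel(vocabulary=vocab, vectors=vectors, config=config or EmbeddingConfig(dim=dim))
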