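"""Reference multi-label coder: embeddings, a convolution, per-label
attention, per-label sigmoid outputs.

The architecture follows the convolutional-attention family of automated
coding models: word embeddings feed a single 1-D convolution; each label
owns an attention vector that pools the convolved sequence into a
label-specific document representation, scored by a label-specific output
vector.  Training minimizes binary cross-entropy for a fixed number of
epochs, evaluating mean average precision (mAP) on the development split
after every epoch and keeping the parameters of the best epoch.  The
implementation is plain vectorized numpy with analytically derived
gradients and Adam updates, which is fast enough for the desk-scale
corpora this package targets and keeps the training loop fully
seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .corpus import Corpus, Document, preprocess_text
from .errors import DivergenceError, EmptyTrainError, UndefinedMetricError
from .hierarchy import CodeId

PAD, UNK = 0, 1


@dataclass(frozen=True)
class CoderConfig:
    min_freq: int = 1
    embed_dim: int = 32
    num_filters: int = 64
    kernel_size: int = 3
    epochs: int = 20
    threshold: float = 0.5
    learning_rate: float = 1e-2
    batch_size: int = 16
    max_len: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


def build_vocab(corpus: Corpus, cfg: CoderConfig) -> dict[str, int]:
    """Token -> id map from the training split, ids 0/1 reserved for
    padding/unknown; deterministic ordering (frequency, then lexicographic)."""
    train = corpus.split("train")
    if not train:
        raise EmptyTrainError("training split is empty")
    freq: dict[str, int] = {}
    for doc in train:
        for tok in preprocess_text(doc.text, max_tokens=cfg.max_len):
            freq[tok] = freq.get(tok, 0) + 1
    kept = sorted(
        (t for t, n in freq.items() if n >= cfg.min_freq),
        key=lambda t: (-freq[t], t),
    )
    vocab = {"<pad>": PAD, "<unk>": UNK}
    for tok in kept:
        vocab[tok] = len(vocab)
    return vocab


def _vectorize(docs: list[Document], vocab: dict[str, int], max_len: int) -> np.ndarray:
    ids = np.zeros((len(docs), max_len), dtype=np.int32)
    for i, doc in enumerate(docs):
        tokens = preprocess_text(doc.text, max_tokens=max_len)
        for j, tok in enumerate(tokens):
            ids[i, j] = vocab.get(tok, UNK)
    return ids


def _label_matrix(
    docs: list[Document], label_index: dict[CodeId, int]
) -> np.ndarray:
    y = np.zeros((len(docs), len(label_index)), dtype=np.float32)
    for i, doc in enumerate(docs):
        for code in doc.labels:
            j = label_index.get(code)
            if j is not None:
                y[i, j] = 1.0
    return y


def _init_params(cfg: CoderConfig, vocab_size: int, n_labels: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, f, k = cfg.embed_dim, cfg.num_filters, cfg.kernel_size

    def xavier(shape):
        bound = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-bound, bound, size=shape).astype(np.float32)

    params = {
        "E": rng.normal(0.0, 0.1, size=(vocab_size, d)).astype(np.float32),
        "Wc": xavier((k * d, f)),
        "bc": np.zeros(f, dtype=np.float32),
        "U": xavier((n_labels, f)),
        "Wo": xavier((n_labels, f)),
        "bo": np.zeros(n_labels, dtype=np.float32),
    }
    params["E"][PAD] = 0.0
    return params


def _forward(params, ids, want_cache=False):
    """Forward pass.  Returns probabilities (B, C) and optionally the cache
    needed for the backward pass."""
    E, Wc, bc, U, Wo, bo = (params[k] for k in ("E", "Wc", "bc", "U", "Wo", "bo"))
    B, L = ids.shape
    kd, f = Wc.shape
    d = E.shape[1]
    k = kd // d
    pad = k // 2
    mask = (ids != PAD).astype(np.float32)  # (B, L)

    H0 = E[ids] * mask[..., None]  # (B, L, d)
    H0p = np.pad(H0, ((0, 0), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(H0p, k, axis=1)  # (B,L,d,k)
    Xc = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, L, kd)
    H = np.tanh(Xc @ Wc + bc) * mask[..., None]  # (B, L, f)

    S = H @ U.T  # (B, L, C)
    S = np.where(mask[..., None] > 0, S, np.float32(-1e9))
    S -= S.max(axis=1, keepdims=True)
    expS = np.exp(S)
    A = expS / expS.sum(axis=1, keepdims=True)  # (B, L, C)

    M = A.transpose(0, 2, 1) @ H  # (B, C, f)
    logits = (M * Wo).sum(-1) + bo  # (B, C)
    probs = 1.0 / (1.0 + np.exp(-logits))
    if not want_cache:
        return probs, None
    return probs, {"mask": mask, "Xc": Xc, "H": H, "A": A, "M": M, "ids": ids}


def _backward(params, cache, dlogits):
    E, Wc, U, Wo = params["E"], params["Wc"], params["U"], params["Wo"]
    mask, Xc, H, A, M, ids = (
        cache["mask"], cache["Xc"], cache["H"], cache["A"], cache["M"], cache["ids"]
    )
    B, L, f = H.shape
    kd = Wc.shape[0]
    d = E.shape[1]
    k = kd // d
    pad = k // 2

    grads = {}
    grads["bo"] = dlogits.sum(0)
    grads["Wo"] = np.einsum("bc,bcf->cf", dlogits, M)
    dM = dlogits[..., None] * Wo[None]  # (B, C, f)

    dA = H @ dM.transpose(0, 2, 1)  # (B, L, C)
    dH = A @ dM  # (B, L, f), attention-pooling branch

    dS = A * (dA - (A * dA).sum(axis=1, keepdims=True))  # softmax backward
    dH += dS @ U
    grads["U"] = dS.reshape(-1, dS.shape[-1]).T @ H.reshape(-1, f)

    dZ = dH * (1.0 - H * H) * mask[..., None]
    grads["Wc"] = Xc.reshape(-1, kd).T @ dZ.reshape(-1, f)
    grads["bc"] = dZ.sum((0, 1))

    dXc = (dZ @ Wc.T).reshape(B, L, k, d)
    dH0p = np.zeros((B, L + 2 * pad, d), dtype=np.float32)
    for j in range(k):
        dH0p[:, j : j + L, :] += dXc[:, :, j, :]
    dH0 = dH0p[:, pad : pad + L, :] * mask[..., None]

    dE = np.zeros_like(E)
    np.add.at(dE, ids.ravel(), dH0.reshape(-1, d))
    dE[PAD] = 0.0
    grads["E"] = dE
    return grads


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedCoder:
    config: CoderConfig
    vocab: dict[str, int]
    labels: list[CodeId]
    params: dict[str, np.ndarray] = field(repr=False)
    selected_epoch: int
    dev_map_per_epoch: list[float]

    @property
    def label_index(self) -> dict[CodeId, int]:
        return {c: j for j, c in enumerate(self.labels)}

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": self.config.__dict__,
            "vocab": self.vocab,
            "labels": self.labels,
            "selected_epoch": self.selected_epoch,
            "dev_map_per_epoch": self.dev_map_per_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))
        path.with_suffix(".dev_map.csv").write_text(
            "epoch,dev_map\n" + "".join(
                f"{i},{m}\n" for i, m in enumerate(self.dev_map_per_epoch, 1)
            )
        )

    @classmethod
    def load(cls, path) -> "TrainedCoder":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as blob:
            params = {k: blob[k] for k in blob.files}
        return cls(
            config=CoderConfig(**meta["config"]),
            vocab=meta["vocab"],
            labels=meta["labels"],
            params=params,
            selected_epoch=meta["selected_epoch"],
            dev_map_per_epoch=meta["dev_map_per_epoch"],
        )


@dataclass
class Predictions:
    doc_ids: list[str]
    labels: list[CodeId]
    scores: np.ndarray = field(repr=False)  # (N, C) probabilities
    threshold: float

    @property
    def label_sets(self) -> list[set[CodeId]]:
        out = []
        for row in self.scores >= self.threshold:
            out.append({self.labels[j] for j in np.flatnonzero(row)})
        return out


def mean_average_precision(scores: np.ndarray, gold: np.ndarray) -> float:
    """Macro mAP: average precision of each label's document ranking,
    averaged over labels with at least one gold positive."""
    has_pos = gold.sum(axis=0) > 0
    if not has_pos.any():
        raise UndefinedMetricError("no label has a positive instance")
    cols = np.flatnonzero(has_pos)
    aps = [
        average_precision_score(gold[:, j], scores[:, j]) for j in cols
    ]
    return float(np.mean(aps))


def _trim(ids: np.ndarray) -> np.ndarray:
    """Drop all-padding trailing columns (cheap length bucketing)."""
    lengths = (ids != PAD).sum(axis=1)
    return ids[:, : max(int(lengths.max(initial=0)), 1)]


def _scores(params, ids, batch_size=256) -> np.ndarray:
    chunks = []
    for start in range(0, len(ids), batch_size):
        probs, _ = _forward(params, _trim(ids[start : start + batch_size]))
        chunks.append(probs)
    return np.concatenate(chunks, axis=0)


def train_coder(train: Corpus | list[Document], dev: Corpus | list[Document],
                cfg: CoderConfig = CoderConfig()) -> TrainedCoder:
    """Train for exactly ``cfg.epochs`` epochs, tracking dev mAP per epoch,
    and return the parameters of the best epoch (ties -> earliest).

    Labels are indexed from the training documents; dev-only labels are
    ignored (they cannot be learned and are scored zero downstream).
    """
    train_docs = train.split("train") if isinstance(train, Corpus) else list(train)
    dev_docs = dev.split("dev") if isinstance(dev, Corpus) else list(dev)
    if not train_docs:
        raise EmptyTrainError("training split is empty")
    if not dev_docs:
        raise ValueError("dev split is empty")

    vocab = build_vocab(Corpus([d.with_(split="train") for d in train_docs]), cfg)
    labels = sorted({c for d in train_docs for c in d.labels})
    label_index = {c: j for j, c in enumerate(labels)}
    dev_only = {c for d in dev_docs for c in d.labels} - set(labels)
    if dev_only:
        import logging

        logging.getLogger(__name__).warning(
            "%d dev-only labels ignored by the coder", len(dev_only)
        )

    ids_train = _vectorize(train_docs, vocab, cfg.max_len)
    y_train = _label_matrix(train_docs, label_index)
    ids_dev = _vectorize(dev_docs, vocab, cfg.max_len)
    y_dev = _label_matrix(dev_docs, label_index)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, len(vocab), len(labels), rng)
    opt = _Adam(params, cfg.learning_rate)

    best_map, best_epoch, best_params = -1.0, 0, None
    dev_maps: list[float] = []
    n = len(train_docs)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            probs, cache = _forward(params, _trim(ids_train[batch]), want_cache=True)
            y = y_train[batch]
            eps = 1e-9
            loss = -np.mean(
                np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps),
                       axis=1)
            )
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            dlogits = (probs - y) / len(batch)
            grads = _backward(params, cache, dlogits)
            opt.step(params, grads)
        dev_scores = _scores(params, ids_dev)
        try:
            epoch_map = mean_average_precision(dev_scores, y_dev)
        except UndefinedMetricError:
            epoch_map = 0.0
        dev_maps.append(epoch_map)
        if epoch_map > best_map:
            best_map, best_epoch = epoch_map, epoch
            best_params = {k: v.copy() for k, v in params.items()}

    return TrainedCoder(
        config=cfg,
        vocab=vocab,
        labels=labels,
        params=best_params,
        selected_epoch=best_epoch,
        dev_map_per_epoch=dev_maps,
    )


def predict(coder: TrainedCoder, docs: list[Document],
            threshold: float | None = None) -> Predictions:
    """Score documents; the predicted set per document is every label whose
    probability is >= the threshold (default: the training config's)."""
    if threshold is None:
        threshold = coder.config.threshold
    ids = _vectorize(docs, coder.vocab, coder.config.max_len)
    scores = _scores(coder.params, ids)
    return Predictions(
        doc_ids=[d.doc_id for d in docs],
        labels=list(coder.labels),
        scores=scores,
        threshold=threshold,
    )
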