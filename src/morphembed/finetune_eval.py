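"""Frozen-embedding evaluation and adapter/full fine-tuning.

Downstream protocols operate on an :class:`EmbeddingMatrix` of per-neuron
CLS vectors: k-nearest-neighbor probing of frozen embeddings, SMOTE-style
class rebalancing, stratified multi-seed condition benchmarking, and
supervised fine-tuning where either the whole encoder or only
per-layer adapters plus a linear classifier are trained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from ._autodiff import Adam, Tensor, log_softmax, wrap_params
from .encoder import EncoderCheckpoint, encode, forward, is_adapter_param
from .preprocess import center_tree, downsample_nodes, featurize, prune_axon
from .swc import NeuronTree


@dataclass
class EmbeddingMatrix:
    """Per-neuron fixed-length vectors aligned to neuron identifiers."""

    ids: list[str]
    vectors: np.ndarray                # (m, d)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("neuron ids must be unique")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("row count must match number of ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        if self.labels is not None and len(self.labels) != len(self.ids):
            raise ValueError("labels must align with ids")

    def subset(self, rows: np.ndarray) -> "EmbeddingMatrix":
        labels = ([self.labels[i] for i in rows]
                  if self.labels is not None else None)
        return EmbeddingMatrix(ids=[self.ids[i] for i in rows],
                               vectors=self.vectors[rows], labels=labels)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.vectors,
                             index=pd.Index(self.ids, name="id"))
        frame.columns = [f"e{j}" for j in range(self.vectors.shape[1])]
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load_tsv(cls, path) -> "EmbeddingMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        labels = None
        if "label" in frame.columns:
            labels = frame.pop("label").astype(str).tolist()
        return cls(ids=[str(i) for i in frame.index],
                   vectors=frame.to_numpy(float), labels=labels)


@dataclass
class EvalReport:
    """A metric aggregated over random seeds (mean and standard deviation)."""

    metric: str
    values: list[float]
    mean: float
    sd: float
    n_seeds: int
    split: float
    settings: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, metric: str, values: list[float], split: float,
                    **settings) -> "EvalReport":
        arr = np.asarray(values, dtype=float)
        return cls(metric=metric, values=list(map(float, arr)),
                   mean=float(arr.mean()), sd=float(arr.std(ddof=0)),
                   n_seeds=len(values), split=split, settings=settings)


# -- embedding -------------------------------------------------------------

def embed_dataset(trees: list[NeuronTree], ckpt: EncoderCheckpoint,
                  labels: list[str] | None = None, prune: bool = True,
                  downsample_to: int | None = None,
                  seed: int = 0) -> EmbeddingMatrix:
    """center -> (optional) prune -> (optional) downsample -> featurize ->
    encode, per neuron; fully deterministic."""
    vectors = []
    ids = []
    for j, tree in enumerate(trees):
        t = center_tree(tree)
        if prune:
            t = prune_axon(t)
        if downsample_to is not None:
            t = downsample_nodes(t, downsample_to, seed=seed + j)
        cls_vec, _ = encode(featurize(t), ckpt.params, ckpt.config)
        vectors.append(cls_vec)
        ids.append(tree.name if tree.name is not None else f"neuron{j:05d}")
    return EmbeddingMatrix(ids=ids, vectors=np.vstack(vectors), labels=labels)


# -- kNN probing -----------------------------------------------------------

def knn_classify(train: EmbeddingMatrix, test: EmbeddingMatrix,
                 k: int = 5) -> tuple[list[str], float | None]:
    """Euclidean k-NN with majority vote; ties go to the nearest neighbor
    whose label is among the tied classes.  Returns (predictions, accuracy);
    accuracy is None when the test set is unlabeled."""
    if train.labels is None:
        raise ValueError("training embeddings must carry labels")
    if not 1 <= k <= len(train.ids):
        raise ValueError(f"k={k} out of range for {len(train.ids)} "
                         "training points")
    nn = NearestNeighbors(n_neighbors=k).fit(train.vectors)
    _, neigh = nn.kneighbors(test.vectors)
    labels = np.asarray(train.labels, dtype=object)
    preds: list[str] = []
    for row in neigh:                       # row is sorted by distance
        votes: dict[str, int] = {}
        for j in row:
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        preds.append(next(labels[j] for j in row if labels[j] in tied))
    accuracy = None
    if test.labels is not None:
        accuracy = float(np.mean([p == t for p, t in zip(preds, test.labels)]))
    return preds, accuracy


# -- rebalancing -----------------------------------------------------------

def rebalance(train: EmbeddingMatrix, seed: int) -> EmbeddingMatrix:
    """Equalize class counts: oversample minorities by interpolation between
    same-class nearest neighbors (x + u * (x_nn - x), u ~ U[0,1]) and
    undersample majorities at random.  Target count is the rounded mean of
    the class counts."""
    if train.labels is None:
        raise ValueError("rebalance requires labels")
    rng = np.random.default_rng(seed)
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError("rebalance requires at least 2 classes")
    by_class = {c: np.flatnonzero(np.asarray(train.labels, object) == c)
                for c in classes}
    target = int(round(np.mean([len(v) for v in by_class.values()])))
    target = max(target, 1)
    vecs, ids, labels = [], [], []
    for c in classes:
        rows = by_class[c]
        x = train.vectors[rows]
        if len(rows) >= target:
            pick = rng.choice(len(rows), size=target, replace=False)
            for j in pick:
                vecs.append(x[j])
                ids.append(train.ids[rows[j]])
                labels.append(c)
            continue
        for j in range(len(rows)):
            vecs.append(x[j])
            ids.append(train.ids[rows[j]])
            labels.append(c)
        n_new = target - len(rows)
        if len(rows) == 1:
            warnings.warn(f"class {c!r} has a single member; "
                          "oversampling by duplication", stacklevel=2)
            for s in range(n_new):
                vecs.append(x[0].copy())
                ids.append(f"{train.ids[rows[0]]}__dup{s}")
                labels.append(c)
            continue
        k = min(5, len(rows) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, neigh = nn.kneighbors(x)
        for s in range(n_new):
            a = int(rng.integers(len(rows)))
            b = int(neigh[a][1 + rng.integers(k)])
            u = rng.uniform()
            vecs.append(x[a] + u * (x[b] - x[a]))
            ids.append(f"{c}__smote{s}")
            labels.append(c)
    return EmbeddingMatrix(ids=ids, vectors=np.vstack(vecs), labels=labels)


# -- condition benchmarking ------------------------------------------------

def condition_benchmark(embeddings: EmbeddingMatrix, n_seeds: int = 5,
                        split: float = 0.7, k: int = 5,
                        seed: int = 0) -> EvalReport:
    """Per seed: stratified split (``split`` fraction to train), rebalance
    the training portion, k-NN classify the rest; report mean +/- sd."""
    if embeddings.labels is None:
        raise ValueError("condition_benchmark requires labels")
    values = []
    for s in range(n_seeds):
        rows = np.arange(len(embeddings.ids))
        train_rows, test_rows = train_test_split(
            rows, train_size=split, random_state=seed + s,
            stratify=embeddings.labels)
        train = rebalance(embeddings.subset(train_rows), seed=seed + s)
        _, acc = knn_classify(train, embeddings.subset(test_rows), k=k)
        values.append(acc)
    return EvalReport.from_values(
        "knn_accuracy", values, split, k=k, n_seeds=n_seeds,
        stratified=True, rebalanced=True)


# -- supervised fine-tuning ------------------------------------------------

@dataclass
class FinetuneConfig:
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 1e-2   # adapters + linear head tolerate a fast rate
    val_fraction: float = 0.3
    seed: int = 0


@dataclass
class FinetuneResult:
    params: dict[str, np.ndarray]      # encoder (+ adapters)
    head: dict[str, np.ndarray]        # linear classifier
    classes: list[str]
    report: EvalReport


def finetune(ckpt: EncoderCheckpoint, trees: list[NeuronTree],
             labels: list[str], mode: str = "adapter",
             cfg: FinetuneConfig | None = None,
             prune: bool = True) -> FinetuneResult:
    """Train a linear classifier on CLS embeddings with cross-entropy.

    mode="adapter": the backbone stays bit-identical; only adapter and
    classifier parameters receive gradient updates (requires a checkpoint
    built with adapter_dim > 0).  mode="full": everything is trainable.
    """
    if cfg is None:
        cfg = FinetuneConfig()
    if mode not in ("adapter", "full"):
        raise ValueError("mode must be 'adapter' or 'full'")
    if mode == "adapter" and ckpt.config.adapter_dim <= 0:
        raise ValueError(
            "adapter fine-tuning needs a checkpoint with adapters; "
            "enable them with encoder.add_adapters(params, config, dim)")

    rng = np.random.default_rng(cfg.seed)
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])
    graphs = []
    for tree in trees:
        t = center_tree(tree)
        if prune:
            t = prune_axon(t)
        graphs.append(featurize(t))

    rows = np.arange(len(graphs))
    train_rows, val_rows = train_test_split(
        rows, test_size=cfg.val_fraction, random_state=cfg.seed, stratify=y)

    d = ckpt.config.d_model
    params = {k: Tensor(v.copy(),
                        requires_grad=(mode == "full" or is_adapter_param(k)))
              for k, v in ckpt.params.items()}
    head = wrap_params({
        "w": rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, len(classes))),
        "b": np.zeros(len(classes))}, requires_grad=True)
    trainable = dict(head)
    for name, t in params.items():
        if mode == "full" or is_adapter_param(name):
            trainable[f"enc::{name}"] = t
    optimizer = Adam(trainable, lr=cfg.learning_rate)

    for _ in range(cfg.epochs):
        order = rng.permutation(train_rows)
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits = []
            for i in batch:
                cls, _ = forward(graphs[i], params, ckpt.config)
                logits.append((cls.reshape(1, -1) @ head["w"] + head["b"]))
            lp = log_softmax(Tensor.cat(logits, axis=0), axis=-1)
            loss = -lp[np.arange(len(batch)), y[batch]].mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

    correct = []
    for i in val_rows:
        cls, _ = forward(graphs[i], params, ckpt.config)
        pred = int(np.argmax(cls.data @ head["w"].data + head["b"].data))
        correct.append(pred == y[i])
    acc = float(np.mean(correct))
    report = EvalReport.from_values(
        f"{mode}_finetune_accuracy", [acc], 1.0 - cfg.val_fraction,
        epochs=cfg.epochs, learning_rate=cfg.learning_rate, mode=mode)
    return FinetuneResult(
        params={k: t.data for k, t in params.items()},
        head={k: t.data for k, t in head.items()},
        classes=classes, report=report)
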