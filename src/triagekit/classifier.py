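"""Reference text classifier: hashed character n-grams + linear softmax.

The encoder is deliberately simple — counts of character 1..3-grams
hashed into a fixed-dimension bucket space, L2-normalised — because the
quantities under study (problem transformations and loss functions) act
on the probability head, not the encoder.  A transformer backend can be
slotted in behind the same contract: any encoder mapping text to a fixed
feature vector feeds the identical softmax head and loss suite (see
docs/methods.md for the adapter contract).

Training is full-batch gradient descent: the analytic loss gradient
w.r.t. probabilities from :mod:`triagekit.losses` is composed with the
softmax Jacobian, so any loss in the suite is trainable.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from . import losses as L
from .transforms import BinaryTask, MultiLabelDataset, SingleLabelDataset

__all__ = [
    "FeatureSpec",
    "TrainConfig",
    "LinearModel",
    "featurize",
    "featurize_batch",
    "train",
    "predict",
    "predict_proba",
    "train_binary_views",
    "predict_label_sets",
]

#: Version tag of the featurization (hash function + gram rules); bump on change.
FEATURE_VERSION = 1


@dataclass(frozen=True)
class FeatureSpec:
    """Character n-gram range and hashed feature dimension."""

    ngram_min: int = 1
    ngram_max: int = 3
    hash_dim: int = 2 ** 16

    def __post_init__(self) -> None:
        if not 1 <= self.ngram_min <= self.ngram_max:
            raise ValueError("need 1 <= ngram_min <= ngram_max")
        if self.hash_dim <= 0:
            raise ValueError("hash_dim must be > 0")


@dataclass
class TrainConfig:
    """Optimisation settings for the linear reference model."""

    learning_rate: float = 0.1
    epochs: int = 200
    seed: int = 0
    loss_id: str = "ce"
    init_scale: float = 0.0  # 0 => zero-initialised weights
    beta_cb: float = 0.999   # cb_focal only


def _grams(text: str, spec: FeatureSpec) -> list[str]:
    return [
        text[i : i + n]
        for n in range(spec.ngram_min, spec.ngram_max + 1)
        for i in range(len(text) - n + 1)
    ]


def _hash_gram(gram: str, dim: int) -> int:
    # blake2b is stable across platforms and Python versions (unlike hash())
    digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % dim


def featurize(text: str, spec: FeatureSpec = FeatureSpec()) -> np.ndarray:
    """L2-normalised hashed n-gram count vector (dense, length hash_dim)."""
    if not text:
        raise ValueError("cannot featurize empty text")
    vec = np.zeros(spec.hash_dim)
    for gram in _grams(text, spec):
        vec[_hash_gram(gram, spec.hash_dim)] += 1.0
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def featurize_batch(texts: list[str], spec: FeatureSpec = FeatureSpec()) -> sp.csr_matrix:
    """Sparse stacked featurization of many texts."""
    indptr = [0]
    indices: list[int] = []
    values: list[float] = []
    for text in texts:
        if not text:
            raise ValueError("cannot featurize empty text")
        counts: dict[int, float] = {}
        for gram in _grams(text, spec):
            h = _hash_gram(gram, spec.hash_dim)
            counts[h] = counts.get(h, 0.0) + 1.0
        norm = float(np.sqrt(sum(v * v for v in counts.values())))
        for h in sorted(counts):
            indices.append(h)
            values.append(counts[h] / norm if norm > 0 else 0.0)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(values), np.array(indices, dtype=np.int64), np.array(indptr, dtype=np.int64)),
        shape=(len(texts), spec.hash_dim),
    )


@dataclass
class LinearModel:
    """Linear softmax classifier over hashed n-gram features."""

    weights: np.ndarray           # hash_dim x C
    bias: np.ndarray              # C
    feature_spec: FeatureSpec
    class_vocab: dict[int, str]   # class_id (1-based) -> descriptor
    train_config: TrainConfig
    loss_trajectory: list[float] = field(default_factory=list)

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.class_vocab)

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "feature_spec": asdict(self.feature_spec),
            "feature_version": FEATURE_VERSION,
            "class_vocab": {str(k): v for k, v in self.class_vocab.items()},
            "train_config": asdict(self.train_config),
            "loss_trajectory": self.loss_trajectory,
        }
        np.savez_compressed(
            path,
            weights=self.weights,
            bias=self.bias,
            meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str) -> "LinearModel":
        archive = np.load(path)
        meta = json.loads(bytes(archive["meta"]).decode("utf-8"))
        return cls(
            weights=archive["weights"],
            bias=archive["bias"],
            feature_spec=FeatureSpec(**meta["feature_spec"]),
            class_vocab={int(k): v for k, v in meta["class_vocab"].items()},
            train_config=TrainConfig(**meta["train_config"]),
            loss_trajectory=list(meta["loss_trajectory"]),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_params(loss_id: str, params: object | None):
    if params is not None:
        return params
    if loss_id in {"focal", "cb_focal"}:
        return L.FocalParams()
    if loss_id in {"tversky", "ftl"}:
        return L.TverskyParams()
    if loss_id == "composite":
        return L.CompositeParams()
    return None


def train(
    data: SingleLabelDataset,
    config: TrainConfig | None = None,
    loss_params: object | None = None,
    spec: FeatureSpec = FeatureSpec(),
) -> LinearModel:
    """Fit the linear softmax model under the configured loss.

    Full-batch gradient descent on the softmax head: per epoch, the
    analytic ∂L/∂p is composed with the softmax Jacobian
    (∂L/∂z_j = p_j(g_j − Σ_k p_k g_k)) and applied with a fixed learning
    rate.  Deterministic given ``config.seed``; the per-epoch loss is
    recorded in ``loss_trajectory``.
    """
    config = config or TrainConfig()
    class_ids = sorted(data.class_vocab)
    if len(class_ids) < 2:
        raise ValueError("training needs at least 2 classes")
    present = {cid for _, cid, _ in data.rows}
    col = {cid: j for j, cid in enumerate(class_ids)}

    X = featurize_batch(data.texts(), spec)
    n, c = X.shape[0], len(class_ids)
    Y = np.zeros((n, c))
    for i, (_, cid, _) in enumerate(data.rows):
        Y[i, col[cid]] = 1.0
    class_counts = np.maximum(Y.sum(axis=0), 1.0)  # for cb_focal

    rng = np.random.default_rng(config.seed)
    if config.init_scale > 0:
        W = rng.normal(0.0, config.init_scale, size=(spec.hash_dim, c))
    else:
        W = np.zeros((spec.hash_dim, c))
    b = np.zeros(c)
    params = _loss_params(config.loss_id, loss_params)

    trajectory: list[float] = []
    for _ in range(config.epochs):
        P = _softmax(X @ W + b)
        value = L.loss_value(
            config.loss_id, P, Y, params,
            class_counts=class_counts, beta_cb=config.beta_cb,
        )
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite {config.loss_id} loss after {len(trajectory)} epochs"
            )
        trajectory.append(value)
        G = L.loss_gradient(
            config.loss_id, P, Y, params,
            class_counts=class_counts, beta_cb=config.beta_cb,
        )
        # softmax Jacobian: dL/dz = P * (G - rowsum(P*G))
        dZ = P * (G - (P * G).sum(axis=1, keepdims=True))
        W -= config.learning_rate * (X.T @ dZ)
        b -= config.learning_rate * dZ.sum(axis=0)

    model = LinearModel(W, b, spec, dict(data.class_vocab), config, trajectory)
    return model


def predict_proba(model: LinearModel, texts: list[str]) -> np.ndarray:
    """Softmax class probabilities, columns ordered by ascending class_id."""
    X = featurize_batch(texts, model.feature_spec)
    return _softmax(X @ model.weights + model.bias)


def predict(model: LinearModel, texts: list[str]) -> np.ndarray:
    """Most probable class id per text; ties break toward the lowest id."""
    probs = predict_proba(model, texts)
    ids = np.array(model.class_ids)
    return ids[np.argmax(probs, axis=1)]  # argmax returns the first maximum


# --------------------------------------------------------------------------
# BR / CC training on top of the reference model
# --------------------------------------------------------------------------

def _binary_dataset(task: BinaryTask) -> SingleLabelDataset:
    # class 1 = absent, class 2 = present; chain features appended as
    # sentinel tokens so the hashed featurizer sees them
    rows = []
    for text, prior_vals, target, prov in task.rows:
        aug = _augment_text(text, task.chain_prior, prior_vals)
        rows.append((aug, target + 1, prov))
    vocab = {1: f"not {task.label_name}", 2: task.label_name}
    return SingleLabelDataset(rows, vocab, method="binary")


def _augment_text(text: str, prior_ids: tuple[int, ...], prior_vals: tuple[int, ...]) -> str:
    if not prior_ids:
        return text
    flags = " ".join(f"\x1f{lid}={v}" for lid, v in zip(prior_ids, prior_vals))
    return f"{text} {flags}"


def train_binary_views(
    tasks: list[BinaryTask],
    config: TrainConfig | None = None,
    spec: FeatureSpec = FeatureSpec(),
) -> dict[int, LinearModel]:
    """One binary model per task (gold prior-label values at train time)."""
    models: dict[int, LinearModel] = {}
    for task in tasks:
        ds = _binary_dataset(task)
        if len({cid for _, cid, _ in ds.rows}) < 2:
            # degenerate task: label constant in training data; skip model,
            # predict the constant at inference
            models[task.label_id] = _constant_model(ds, spec, config or TrainConfig())
            continue
        models[task.label_id] = train(ds, config, spec=spec)
    return models


def _constant_model(
    ds: SingleLabelDataset, spec: FeatureSpec, config: TrainConfig
) -> LinearModel:
    constant = ds.rows[0][1]
    b = np.zeros(2)
    b[constant - 1] = 50.0  # saturates the softmax at the constant class
    return LinearModel(np.zeros((spec.hash_dim, 2)), b, spec, dict(ds.class_vocab), config)


def predict_label_sets(
    models: dict[int, LinearModel],
    tasks: list[BinaryTask],
    texts: list[str],
    threshold: float = 0.5,
) -> list[frozenset[int]]:
    """Predicted label set per text: labels whose probability exceeds 0.5.

    For classifier chains, each task consumes the *predicted* 0/1 values
    of earlier chain labels (gold values are only used in training).
    """
    n = len(texts)
    decided: dict[int, np.ndarray] = {}
    for task in sorted(tasks, key=lambda t: len(t.chain_prior)):
        model = models[task.label_id]
        aug = [
            _augment_text(
                texts[i],
                task.chain_prior,
                tuple(int(decided[p][i]) for p in task.chain_prior),
            )
            for i in range(n)
        ]
        probs = predict_proba(model, aug)
        present_col = model.class_ids.index(2)
        decided[task.label_id] = (probs[:, present_col] > threshold).astype(int)
    return [
        frozenset(lid for lid, flags in decided.items() if flags[i])
        for i in range(n)
    ]
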