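"""Siamese twin-tower metric model over encoded name strings.

Two weight-sharing encoder towers map a pair of names to summary vectors;
the merge layer compares them with the cosine distance (clipped to
[0, 1]) and training minimizes the contrastive loss: matching pairs
(label 0) are pulled to distance 0, distant pairs (label 1) are pushed
beyond a margin. After training, the model serves as a learned string
distance for top-k retrieval.

Architecture (defaults): integer-encoded characters are passed through a
per-position embedding network (two dense layers of 130 units, then a
30-dimensional output), a shared bidirectional LSTM with 65 units per
direction consumes the 65-position sequence, and the concatenated final
hidden states of the two directions form each tower's summary vector.
The output distance is ``d = min(1 - cos, 1)``: 0 for identical inputs,
0.5 at a 60-degree angle, 1 at orthogonality or beyond.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn, normalize
from .errors import IncompatibleManifest, InvalidConfig, ZeroVector
from .fuzzy import Method, RankedMatches
from .pairgen import LabeledPair, PairDataset

_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the Siamese model.

    ``recurrent_units`` is the LSTM hidden width per direction; the
    sequence length is fixed by the 65-position encoding. ``margin`` is
    the contrastive-loss margin in rescaled-distance units (the model
    distance lives in [0, 1], so margin 1.0 demands maximal separation).
    """

    max_len: int = normalize.MAX_LEN
    vocab_size: int = normalize.VOCAB_SIZE
    embed_hidden: int = 130
    embed_layers: int = 2
    embed_dim: int = 30
    recurrent_units: int = 65
    pooling: str = "final"  # tower summary: "final" hidden states or masked "mean"
    loss_space: str = "output"  # contrastive loss on the "output" (rescaled cosine)
    # distance or on the "euclidean" distance between tower summaries
    margin: float = 1.0
    dropout: float = 0.0  # inverted dropout on embedded characters (train only)
    learning_rate: float = 3e-3
    lr_schedule: str = "constant"  # "constant" or "cosine" decay over lr_decay_epochs
    lr_decay_epochs: int = 60
    lr_min_factor: float = 0.05
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 5
    min_delta: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.margin <= 0 or self.max_epochs < 1:
            raise InvalidConfig("embed_dim >= 1, margin > 0 and max_epochs >= 1 required")
        if self.embed_layers != 2:
            raise InvalidConfig("the embedding pipeline is fixed at two hidden layers")
        if self.vocab_size < 2 or self.recurrent_units < 1 or self.patience < 0:
            raise InvalidConfig("invalid vocab_size / recurrent_units / patience")
        if self.pooling not in ("final", "mean"):
            raise InvalidConfig("pooling must be 'final' or 'mean'")
        if self.lr_schedule not in ("constant", "cosine") or not 0.0 <= self.dropout < 1.0:
            raise InvalidConfig("bad lr_schedule or dropout")
        if self.loss_space not in ("output", "euclidean"):
            raise InvalidConfig("loss_space must be 'output' or 'euclidean'")


@dataclass
class TrainingHistory:
    """Per-epoch metrics; accuracy uses the 0.5 distance threshold."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return max(self.val_accuracy) if self.val_accuracy else float("nan")

    def to_csv(self, path: str | Path) -> None:
        import csv

        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"])
            for e in range(len(self.train_loss)):
                w.writerow([e + 1, self.train_loss[e], self.train_accuracy[e],
                            self.val_loss[e], self.val_accuracy[e]])


class SiameseModel:
    """Shared-weight twin encoder producing a distance in [0, 1]."""

    def __init__(self, config: ModelConfig, params: nn.ParamDict | None = None):
        self.config = config
        if params is None:
            rng = np.random.default_rng(config.seed)
            params = nn.init_params(
                config.vocab_size,
                config.embed_hidden,
                config.embed_dim,
                config.recurrent_units,
                rng,
            )
        self.params = params

    # Both towers are literally the same parameter set; expose that.
    @property
    def tower_params(self) -> tuple[nn.ParamDict, nn.ParamDict]:
        return self.params, self.params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Encode a batch of integer sequences into summary vectors."""
        v, _ = nn.encoder_forward(self.params, X, pooling=self.config.pooling)
        return v

    def embed_names(self, names: Sequence[str], *, batch_size: int = 512) -> np.ndarray:
        X = normalize.encode_batch(names, max_len=self.config.max_len)
        X = _trim(X)
        outs = [self.embed(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(outs, axis=0)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - (u . v) / (||u|| ||v||)``, in [0, 2].

    Raises
    ------
    ZeroVector
        If either vector has zero norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVector("cosine distance undefined for a zero vector")
    return float(1.0 - float(u @ v) / (nu * nv))


def contrastive_loss(distance, label, margin: float = 1.0) -> float:
    """Contrastive loss: ``d^2`` for matching (label 0), hinge for distant.

    Accepts scalars or arrays; arrays are averaged over the batch.
    """
    d = np.asarray(distance, dtype=float)
    y = np.asarray(label)
    if (d < 0).any() or margin <= 0:
        raise ValueError("distance must be >= 0 and margin > 0")
    loss = np.where(y == 0, d**2, np.maximum(0.0, margin - d) ** 2)
    return float(loss.mean())


def build_model(config: ModelConfig | None = None) -> SiameseModel:
    """Construct an untrained model from a configuration."""
    return SiameseModel(config or ModelConfig())


def _trim(X: np.ndarray) -> np.ndarray:
    """Drop the all-padding tail columns shared by a whole batch.

    Masked LSTM steps carry state unchanged and padded embedding positions
    are zeroed, so this is a pure speed optimization with identical output.
    """
    lengths = (X > 0).sum(axis=1)
    t = int(lengths.max()) if len(lengths) else 1
    return X[:, :t]


def _encode_pairs(pairs: Sequence[LabeledPair], max_len: int):
    qa = normalize.encode_batch([p.query for p in pairs], max_len=max_len)
    qb = normalize.encode_batch([p.target for p in pairs], max_len=max_len)
    y = np.array([p.label for p in pairs], dtype=np.int64)
    return qa, qb, y


def _evaluate(model: SiameseModel, Xa, Xb, y, margin: float, batch_size: int = 1024,
              loss_space: str = "output"):
    losses = []
    correct = 0
    n = len(y)
    for i in range(0, n, batch_size):
        sl = slice(i, i + batch_size)
        X = _trim(np.concatenate([Xa[sl], Xb[sl]], axis=0))
        v = model.embed(X)
        m = len(y[sl])
        d = nn.pair_distances_from_vectors(v[:m], v[m:])
        losses.append(nn.contrastive_loss_from_vectors(v[:m], v[m:], y[sl], margin,
                                                       loss_space) * m)
        correct += int(((d >= 0.5).astype(int) == y[sl]).sum())
    return sum(losses) / n, correct / n


def pair_accuracy_from_distances(d: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of pairs where ``(d >= threshold)`` equals the 0/1 label."""
    return float(((np.asarray(d) >= threshold).astype(int) == np.asarray(labels)).mean())


def train(
    model: SiameseModel,
    data: PairDataset,
    config: ModelConfig | None = None,
    *,
    verbose: bool = False,
) -> tuple[SiameseModel, TrainingHistory]:
    """Train with minibatch Adam, early stopping on validation loss.

    Stops when validation loss has not improved by ``min_delta`` for
    ``patience`` consecutive epochs (or at ``max_epochs``); the weights of
    the epoch with the best validation *accuracy* are kept.
    """
    config = config or model.config
    if not data.train or not data.validation:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    Xa, Xb, y = _encode_pairs(data.train, config.max_len)
    Va, Vb, vy = _encode_pairs(data.validation, config.max_len)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val_loss = np.inf
    best_val_acc = -np.inf
    best_params: nn.ParamDict | None = None
    wait = 0
    n = len(y)
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        if config.lr_schedule == "cosine":
            frac = min(1.0, (epoch - 1) / max(1, config.lr_decay_epochs - 1))
            scale = config.lr_min_factor + (1.0 - config.lr_min_factor) * 0.5 * (
                1.0 + np.cos(np.pi * frac)
            )
            opt.lr = config.learning_rate * scale
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            ba = Xa[idx]
            bb = Xb[idx]
            width = max(int((ba > 0).sum(1).max()), int((bb > 0).sum(1).max()))
            loss, d, grads = nn.loss_and_grads(
                model.params, ba[:, :width], bb[:, :width], y[idx], config.margin,
                pooling=config.pooling, loss_space=config.loss_space,
                dropout=config.dropout, dropout_rng=rng,
            )
            opt.step(model.params, grads)
            ep_loss += loss * len(idx)
            ep_correct += int(((d >= 0.5).astype(int) == y[idx]).sum())
        val_loss, val_acc = _evaluate(model, Va, Vb, vy, config.margin,
                                      loss_space=config.loss_space)
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_params = {k: p.copy() for k, p in model.params.items()}
            history.best_epoch = epoch
        if val_loss < best_val_loss - config.min_delta:
            best_val_loss = val_loss
            wait = 0
        else:
            wait += 1
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {ep_loss / n:.4f}  acc {ep_correct / n:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}  "
                f"[{time.perf_counter() - t0:.1f}s]"
            )
        history.stopped_epoch = epoch
        if wait > config.patience:
            break
    if best_params is not None:
        model.params = best_params
    return model, history


def pair_distance(model: SiameseModel, a: np.ndarray | str, b: np.ndarray | str) -> float:
    """Distance in [0, 1] between two names or encoded sequences.

    Deterministic given the model parameters; exactly 0 for identical
    inputs and symmetric under argument swap.
    """
    if isinstance(a, str):
        a = normalize.encode_name(a, max_len=model.config.max_len)
    if isinstance(b, str):
        b = normalize.encode_name(b, max_len=model.config.max_len)
    X = _trim(np.stack([np.asarray(a), np.asarray(b)]))
    v = model.embed(X)
    return float(nn.pair_distances_from_vectors(v[:1], v[1:])[0])


def pair_distances(model: SiameseModel, pairs: Sequence[LabeledPair]) -> np.ndarray:
    """Vectorized model distances for a list of labeled pairs."""
    Xa, Xb, _ = _encode_pairs(pairs, model.config.max_len)
    out = np.empty(len(pairs))
    bs = 1024
    for i in range(0, len(pairs), bs):
        X = _trim(np.concatenate([Xa[i : i + bs], Xb[i : i + bs]], axis=0))
        v = model.embed(X)
        m = min(bs, len(pairs) - i)
        out[i : i + m] = nn.pair_distances_from_vectors(v[:m], v[m:])
    return out


def sm_top_k(
    model: SiameseModel,
    query: str,
    corpus: Sequence[str],
    k: int = 20,
    *,
    corpus_vectors: np.ndarray | None = None,
) -> RankedMatches:
    """Rank a corpus by ascending model distance to the query.

    ``corpus_vectors`` (from :meth:`SiameseModel.embed_names`) can be
    passed to amortize corpus encoding across queries. Ties break by
    ascending candidate string.
    """
    corpus = list(corpus)
    if corpus_vectors is None:
        corpus_vectors = model.embed_names(corpus)
    qv = model.embed_names([query])
    d = nn.pair_distances_from_vectors(
        np.repeat(qv, len(corpus), axis=0), corpus_vectors
    )
    scored = sorted(zip(corpus, d.tolist()), key=lambda cs: (cs[1], cs[0]))
    entries = [(c, s, rank) for rank, (c, s) in enumerate(scored[:k], start=1)]
    return RankedMatches(query=query, method=Method.SM, k=k, entries=entries)


# ---------------------------------------------------------------------------
# Persistence


def _data_hash(data: PairDataset | None) -> str | None:
    if data is None:
        return None
    h = hashlib.sha256()
    for split in (data.train, data.validation, data.holdout):
        for p in split:
            h.update(f"{p.query}\t{p.target}\t{p.label}\n".encode())
    return h.hexdigest()[:16]


def save_model(
    model: SiameseModel,
    path: str | Path,
    *,
    history: TrainingHistory | None = None,
    data: PairDataset | None = None,
) -> None:
    """Persist weights plus a JSON manifest (config, seed, data hash, metrics)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.params)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "seed": model.config.seed,
        "data_hash": _data_hash(data),
        "n_parameters": model.n_parameters(),
    }
    if history is not None:
        manifest["best_epoch"] = history.best_epoch
        manifest["stopped_epoch"] = history.stopped_epoch
        manifest["best_val_accuracy"] = history.best_val_accuracy
        history.to_csv(path / "history.csv")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> SiameseModel:
    """Load a saved model, validating its manifest against the code.

    Raises
    ------
    IncompatibleManifest
        If the manifest is missing, from another format version, or its
        configuration does not reproduce the stored parameter shapes.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise IncompatibleManifest(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise IncompatibleManifest(
            f"format version {manifest.get('format_version')} != {_FORMAT_VERSION}"
        )
    try:
        config = ModelConfig(**manifest["config"])
    except (TypeError, KeyError, InvalidConfig) as exc:
        raise IncompatibleManifest(f"bad config in manifest: {exc}") from exc
    with np.load(path / "weights.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    expected = SiameseModel(config).params
    if set(expected) != set(params) or any(
        expected[k].shape != params[k].shape for k in expected
    ):
        raise IncompatibleManifest("stored weights do not match the manifest config")
    return SiameseModel(config, params)
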