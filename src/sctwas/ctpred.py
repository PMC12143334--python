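"""Feed-forward predictor of expression percentiles from feature vectors.

The architecture is an input projection (n_tracks -> 64) followed by three
identical 64 -> 64 hidden layers, each with ReLU and dropout (rate 0.05),
and a 64 -> 1 output head. Training minimizes MSE with L2 weight decay
(5e-4) using Adam; the checkpoint with the best validation loss within
``max_epochs`` is kept. With the full 5,313-track profile the model has
exactly 352,641 trainable parameters.

Genes are split into train/validation/test sets by chromosome so that no
sequence context is shared across sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epifeatures import GeneAnnotation

__all__ = [
    "CtPredHyperparams",
    "CtPredModel",
    "ChromosomeSplit",
    "split_by_chromosome",
    "train_ctpred",
    "predict",
    "evaluate_across_genes",
    "evaluate_across_individuals",
    "parameter_count",
    "save_model",
    "load_model",
]

HIDDEN_DIM = 64
N_HIDDEN_LAYERS = 4  # input projection + three identical hidden layers


@dataclass
class CtPredHyperparams:
    hidden_dim: int = HIDDEN_DIM
    n_hidden_layers: int = N_HIDDEN_LAYERS
    dropout: float = 0.05
    weight_decay: float = 5e-4
    max_epochs: int = 80
    patience: int = 10
    learning_rate: float = 3e-3
    batch_size: int | None = 32  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class CtPredModel:
    weights: list[np.ndarray]  # per layer, shape (d_in, d_out)
    biases: list[np.ndarray]   # per layer, shape (d_out,)
    hyperparams: CtPredHyperparams
    cell_type: str = ""
    train_chromosomes: tuple[str, ...] = ()
    # input standardization learned from the training genes
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)


def parameter_count(input_dim: int, hidden_dim: int = HIDDEN_DIM,
                    n_hidden_layers: int = N_HIDDEN_LAYERS) -> int:
    """Trainable parameter count of the architecture without instantiating it."""
    n = input_dim * hidden_dim + hidden_dim
    n += (n_hidden_layers - 1) * (hidden_dim * hidden_dim + hidden_dim)
    n += hidden_dim * 1 + 1
    return n


def _init_model(input_dim: int, hp: CtPredHyperparams, cell_type: str,
                rng: np.random.Generator) -> CtPredModel:
    dims = [input_dim] + [hp.hidden_dim] * hp.n_hidden_layers + [1]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return CtPredModel(weights=weights, biases=biases, hyperparams=hp, cell_type=cell_type)


def _forward(model: CtPredModel, X: np.ndarray, *, dropout_rng=None,
             ) -> tuple[np.ndarray, list]:
    """Returns predictions and the cache needed for backprop. Dropout is
    applied (inverted scaling) only when ``dropout_rng`` is supplied."""
    hp = model.hyperparams
    h = X
    cache = []
    n_layers = len(model.weights)
    for li, (W, b) in enumerate(zip(model.weights, model.biases)):
        a = h @ W + b
        if li < n_layers - 1:
            z = np.maximum(a, 0.0)
            if dropout_rng is not None and hp.dropout > 0:
                mask = (dropout_rng.random(z.shape) >= hp.dropout) / (1.0 - hp.dropout)
                z = z * mask
            else:
                mask = None
            cache.append((h, a, mask))
            h = z
        else:
            cache.append((h, a, None))
            h = a
    return h[:, 0], cache


def _backward(model: CtPredModel, cache: list, y_pred: np.ndarray, y: np.ndarray,
              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of mean squared error wrt all weights and biases."""
    hp = model.hyperparams
    n = len(y)
    delta = (2.0 / n) * (y_pred - y)[:, None]  # d MSE / d output
    grads_W: list[np.ndarray] = [None] * len(model.weights)
    grads_b: list[np.ndarray] = [None] * len(model.biases)
    n_layers = len(model.weights)
    for li in range(n_layers - 1, -1, -1):
        h_in, a, mask = cache[li]
        if li < n_layers - 1:
            if mask is not None:
                delta = delta * mask
            delta = delta * (a > 0)
        grads_W[li] = h_in.T @ delta
        grads_b[li] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ model.weights[li].T
    return grads_W, grads_b


def train_ctpred(features: Mapping[str, np.ndarray],
                 targets: Mapping[str, float],
                 split: "ChromosomeSplit",
                 genes: Sequence[GeneAnnotation],
                 hp: CtPredHyperparams | None = None,
                 cell_type: str = "",
                 ) -> tuple[CtPredModel, pd.DataFrame]:
    """Train on genes from the training chromosomes, checkpoint on the
    validation chromosomes; returns the best model and a per-epoch log.

    Raises on a feature/target key mismatch (missing genes listed) or a
    NaN loss (epoch reported).
    """
    hp = hp or CtPredHyperparams()
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    def collect(chroms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        ids = [g.gene_id for c in chroms for g in by_chrom.get(c, [])]
        missing = [g for g in ids if g not in features or g not in targets]
        if missing:
            raise KeyError(f"genes without features/targets: {missing[:10]}"
                           + ("..." if len(missing) > 10 else ""))
        X = np.vstack([features[g] for g in ids]) if ids else np.empty((0, 0))
        y = np.array([targets[g] for g in ids])
        return X, y, ids

    X_tr, y_tr, _ = collect(sorted(split.train))
    X_va, y_va, _ = collect(sorted(split.validation))
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("empty training or validation set")

    rng = np.random.default_rng(hp.seed)
    model = _init_model(X_tr.shape[1], hp, cell_type, rng)
    model.train_chromosomes = tuple(sorted(split.train))
    model.feature_mean = X_tr.mean(axis=0)
    model.feature_scale = np.where(X_tr.std(axis=0) > 1e-12, X_tr.std(axis=0), 1.0)
    X_tr = model.standardize(X_tr)
    X_va = model.standardize(X_va)

    # Adam state
    mW = [np.zeros_like(w) for w in model.weights]
    vW = [np.zeros_like(w) for w in model.weights]
    mB = [np.zeros_like(b) for b in model.biases]
    vB = [np.zeros_like(b) for b in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0

    n = len(y_tr)
    batch = hp.batch_size or n
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    log_rows = []

    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            y_pred, cache = _forward(model, X_tr[idx], dropout_rng=rng)
            gW, gB = _backward(model, cache, y_pred, y_tr[idx])
            t += 1
            for li in range(len(model.weights)):
                g = gW[li] + hp.weight_decay * model.weights[li]
                mW[li] = b1 * mW[li] + (1 - b1) * g
                vW[li] = b2 * vW[li] + (1 - b2) * g * g
                mhat = mW[li] / (1 - b1**t)
                vhat = vW[li] / (1 - b2**t)
                model.weights[li] -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
                g = gB[li]
                mB[li] = b1 * mB[li] + (1 - b1) * g
                vB[li] = b2 * vB[li] + (1 - b2) * g * g
                mhat = mB[li] / (1 - b1**t)
                vhat = vB[li] / (1 - b2**t)
                model.biases[li] -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)

        train_mse = float(np.mean((_forward(model, X_tr)[0] - y_tr) ** 2))
        val_mse = float(np.mean((_forward(model, X_va)[0] - y_va) ** 2))
        if not np.isfinite(train_mse) or not np.isfinite(val_mse):
            raise FloatingPointError(f"NaN/inf loss at epoch {epoch}")
        log_rows.append((epoch, train_mse, val_mse))
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_state = ([w.copy() for w in model.weights],
                          [b.copy() for b in model.biases])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= hp.patience:
                break

    if best_state is not None:
        model.weights, model.biases = best_state
    log = pd.DataFrame(log_rows, columns=["epoch", "train_mse", "val_mse"])
    return model, log


def predict(model: CtPredModel, features: np.ndarray | Mapping[str, np.ndarray],
            ) -> np.ndarray | pd.Series:
    """Deterministic forward pass (dropout disabled); outputs unclamped."""
    if isinstance(features, Mapping):
        ids = list(features)
        X = np.vstack([features[g] for g in ids])
        return pd.Series(predict(model, X), index=ids)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != model input dim {model.input_dim}")
    return _forward(model, model.standardize(X))[0]


# --------------------------------------------------------------------------
# chromosome splits
# --------------------------------------------------------------------------

@dataclass
class ChromosomeSplit:
    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [self.train, self.validation, self.test]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split chromosome sets must be disjoint")


def split_by_chromosome(genes: Sequence[GeneAnnotation],
                        fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                        seed: int = 0) -> ChromosomeSplit:
    """Shuffle chromosomes and assign each greedily to the set with the
    largest remaining gene-count deficit relative to its target fraction."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    chroms = sorted(counts)
    if len(chroms) < 3:
        raise ValueError(f"need >= 3 chromosomes, got {len(chroms)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(chroms))
    total = sum(counts.values())
    targets = [f * total for f in fractions]
    assigned: list[list[str]] = [[], [], []]
    sizes = [0, 0, 0]
    for c in order:
        deficits = [targets[k] - sizes[k] for k in range(3)]
        k = int(np.argmax(deficits))
        assigned[k].append(c)
        sizes[k] += counts[c]
    # guarantee non-empty sets
    for k in range(3):
        if not assigned[k]:
            donor = int(np.argmax([len(a) for a in assigned]))
            moved = assigned[donor].pop()
            assigned[k].append(moved)
    return ChromosomeSplit(train=frozenset(assigned[0]),
                           validation=frozenset(assigned[1]),
                           test=frozenset(assigned[2]), seed=seed)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate_across_genes(pred: np.ndarray, obs: np.ndarray,
                          ) -> tuple[float, float, int]:
    """Pearson r over genes; returns (r, two-sided p, n)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D and equally long")
    if len(pred) < 3:
        raise ValueError("need >= 3 genes")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("zero variance: Pearson r undefined")
    r, p = stats.pearsonr(pred, obs)
    return float(r), float(p), len(pred)


def evaluate_across_individuals(pred: pd.DataFrame, obs: pd.DataFrame,
                                ) -> tuple[pd.DataFrame, "object"]:
    """Per-gene Pearson r and two-sided p across individuals (rows = genes),
    plus the pi1/m1 summary over the resulting p-values.

    Constant rows (in either matrix) are skipped; the count is reported in
    the returned frame's ``attrs['n_skipped']``.
    """
    from .multicell import estimate_pi1

    if pred.shape[1] < 5:
        raise ValueError("need >= 5 individuals")
    common = pred.index.intersection(obs.index)
    rows = []
    skipped = 0
    for g in common:
        x = pred.loc[g].to_numpy(dtype=float)
        y = obs.loc[g, pred.columns].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            skipped += 1
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((g, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["gene_id", "r", "pvalue"])
    df.attrs["n_skipped"] = skipped
    est = estimate_pi1(df["pvalue"].to_numpy()) if len(df) else None
    return df, est


# --------------------------------------------------------------------------
# serialization: single .npz archive with a JSON header
# --------------------------------------------------------------------------

def save_model(model: CtPredModel, path: str | Path) -> None:
    header = {
        "hyperparams": asdict(model.hyperparams),
        "cell_type": model.cell_type,
        "train_chromosomes": list(model.train_chromosomes),
        "n_layers": len(model.weights),
    }
    arrays = {"__header__": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    np.savez(path, **arrays)


def load_model(path: str | Path) -> CtPredModel:
    data = np.load(path)
    header = json.loads(bytes(data["__header__"]).decode())
    n_layers = header["n_layers"]
    return CtPredModel(
        weights=[data[f"W{i}"] for i in range(n_layers)],
        biases=[data[f"b{i}"] for i in range(n_layers)],
        hyperparams=CtPredHyperparams(**header["hyperparams"]),
        cell_type=header["cell_type"],
        train_chromosomes=tuple(header["train_chromosomes"]),
        feature_mean=data.get("feature_mean"),
        feature_scale=data.get("feature_scale"),
    )
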