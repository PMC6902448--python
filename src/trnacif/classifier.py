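"""Multilayer-perceptron phyloclassifier over standardized score vectors.

The network maps a genome's standardized clade-score vector to a
classification probability vector over clades (soft-max output). The
training contract is full-batch quasi-Newton optimization (L-BFGS) of the
L2-penalized cross-entropy, rectifier hidden units, up to ``max_epochs``
iterations with an early stop once the loss improvement falls below
``tol``. Architecture is optimized by exhaustive search over small
hidden-layer configurations using leave-one-out cross-validation (LOOCV)
accuracy, in which the held-out genome is also excluded from its own
clade's logo estimation (handled upstream in the training matrix).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from trnacif.scoring import (
    ScoreStandardizer,
    ScoreVector,
    TrainingMatrix,
    apply_standardizer,
    fit_standardizer,
)

__all__ = [
    "NetworkSpec",
    "TrainedPhyloclassifier",
    "ClassificationReport",
    "train_network",
    "fit_phyloclassifier",
    "predict_probabilities",
    "loocv_accuracy",
    "search_architecture",
    "enumerate_architectures",
    "assess_equivocality",
    "oversample_indices",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the phyloclassifier network."""

    hidden_layers: tuple[int, ...] = (13,)
    activation: str = "relu"
    l2_alpha: float = 0.01
    max_epochs: int = 2000
    tol: float = 1e-4
    patience: int = 2
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden_layers must be a non-empty tuple of widths >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        object.__setattr__(self, "hidden_layers", tuple(int(w) for w in self.hidden_layers))

    def build(self) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layers,
            activation=self.activation,
            solver="lbfgs",
            alpha=self.l2_alpha,
            max_iter=self.max_epochs,
            tol=self.tol,
            shuffle=self.shuffle,
            random_state=self.seed,
        )

    def n_parameters(self, n_in: int, n_out: int) -> int:
        dims = (n_in, *self.hidden_layers, n_out)
        return sum((a + 1) * b for a, b in zip(dims[:-1], dims[1:]))

    def with_seed(self, seed: int) -> "NetworkSpec":
        return NetworkSpec(
            self.hidden_layers, self.activation, self.l2_alpha,
            self.max_epochs, self.tol, self.patience, self.shuffle, int(seed),
        )


@dataclass
class ClassificationReport:
    """Classification of one genome: full probability vector plus summary."""

    genome_id: str
    probabilities: dict[str, float]
    top_clade: str
    top_probability: float
    equivocal: bool | None = None
    tie: bool = False
    bootstrap_support: tuple[int, int] | None = None


@dataclass
class TrainedPhyloclassifier:
    """A fitted network together with its standardizer and clade order."""

    spec: NetworkSpec
    clade_order: tuple[str, ...]
    standardizer: ScoreStandardizer | None
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    fitted_classes: np.ndarray  # indices into clade_order seen at fit time
    training_log: dict = field(default_factory=dict)

    def predict_matrix(self, X_std: np.ndarray) -> np.ndarray:
        """Probability matrix (n, K) over ``clade_order`` via the network's
        forward pass (rectifier hiddens, soft-max output)."""
        z = np.asarray(X_std, dtype=float)
        if z.ndim == 1:
            z = z[None, :]
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            z = np.maximum(z @ W + b, 0.0)
        out = z @ self.coefs[-1] + self.intercepts[-1]
        if out.shape[1] == 1:  # two fitted classes: single logistic unit
            p1 = 1.0 / (1.0 + np.exp(-out[:, 0]))
            local = np.column_stack([1.0 - p1, p1])
        else:
            out -= out.max(axis=1, keepdims=True)
            e = np.exp(out)
            local = e / e.sum(axis=1, keepdims=True)
        probs = np.zeros((local.shape[0], len(self.clade_order)))
        probs[:, self.fitted_classes] = local
        return probs


def _fit_mlp(X: np.ndarray, y: np.ndarray, spec: NetworkSpec) -> MLPClassifier:
    model = spec.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, y)
    return model


def train_network(
    X: np.ndarray,
    y: Sequence[str],
    spec: NetworkSpec,
    clade_order: tuple[str, ...] | None = None,
    standardizer: ScoreStandardizer | None = None,
) -> TrainedPhyloclassifier:
    """Train the network on standardized score vectors.

    ``y`` are clade labels; ``clade_order`` fixes the output order (defaults
    to the sorted label set). Deterministic given ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    labels = list(y)
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("training requires >= 2 distinct clade labels")
    if clade_order is None:
        clade_order = tuple(present)
    index = {c: i for i, c in enumerate(clade_order)}
    try:
        y_int = np.array([index[c] for c in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc} not in clade_order {clade_order}") from exc
    model = _fit_mlp(X, y_int, spec)
    return TrainedPhyloclassifier(
        spec=spec,
        clade_order=tuple(clade_order),
        standardizer=standardizer,
        coefs=[np.asarray(c) for c in model.coefs_],
        intercepts=[np.asarray(b) for b in model.intercepts_],
        fitted_classes=np.asarray(model.classes_, dtype=int),
        training_log={"final_loss": float(model.loss_), "epochs_run": int(model.n_iter_)},
    )


def oversample_indices(labels: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """Row indices that balance clades by within-clade resampling with
    replacement up to the best-sampled clade's size. Original rows are
    always retained; only the additions are random."""
    labels = np.asarray(labels)
    clades, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    keep = [np.arange(len(labels))]
    for clade, count in zip(clades, counts):
        if count < target:
            pool = np.flatnonzero(labels == clade)
            keep.append(rng.choice(pool, size=target - count, replace=True))
    return np.concatenate(keep)


def fit_phyloclassifier(
    tm: TrainingMatrix,
    spec: NetworkSpec,
    balance: bool = False,
    balance_seed: int | None = None,
) -> TrainedPhyloclassifier:
    """Standardize the training matrix, optionally clade-balance it by
    oversampling, and train the network on all training genomes."""
    S, labels = tm.S, list(tm.labels)
    if balance:
        rng = np.random.default_rng(
            spec.seed if balance_seed is None else balance_seed
        )
        idx = oversample_indices(labels, rng)
        S = S[idx]
        labels = [labels[i] for i in idx]
    standardizer = fit_standardizer(S, tm.clade_order)
    return train_network(
        standardizer.transform(S), labels, spec, tm.clade_order, standardizer
    )


def _reports_from_probs(
    genome_ids: Sequence[str],
    probs: np.ndarray,
    clade_order: tuple[str, ...],
) -> list[ClassificationReport]:
    reports = []
    for gid, p in zip(genome_ids, probs):
        top = int(np.argmax(p))  # ties: first clade in clade_order wins
        tie = bool(np.sum(p == p[top]) > 1)
        if tie:
            logger.warning(
                "genome %s: tied top probability; reporting first clade in order (%s)",
                gid, clade_order[top],
            )
        reports.append(
            ClassificationReport(
                genome_id=str(gid),
                probabilities={c: float(v) for c, v in zip(clade_order, p)},
                top_clade=clade_order[top],
                top_probability=float(p[top]),
                tie=tie,
            )
        )
    return reports


def predict_probabilities(
    model: TrainedPhyloclassifier,
    vectors: Sequence[ScoreVector] | np.ndarray,
    genome_ids: Sequence[str] | None = None,
) -> list[ClassificationReport]:
    """Classify score vectors; raw vectors are standardized with the model's
    own standardizer first."""
    if isinstance(vectors, np.ndarray):
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        ids = list(genome_ids) if genome_ids is not None else [
            f"q{i}" for i in range(X.shape[0])
        ]
    else:
        ids, rows = [], []
        for v in vectors:
            if v.clade_order != model.clade_order:
                raise ValueError(
                    f"vector {v.genome_id}: clade order {v.clade_order} does not "
                    f"match model {model.clade_order}"
                )
            if v.standardized is not None:
                rows.append(v.standardized)
            else:
                if model.standardizer is None:
                    raise ValueError("model has no standardizer; pass standardized vectors")
                rows.append(apply_standardizer(v, model.standardizer).standardized)
            ids.append(v.genome_id)
        X = np.vstack(rows)
        return _reports_from_probs(ids, model.predict_matrix(X), model.clade_order)
    if model.standardizer is not None:
        X = model.standardizer.transform(X)
    return _reports_from_probs(ids, model.predict_matrix(X), model.clade_order)


def assess_equivocality(
    report: ClassificationReport, threshold: float = 0.80
) -> bool:
    """Equivocal ("none-of-the-above") when the top classification
    probability is below ``threshold``. Sets and returns the flag."""
    report.equivocal = bool(report.top_probability < threshold)
    return report.equivocal


# ---------------------------------------------------------------------------
# LOOCV and architecture search

def loocv_accuracy(
    tm: TrainingMatrix,
    spec: NetworkSpec,
    labels: Sequence[str] | None = None,
    balance: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy over training genomes.

    Each fold refits the standardizer and network on the remaining genomes'
    leave-one-out score vectors (optionally clade-balanced by oversampling)
    and classifies the held-out genome. ``labels`` overrides the matrix's
    true labels (used by the permutation test). Returns the accuracy and a
    per-genome outcome table.
    """
    S = tm.S
    y = list(labels) if labels is not None else list(tm.labels)
    if len(y) != S.shape[0]:
        raise ValueError("label count does not match matrix rows")
    n = S.shape[0]
    rng = np.random.default_rng(spec.seed)
    rows = []
    correct = 0
    all_idx = np.arange(n)
    for i in range(n):
        train = all_idx[all_idx != i]
        St = S[train]
        yt = [y[j] for j in train]
        if balance:
            bidx = oversample_indices(yt, rng)
            St = St[bidx]
            yt = [yt[j] for j in bidx]
        standardizer = fit_standardizer(St, tm.clade_order)
        model = train_network(
            standardizer.transform(St), yt, spec, tm.clade_order, standardizer
        )
        probs = model.predict_matrix(standardizer.transform(S[i]))
        report = _reports_from_probs([tm.genome_ids[i]], probs, tm.clade_order)[0]
        hit = report.top_clade == y[i]
        correct += hit
        rows.append(
            (tm.genome_ids[i], y[i], report.top_clade, report.top_probability, hit)
        )
    table = pd.DataFrame(
        rows, columns=["genome_id", "true_clade", "predicted_clade", "top_probability", "correct"]
    )
    return correct / n, table


def enumerate_architectures(
    layer_range: tuple[int, int] = (1, 4),
    width_range: tuple[int, int] = (8, 16),
) -> list[tuple[int, ...]]:
    """All hidden-layer configurations with the given layer count and
    per-layer width bounds (each layer's width varies independently)."""
    lo_l, hi_l = layer_range
    lo_w, hi_w = width_range
    if lo_l < 1 or hi_l < lo_l or lo_w < 1 or hi_w < lo_w:
        raise ValueError("empty architecture bounds")
    widths = range(lo_w, hi_w + 1)
    out: list[tuple[int, ...]] = []
    for n_layers in range(lo_l, hi_l + 1):
        out.extend(itertools.product(widths, repeat=n_layers))
    return out


def search_architecture(
    tm: TrainingMatrix,
    base_spec: NetworkSpec | None = None,
    layer_range: tuple[int, int] = (1, 4),
    width_range: tuple[int, int] = (8, 16),
    balance: bool = False,
) -> tuple[NetworkSpec, pd.DataFrame]:
    """Exhaustive architecture search by LOOCV accuracy.

    Ties are broken by fewest parameters, then fewest layers, then
    enumeration order — all deterministic.
    """
    if base_spec is None:
        base_spec = NetworkSpec()
    K = len(tm.clade_order)
    results = []
    best = None
    for arch in enumerate_architectures(layer_range, width_range):
        spec = NetworkSpec(
            arch, base_spec.activation, base_spec.l2_alpha, base_spec.max_epochs,
            base_spec.tol, base_spec.patience, base_spec.shuffle, base_spec.seed,
        )
        acc, _ = loocv_accuracy(tm, spec, balance=balance)
        n_par = spec.n_parameters(K, K)
        results.append((arch, len(arch), n_par, acc))
        key = (-acc, n_par, len(arch))
        if best is None or key < best[0]:
            best = (key, spec)
    table = pd.DataFrame(
        results, columns=["hidden_layers", "n_layers", "n_parameters", "loocv_accuracy"]
    )
    return best[1], table


# ---------------------------------------------------------------------------
# model persistence (versioned JSON archive)

def save_model(model: TrainedPhyloclassifier, path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "spec": asdict(model.spec),
        "clade_order": list(model.clade_order),
        "standardizer": None
        if model.standardizer is None
        else {
            "mean": model.standardizer.mean.tolist(),
            "sd": model.standardizer.sd.tolist(),
            "clade_order": list(model.standardizer.clade_order),
            "n_train": model.standardizer.n_train,
        },
        "coefs": [c.tolist() for c in model.coefs],
        "intercepts": [b.tolist() for b in model.intercepts],
        "fitted_classes": model.fitted_classes.tolist(),
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedPhyloclassifier:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    spec_d = payload["spec"]
    spec_d["hidden_layers"] = tuple(spec_d["hidden_layers"])
    std = payload["standardizer"]
    standardizer = None
    if std is not None:
        standardizer = ScoreStandardizer(
            np.array(std["mean"]), np.array(std["sd"]),
            tuple(std["clade_order"]), int(std["n_train"]),
        )
    return TrainedPhyloclassifier(
        spec=NetworkSpec(**spec_d),
        clade_order=tuple(payload["clade_order"]),
        standardizer=standardizer,
        coefs=[np.array(c) for c in payload["coefs"]],
        intercepts=[np.array(b) for b in payload["intercepts"]],
        fitted_classes=np.array(payload["fitted_classes"], dtype=int),
        training_log=payload["training_log"],
    )
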