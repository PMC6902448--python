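"""Robustness battery: permutation null, site bootstrap, leave-clade-out,
oversampling balance, and confusion metrics.

* **Permutation test** — clade labels are permuted over training genomes
  (score vectors are unchanged by relabeling, so cached leave-one-out
  vectors are reused), the classifier is retrained and LOOCV accuracy
  recomputed per replicate; the p-value is the positively biased
  permutation estimator (b+1)/(B+1) with b = #{null >= observed}.
* **Site bootstrap** — alignment columns are resampled with replacement to
  the original column count (the same column multiset is applied to
  training and query genes), then logo estimation, training-matrix
  construction, model retraining, and classification are re-run.
* **Leave-clade-out** — one clade is removed from training; its genomes
  become queries against the reduced model, probing "none-of-the-above"
  (equivocal) behavior.
* **Oversampling balance** — training score vectors are resampled with
  replacement within each clade up to the best-sampled clade's size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trnacif.classifier import (
    ClassificationReport,
    NetworkSpec,
    assess_equivocality,
    fit_phyloclassifier,
    loocv_accuracy,
    oversample_indices,
    predict_probabilities,
)
from trnacif.scoring import PipelineWorkspace, TrainingMatrix
from trnacif.trna_io import (
    CladeMap,
    CladePartition,
    GenomeComplement,
    SprinzlAlignment,
    partition_by_clade,
)

__all__ = [
    "PermutationNull",
    "BootstrapSummary",
    "ConfusionSummary",
    "LeaveCladeOutResult",
    "confusion_metrics",
    "permutation_test",
    "site_bootstrap",
    "leave_clade_out_variant",
    "oversample_balance",
]


# ---------------------------------------------------------------------------
# confusion metrics

@dataclass
class ConfusionSummary:
    """One-vs-all confusion metrics per clade plus the overall accuracy."""

    matrix: pd.DataFrame  # rows: true clade; columns: predicted clade
    per_clade: pd.DataFrame  # precision, recall, balanced_accuracy
    accuracy: float


def confusion_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionSummary:
    """One-vs-all precision, recall, and balanced accuracy per clade.

    precision = tp/(tp+fp) (0 when the clade is never predicted),
    recall = tp/(tp+fn), balanced accuracy = (TPR+TNR)/2.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("label lists must be non-empty and of equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = list(labels)
    li = {c: i for i, c in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[li[t], li[p]] += 1
    total = M.sum()
    rows = []
    for i, clade in enumerate(labels):
        tp = M[i, i]
        fp = M[:, i].sum() - tp
        fn = M[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        tnr = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        rows.append((clade, precision, tpr, (tpr + tnr) / 2.0))
    per_clade = pd.DataFrame(
        rows, columns=["clade", "precision", "recall", "balanced_accuracy"]
    ).set_index("clade")
    matrix = pd.DataFrame(M, index=labels, columns=labels)
    return ConfusionSummary(matrix, per_clade, float(np.trace(M) / total))


# ---------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationNull:
    """Null distribution of LOOCV accuracy under clade-label permutation."""

    replicates: int
    null_accuracies: np.ndarray
    observed: float
    p_value: float


def permutation_test(
    tm: TrainingMatrix,
    spec: NetworkSpec,
    B: int,
    seed: int = 0,
    observed: float | None = None,
) -> PermutationNull:
    """Permute clade labels over training genomes B times; each replicate
    retrains and re-runs LOOCV on the cached score vectors. The p-value is
    (b+1)/(B+1) with b = #{null accuracies >= observed}."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if observed is None:
        observed, _ = loocv_accuracy(tm, spec)
    rng = np.random.default_rng(seed)
    labels = np.asarray(tm.labels)
    null = np.empty(B)
    for r in range(B):
        permuted = labels[rng.permutation(len(labels))]
        null[r], _ = loocv_accuracy(tm, spec, labels=list(permuted))
    b = int(np.sum(null >= observed))
    return PermutationNull(B, null, float(observed), (b + 1) / (B + 1))


# ---------------------------------------------------------------------------
# site bootstrap

@dataclass
class BootstrapSummary:
    """Per-genome classification consistency over column-resampled replicates."""

    replicates: int
    per_genome: dict[str, int | None]  # replicates whose top clade = reference
    per_genome_frequencies: pd.DataFrame  # genome x clade replicate fractions


def site_bootstrap(
    aln_or_partition: SprinzlAlignment | CladePartition,
    clade_map: CladeMap | None,
    queries: Sequence[GenomeComplement] = (),
    spec: NetworkSpec | None = None,
    R: int = 100,
    seed: int = 0,
    reference: Mapping[str, str] | None = None,
    background: str = "clade_frequencies",
    correction: str = "miller_madow",
) -> BootstrapSummary:
    """R replicates of the full pipeline under alignment-column resampling.

    Each replicate draws columns with replacement to the original column
    count (a coordinate drawn twice contributes its features twice), applies
    the same column multiset to training and query genes, re-estimates
    logos, rebuilds the training matrix, retrains the classifier, and
    classifies every training genome (via its leave-one-out vector) and
    every query. ``reference`` maps genome -> expected clade; training
    genomes default to their true clade.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if spec is None:
        spec = NetworkSpec()
    if isinstance(aln_or_partition, CladePartition):
        partition = aln_or_partition
    else:
        if clade_map is None:
            raise ValueError("clade_map required when passing an alignment")
        partition = partition_by_clade(
            aln_or_partition, clade_map, query_only=[q.genome_id for q in queries]
        )
    ws = PipelineWorkspace(partition, background, correction)
    L = len(ws.coordinates)
    rng = np.random.default_rng(seed)
    ref = dict(zip(ws.genome_ids, ws.labels))
    if reference:
        ref.update(reference)
    all_ids = list(ws.genome_ids) + [q.genome_id for q in queries]
    clades = list(ws.clade_order)
    tallies = pd.DataFrame(0, index=all_ids, columns=clades, dtype=int)
    hits = {gid: 0 for gid in all_ids}
    for _ in range(R):
        idx = rng.integers(0, L, size=L)
        tm = ws.training_matrix(column_idx=idx)
        model = fit_phyloclassifier(tm, spec)
        probs = model.predict_matrix(model.standardizer.transform(tm.S))
        tops = [clades[j] for j in probs.argmax(axis=1)]
        qvecs = ws.score_queries(queries, column_idx=idx, logos=tm.logos)
        if qvecs:
            reports = predict_probabilities(model, qvecs)
            tops += [r.top_clade for r in reports]
        for gid, top in zip(all_ids, tops):
            tallies.loc[gid, top] += 1
            if ref.get(gid) == top:
                hits[gid] += 1
    per_genome = {
        gid: (hits[gid] if gid in ref else None) for gid in all_ids
    }
    return BootstrapSummary(R, per_genome, tallies / R)


# ---------------------------------------------------------------------------
# leave-clade-out

@dataclass
class LeaveCladeOutResult:
    """A model retrained without one clade, and the resulting reports."""

    excluded_clade: str
    model: object
    in_model_reports: list[ClassificationReport]
    excluded_reports: list[ClassificationReport]
    training_matrix: TrainingMatrix = field(repr=False, default=None)


def leave_clade_out_variant(
    partition: CladePartition,
    excluded_clade: str,
    spec: NetworkSpec | None = None,
    threshold: float = 0.80,
    background: str = "clade_frequencies",
    correction: str = "miller_madow",
    balance: bool = False,
) -> LeaveCladeOutResult:
    """Retrain without ``excluded_clade``; its genomes become queries.

    The model's input/output dimension shrinks to the remaining clades, so
    the excluded label can never be predicted. Every report carries the
    equivocality ("none-of-the-above") flag at ``threshold``.
    """
    if spec is None:
        spec = NetworkSpec()
    if excluded_clade not in partition.clade_genes:
        raise ValueError(f"clade {excluded_clade!r} is not in the partition")
    remaining = {
        c: genes for c, genes in partition.clade_genes.items() if c != excluded_clade
    }
    if len(remaining) < 2:
        raise ValueError("leave-clade-out requires >= 2 remaining clades")
    reduced = CladePartition(partition.coordinates, remaining)
    ws = PipelineWorkspace(reduced, background, correction)
    tm = ws.training_matrix()
    model = fit_phyloclassifier(tm, spec, balance=balance)
    in_reports = predict_probabilities(
        model, model.standardizer.transform(tm.S), genome_ids=tm.genome_ids
    )
    # excluded genomes -> query complements against full-data reduced logos
    by_genome: dict[str, list] = {}
    for g in partition.clade_genes[excluded_clade]:
        by_genome.setdefault(g.genome_id, []).append(g)
    queries = [GenomeComplement(gid, genes) for gid, genes in sorted(by_genome.items())]
    qvecs = ws.score_queries(queries, logos=tm.logos)
    out_reports = predict_probabilities(model, qvecs)
    for r in in_reports + out_reports:
        assess_equivocality(r, threshold)
    return LeaveCladeOutResult(excluded_clade, model, in_reports, out_reports, tm)


# ---------------------------------------------------------------------------
# oversampling balance

def oversample_balance(
    S: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Clade-balance training score vectors by within-clade resampling with
    replacement up to the best-sampled clade's size. Original vectors are
    always retained. Returns (balanced matrix, balanced labels, row indices
    into the input)."""
    S = np.asarray(S, dtype=float)
    labels = list(labels)
    if S.shape[0] != len(labels):
        raise ValueError("matrix rows and labels differ in length")
    rng = np.random.default_rng(seed)
    idx = oversample_indices(labels, rng)
    return S[idx], [labels[i] for i in idx], idx
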