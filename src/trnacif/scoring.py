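"""Genome score vectors against clade function logos, and standardization.

The score of genome g against clade X is the average, over the genes t of
its tRNA complement T_g, of the summed Gorodkin heights of the features
carried by each gene for the gene's own functional class:

    S_g^X = (1/|T_g|) * sum_{t in T_g} sum_{f in t} h^{i_t}_{f,X}

in bits per gene. Features (or classes) absent from logo X contribute 0,
and gaps contribute nothing. Training genomes are scored with
self-information leakage prevented: genome g's own clade logo is
re-estimated from T_X^g = T_X - T_g before scoring g.

Score vectors are standardized for classifier input by subtracting the
per-clade mean of the training scores and dividing by the per-clade
standard deviation (zero deviations are replaced by 1, so a degenerate
column standardizes to identically 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trnacif.alphabet import CLASSES, encode_sequence
from trnacif.logos import (
    FunctionLogo,
    _count_tensor,
    logo_from_counts,
)
from trnacif.trna_io import CladePartition, GenomeComplement, MappingError

__all__ = [
    "ScoreVector",
    "ScoreStandardizer",
    "TrainingMatrix",
    "PipelineWorkspace",
    "score_complement",
    "build_training_matrix",
    "fit_standardizer",
    "apply_standardizer",
    "write_score_matrix",
    "read_score_matrix",
]


@dataclass
class ScoreVector:
    """Per-genome vector of clade scores (bits/gene) in a fixed clade order."""

    genome_id: str
    scores: np.ndarray
    clade_order: tuple[str, ...]
    standardized: np.ndarray | None = None

    def as_dict(self, standardized: bool = False) -> dict[str, float]:
        vals = self.standardized if standardized else self.scores
        if vals is None:
            raise ValueError("vector has not been standardized")
        return dict(zip(self.clade_order, map(float, vals)))


@dataclass
class ScoreStandardizer:
    """Per-clade-element location/scale fitted on training score vectors."""

    mean: np.ndarray
    sd: np.ndarray
    clade_order: tuple[str, ...]
    n_train: int

    def transform(self, S: np.ndarray) -> np.ndarray:
        return (np.asarray(S, dtype=float) - self.mean) / self.sd


@dataclass
class TrainingMatrix:
    """Leave-one-out training score vectors plus full-data logos.

    Row i holds genome ``genome_ids[i]`` (true clade ``labels[i]``) scored
    against the clade logos with its own genes removed from its own clade's
    logo estimation. ``logos`` are the full-data logos used for queries.
    """

    S: np.ndarray  # (n_genomes, K)
    genome_ids: list[str]
    labels: list[str]
    clade_order: tuple[str, ...]
    coordinates: tuple[str, ...]
    logos: dict[str, FunctionLogo]
    workspace: "PipelineWorkspace | None" = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.S, columns=list(self.clade_order))
        df.insert(0, "genome_id", self.genome_ids)
        df.insert(1, "clade", self.labels)
        return df


# ---------------------------------------------------------------------------
# generic query scoring

def _score_with_heights(
    H: np.ndarray, codes: np.ndarray, class_idx: np.ndarray
) -> float:
    """Mean over genes of summed heights H[class, coordinate, base_code]."""
    L = codes.shape[1]
    vals = H[class_idx[:, None], np.arange(L)[None, :], codes]
    return float(vals.sum(axis=1).mean())


def _encode_complement(
    complement: GenomeComplement,
) -> tuple[np.ndarray, np.ndarray]:
    codes = np.vstack([encode_sequence(g.aligned_seq) for g in complement.genes])
    idx = np.empty(len(complement.genes), dtype=np.int64)
    for i, g in enumerate(complement.genes):
        if g.functional_type is None:
            raise ValueError(f"gene {g.gene_id} has no functional type")
        idx[i] = CLASSES.index(g.functional_type)
    return codes, idx


def score_complement(
    complement: GenomeComplement,
    logos: Mapping[str, FunctionLogo],
    coordinates: Sequence[str] | None = None,
) -> ScoreVector:
    """Score one genome complement against a set of clade logos.

    ``coordinates`` names the query's coordinate frame (defaults to the
    logos' frame). Query coordinates unknown to a logo, classes outside a
    logo's support, and gap symbols all contribute 0.
    """
    if len(complement.genes) == 0:
        raise ValueError("empty genome complement")
    clade_order = tuple(sorted(logos))
    if not clade_order:
        raise ValueError("no logos supplied")
    codes, class_idx = _encode_complement(complement)
    scores = np.empty(len(clade_order))
    for j, clade in enumerate(clade_order):
        logo = logos[clade]
        H = logo.heights_global()
        if coordinates is not None and tuple(coordinates) != logo.coordinates:
            # map query columns onto the logo frame by coordinate label;
            # unmatched columns hit an appended zero column
            L_logo = len(logo.coordinates)
            Hx = np.concatenate([H, np.zeros((H.shape[0], 1, 5))], axis=1)
            col = np.array(
                [logo._coord_index.get(str(c), L_logo) for c in coordinates]
            )
            vals = Hx[class_idx[:, None], col[None, :], codes]
            scores[j] = float(vals.sum(axis=1).mean())
        else:
            if codes.shape[1] != len(logo.coordinates):
                raise ValueError(
                    f"complement width {codes.shape[1]} does not match logo "
                    f"{clade} frame of {len(logo.coordinates)} coordinates"
                )
            scores[j] = _score_with_heights(H, codes, class_idx)
    return ScoreVector(complement.genome_id, scores, clade_order)


# ---------------------------------------------------------------------------
# leakage-safe training matrix

class PipelineWorkspace:
    """Encoded training data with cached per-genome count tensors.

    Built once per partition; supports repeated training-matrix builds under
    alignment-column resampling (site bootstrap) without re-encoding.
    """

    def __init__(
        self,
        partition: CladePartition,
        background: str = "clade_frequencies",
        correction: str = "miller_madow",
    ):
        self.partition = partition
        self.background = background
        self.correction = correction
        self.coordinates = tuple(partition.coordinates)
        self.clade_order = tuple(sorted(partition.clade_genes))
        self.genome_ids: list[str] = []
        self.labels: list[str] = []
        self._codes: dict[str, np.ndarray] = {}
        self._class_idx: dict[str, np.ndarray] = {}
        self._counts: dict[str, np.ndarray] = {}
        self._class_counts: dict[str, np.ndarray] = {}
        self._clade_genomes: dict[str, list[str]] = {}
        for clade in self.clade_order:
            genes_by_genome: dict[str, list] = {}
            for g in partition.clade_genes[clade]:
                genes_by_genome.setdefault(g.genome_id, []).append(g)
            gids = sorted(genes_by_genome)
            self._clade_genomes[clade] = gids
            for gid in gids:
                comp = GenomeComplement(gid, genes_by_genome[gid])
                codes, cidx = _encode_complement(comp)
                self._codes[gid] = codes
                self._class_idx[gid] = cidx
                self._counts[gid] = _count_tensor(codes, cidx, len(CLASSES))
                self._class_counts[gid] = np.bincount(cidx, minlength=len(CLASSES))
                self.genome_ids.append(gid)
                self.labels.append(clade)

    # -- logo building -----------------------------------------------------
    def _clade_totals(
        self, column_idx: np.ndarray | None
    ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        C, N = {}, {}
        for clade, gids in self._clade_genomes.items():
            Cx = np.sum([self._counts[g] for g in gids], axis=0)
            if column_idx is not None:
                Cx = Cx[:, column_idx, :]
            C[clade] = Cx
            N[clade] = np.sum([self._class_counts[g] for g in gids], axis=0)
        return C, N

    def _frame(self, column_idx: np.ndarray | None) -> tuple[str, ...]:
        if column_idx is None:
            return self.coordinates
        # resampled columns keep their coordinate identity; labels are
        # disambiguated with a draw index to stay unique
        return tuple(
            f"{self.coordinates[i]}.{k}" for k, i in enumerate(column_idx)
        )

    def full_logos(
        self, column_idx: np.ndarray | None = None
    ) -> dict[str, FunctionLogo]:
        C, N = self._clade_totals(column_idx)
        pooled = np.sum(list(N.values()), axis=0)
        frame = self._frame(column_idx)
        return {
            clade: logo_from_counts(
                clade, frame, C[clade], N[clade],
                self.background, self.correction, pooled,
            )
            for clade in self.clade_order
        }

    def training_matrix(
        self, column_idx: np.ndarray | None = None
    ) -> TrainingMatrix:
        """Leave-one-out score vectors for every training genome."""
        C, N = self._clade_totals(column_idx)
        pooled = np.sum(list(N.values()), axis=0)
        frame = self._frame(column_idx)
        logos = {
            clade: logo_from_counts(
                clade, frame, C[clade], N[clade],
                self.background, self.correction, pooled,
            )
            for clade in self.clade_order
        }
        H_full = {clade: logos[clade].heights_global() for clade in self.clade_order}
        S = np.empty((len(self.genome_ids), len(self.clade_order)))
        for i, (gid, clade) in enumerate(zip(self.genome_ids, self.labels)):
            codes = self._codes[gid]
            if column_idx is not None:
                codes = codes[:, column_idx]
            cg = self._counts[gid]
            if column_idx is not None:
                cg = cg[:, column_idx, :]
            C_loo = C[clade] - cg
            N_loo = N[clade] - self._class_counts[gid]
            if N_loo.sum() == 0:
                raise MappingError(
                    f"clade {clade} contains only genome {gid}; "
                    "leave-one-out logo estimation is degenerate"
                )
            logo_loo = logo_from_counts(
                clade, frame, C_loo, N_loo,
                self.background, self.correction, pooled,
            )
            H_loo = logo_loo.heights_global()
            cidx = self._class_idx[gid]
            for j, other in enumerate(self.clade_order):
                H = H_loo if other == clade else H_full[other]
                S[i, j] = _score_with_heights(H, codes, cidx)
        return TrainingMatrix(
            S=S,
            genome_ids=list(self.genome_ids),
            labels=list(self.labels),
            clade_order=self.clade_order,
            coordinates=frame,
            logos=logos,
            workspace=self,
        )

    def score_queries(
        self,
        queries: Sequence[GenomeComplement],
        column_idx: np.ndarray | None = None,
        logos: Mapping[str, FunctionLogo] | None = None,
    ) -> list[ScoreVector]:
        """Score query complements against full-data logos (optionally under
        the same column resample as a bootstrap training matrix)."""
        if logos is None:
            logos = self.full_logos(column_idx)
        H = {clade: logos[clade].heights_global() for clade in self.clade_order}
        out = []
        for comp in queries:
            codes, cidx = _encode_complement(comp)
            if codes.shape[1] != len(self.coordinates):
                raise ValueError(
                    f"query {comp.genome_id} width {codes.shape[1]} does not "
                    f"match training frame of {len(self.coordinates)} coordinates"
                )
            if column_idx is not None:
                codes = codes[:, column_idx]
            scores = np.array(
                [_score_with_heights(H[c], codes, cidx) for c in self.clade_order]
            )
            out.append(ScoreVector(comp.genome_id, scores, self.clade_order))
        return out


def build_training_matrix(
    partition: CladePartition,
    background: str = "clade_frequencies",
    correction: str = "miller_madow",
) -> TrainingMatrix:
    """Score every training genome against leave-one-out clade logos.

    For each training genome g, its own clade's logo is re-estimated from
    T_X^g (g's genes removed) before scoring g; other clades' logos are the
    full-data logos. Rows are ordered by clade, then genome id.
    """
    return PipelineWorkspace(partition, background, correction).training_matrix()


# ---------------------------------------------------------------------------
# standardization

def fit_standardizer(
    S: np.ndarray | TrainingMatrix, clade_order: tuple[str, ...] | None = None
) -> ScoreStandardizer:
    """Fit per-clade mean and standard deviation on >= 2 training vectors.

    Zero standard deviations are replaced by 1 (with a warning), so constant
    columns standardize to identically 0 instead of erroring.
    """
    if isinstance(S, TrainingMatrix):
        clade_order = S.clade_order
        S = S.S
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("standardizer requires a matrix of >= 2 training vectors")
    if clade_order is None:
        raise ValueError("clade_order is required")
    mean = S.mean(axis=0)
    sd = S.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            "zero-variance score column(s) standardized with sd=1", stacklevel=2
        )
        sd = np.where(sd == 0, 1.0, sd)
    return ScoreStandardizer(mean, sd, tuple(clade_order), S.shape[0])


def apply_standardizer(
    v: ScoreVector, standardizer: ScoreStandardizer
) -> ScoreVector:
    """Return a copy of ``v`` with the standardized score field populated."""
    if v.clade_order != standardizer.clade_order:
        raise ValueError(
            f"clade order mismatch: vector {v.clade_order} vs "
            f"standardizer {standardizer.clade_order}"
        )
    return ScoreVector(
        v.genome_id, v.scores, v.clade_order, standardizer.transform(v.scores)
    )


# ---------------------------------------------------------------------------
# score-matrix I/O

def write_score_matrix(
    tm_or_frame: TrainingMatrix | pd.DataFrame,
    path: str | Path,
    standardized: bool = False,
) -> None:
    df = tm_or_frame.to_frame() if isinstance(tm_or_frame, TrainingMatrix) else tm_or_frame
    df = df.copy()
    df["standardized"] = bool(standardized)
    df.to_csv(path, sep="\t", index=False)


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
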