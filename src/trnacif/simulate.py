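"""Clade-structured synthetic tRNA gene complements with planted CIFs.

The generator emulates the structure of real clade-partitioned tRNA data:
K clades of genomes, each genome carrying a near-complete functional
repertoire of 30-55 aligned genes over ~72 Sprinzl coordinates and 22
functional classes. Sequence content has three layers:

* **shared identity determinants** — class-specific (coordinate, base)
  determinants common to all clades, emulating universal tRNA identity
  elements;
* **clade-planted determinants** — clade-specific (class, coordinate,
  base) determinants, the ground-truth CIFs; planted (class, coordinate)
  pairs are disjoint across clades and from the shared determinants;
* **background noise** — everywhere else, a gap with probability
  ``gap_rate``, otherwise a uniformly random base.

Each determinant is respected with probability ``signal`` (otherwise the
position falls back to background noise), so ``signal`` = 1 plants
perfectly recoverable CIFs and ``signal`` = 0 makes clades statistically
exchangeable. A truth record lists every determinant for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from trnacif.alphabet import BASES, CLASSES, GAP
from trnacif.trna_io import (
    CladeMap,
    GenomeComplement,
    SprinzlAlignment,
    TRNAGeneRecord,
)

__all__ = ["SyntheticDesign", "generate_dataset", "generate_novel_clade_queries"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for the synthetic benchmark generator."""

    n_clades: int = 8
    genomes_per_clade: int | tuple[int, ...] = 25
    genes_per_genome: tuple[int, int] = (30, 55)
    n_coordinates: int = 72
    classes: tuple[str, ...] = CLASSES
    n_planted_features: int = 20
    signal: float = 0.9
    background_identity: int = 3
    gap_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal <= 1 or not 0 <= self.gap_rate <= 1:
            raise ValueError("signal and gap_rate must be in [0, 1]")
        if self.n_clades < 1 or self.n_coordinates < 1:
            raise ValueError("n_clades and n_coordinates must be >= 1")
        lo, hi = self.genes_per_genome
        if lo < 1 or hi < lo:
            raise ValueError("genes_per_genome must be a non-empty range")
        for c in self.classes:
            if c not in CLASSES:
                raise ValueError(f"unknown functional class {c!r}")

    def clade_sizes(self) -> tuple[int, ...]:
        if isinstance(self.genomes_per_clade, int):
            return (self.genomes_per_clade,) * self.n_clades
        sizes = tuple(self.genomes_per_clade)
        if len(sizes) != self.n_clades:
            raise ValueError("genomes_per_clade list must have n_clades entries")
        return sizes

    def clade_labels(self) -> tuple[str, ...]:
        return tuple(f"C{k + 1:02d}" for k in range(self.n_clades))


def _sample_determinants(
    rng: np.random.Generator, design: SyntheticDesign, n_clade_sets: int
) -> tuple[dict[int, list[tuple[int, int]]], list[list[tuple[int, int, int]]]]:
    """Shared determinants per class and planted determinant sets.

    Returns (shared: class_idx -> [(coord, base)], planted: one list per
    clade set of (class_idx, coord, base)). Sampling is sequential per
    clade, so the first K clade sets are identical whether or not an extra
    (novel) clade set is drawn afterwards with the same stream.
    """
    n_cls = len(design.classes)
    L = design.n_coordinates
    shared: dict[int, list[tuple[int, int]]] = {}
    used: set[tuple[int, int]] = set()
    for ci in range(n_cls):
        if design.background_identity > L:
            raise ValueError("infeasible design: more shared determinants than columns")
        coords = rng.choice(L, size=design.background_identity, replace=False)
        shared[ci] = [(int(c), int(rng.integers(4))) for c in coords]
        used.update((ci, c) for c, _ in shared[ci])
    pool = [
        (ci, c) for ci in range(n_cls) for c in range(L) if (ci, c) not in used
    ]
    planted: list[list[tuple[int, int, int]]] = []
    for _ in range(n_clade_sets):
        if design.n_planted_features > len(pool):
            raise ValueError(
                "infeasible design: not enough free (class, coordinate) pairs "
                "for the requested planted features"
            )
        pick = rng.choice(len(pool), size=design.n_planted_features, replace=False)
        chosen = [pool[i] for i in sorted(pick)]
        planted.append(
            [(ci, c, int(rng.integers(4))) for ci, c in chosen]
        )
        taken = set(chosen)
        pool = [p for p in pool if p not in taken]
    return shared, planted


def _gene_class_list(
    rng: np.random.Generator, design: SyntheticDesign, n_genes: int
) -> list[int]:
    n_cls = len(design.classes)
    if n_genes >= n_cls:
        extra = rng.integers(0, n_cls, size=n_genes - n_cls)
        return list(range(n_cls)) + [int(e) for e in extra]
    return [int(i) for i in rng.permutation(n_cls)[:n_genes]]


def _make_genome(
    rng: np.random.Generator,
    design: SyntheticDesign,
    genome_id: str,
    determinants: dict[int, list[tuple[int, int]]],
) -> list[TRNAGeneRecord]:
    lo, hi = design.genes_per_genome
    n_genes = int(rng.integers(lo, hi + 1))
    class_list = _gene_class_list(rng, design, n_genes)
    L = design.n_coordinates
    # background layer: gaps then uniform bases
    codes = rng.integers(0, 4, size=(n_genes, L)).astype(np.uint8)
    gaps = rng.random((n_genes, L)) < design.gap_rate
    codes[gaps] = 4
    for gi, ci in enumerate(class_list):
        for coord, base in determinants.get(ci, ()):
            if rng.random() < design.signal:
                codes[gi, coord] = base
    table = BASES + GAP
    genes = []
    per_class_counter: dict[int, int] = {}
    for gi, ci in enumerate(class_list):
        m = per_class_counter.get(ci, 0) + 1
        per_class_counter[ci] = m
        cls = design.classes[ci]
        genes.append(
            TRNAGeneRecord(
                gene_id=f"{genome_id}|{cls}{m}",
                genome_id=genome_id,
                aligned_seq="".join(table[b] for b in codes[gi]),
                functional_type=cls,
            )
        )
    return genes


def _clade_determinant_map(
    design: SyntheticDesign,
    shared: dict[int, list[tuple[int, int]]],
    planted: list[tuple[int, int, int]],
) -> dict[int, list[tuple[int, int]]]:
    dets = {ci: list(pairs) for ci, pairs in shared.items()}
    for ci, coord, base in planted:
        dets.setdefault(ci, []).append((coord, base))
    return dets


def _truth_entry(design: SyntheticDesign, ci: int, coord: int, base: int) -> dict:
    return {
        "class": design.classes[ci],
        "coordinate": str(coord + 1),
        "base": BASES[base],
    }


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[SprinzlAlignment, CladeMap, dict]:
    """Generate a clade-structured alignment, its clade map, and the truth
    record of planted determinants. Deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    shared, planted = _sample_determinants(rng, design, design.n_clades)
    labels = design.clade_labels()
    sizes = design.clade_sizes()
    genes: list[TRNAGeneRecord] = []
    assignments: dict[str, str] = {}
    for k, (clade, size) in enumerate(zip(labels, sizes)):
        dets = _clade_determinant_map(design, shared, planted[k])
        for j in range(size):
            gid = f"{clade}.g{j + 1:03d}"
            assignments[gid] = clade
            genes.extend(_make_genome(rng, design, gid, dets))
    coords = tuple(str(i + 1) for i in range(design.n_coordinates))
    aln = SprinzlAlignment(coords, genes)
    clade_map = CladeMap(assignments, min_gene_count=1)
    truth = {
        "shared": [_truth_entry(design, ci, c, b) for ci in sorted(shared)
                   for c, b in shared[ci]],
        "planted": {
            clade: [_truth_entry(design, ci, c, b) for ci, c, b in planted[k]]
            for k, clade in enumerate(labels)
        },
    }
    return aln, clade_map, truth


def generate_novel_clade_queries(
    design: SyntheticDesign, n_genomes: int
) -> tuple[list[GenomeComplement], dict]:
    """Genomes from a (K+1)-th clade with its own planted determinants,
    never present in the training design.

    The training clades' determinants are re-derived from the same seed, so
    the novel clade's determinants are guaranteed disjoint from them.
    """
    rng = np.random.default_rng(design.seed)
    shared, planted = _sample_determinants(rng, design, design.n_clades + 1)
    novel = planted[-1]
    dets = _clade_determinant_map(design, shared, novel)
    qrng = np.random.default_rng([design.seed, 0x4E56])  # independent stream
    complements = []
    for j in range(n_genomes):
        gid = f"NOVEL.g{j + 1:03d}"
        complements.append(
            GenomeComplement(gid, _make_genome(qrng, design, gid, dets))
        )
    truth = {"planted": {"NOVEL": [_truth_entry(design, ci, c, b) for ci, c, b in novel]}}
    return complements, truth
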