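"""Seeded validation studies for the whole pipeline.

Every study here is a frozen, deterministic experiment on synthetic
benchmarks with planted CIFs; together they exercise logo estimation,
Eq.-1 scoring, classifier training, and the robustness battery end to end.
Study sizes are chosen to run on a single CPU in minutes; the methods note
documents the design of each study and what it does and does not show.

All studies derive their randomness from a single integer ``seed``.
"""

from __future__ import annotations

import math

import numpy as np

from trnacif.alphabet import BASES, CLASSES
from trnacif.classifier import NetworkSpec, loocv_accuracy
from trnacif.logos import estimate_clade_logos
from trnacif.robustness import (
    confusion_metrics,
    leave_clade_out_variant,
    permutation_test,
    site_bootstrap,
)
from trnacif.scoring import build_training_matrix, score_complement
from trnacif.simulate import SyntheticDesign, generate_dataset
from trnacif.trna_io import GenomeComplement, partition_by_clade

__all__ = [
    "benchmark_design",
    "loocv_benchmark",
    "leave_clade_out_benchmark",
    "permutation_calibration",
    "bootstrap_consistency",
    "balance_study",
    "oracle_equivalence",
    "height_normalization_check",
]


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1009 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# worked examples on published summary counts

#: Published per-clade summary counts for the cyanobacterial training
#: release (genomes G, tRNA genes T, non-gap bases N) used as worked
#: examples for the summary arithmetic.
REFERENCE_CLADE_COUNTS = {
    "A": {"genomes": 11, "genes": 555, "bases": 40362},
    "B1": {"genomes": 27, "genes": 1395, "bases": 101640},
}

#: Published plastid classification outcome: 433 genomes to the late-
#: branching fused clade plus 4 to clade A, out of 440 plastid genomes.
REFERENCE_PLASTID_CLASSIFICATION = {"late_branching": 433 + 4, "total": 440}


def worked_examples() -> dict:
    """Summary-arithmetic worked examples recomputed from reference counts."""
    from trnacif.trna_io import summary_from_counts

    out = {}
    for clade, c in REFERENCE_CLADE_COUNTS.items():
        ratios = summary_from_counts(c["genomes"], c["genes"], c["bases"])
        out[f"genes_per_genome_clade_{clade.lower()}"] = ratios["genes_per_genome"]
        out[f"bases_per_gene_clade_{clade.lower()}"] = ratios["bases_per_gene"]
    ref = REFERENCE_PLASTID_CLASSIFICATION
    out["late_branching_plastid_percent"] = round(
        100.0 * ref["late_branching"] / ref["total"], 2
    )
    return out


# ---------------------------------------------------------------------------
# the 8-clade high-signal benchmark

def benchmark_design(seed: int) -> SyntheticDesign:
    """The standard 8-clade recovery benchmark: 25 genomes per clade,
    40 genes per genome, 20 planted CIFs per clade at signal 0.9."""
    return SyntheticDesign(
        n_clades=8, genomes_per_clade=25, genes_per_genome=(40, 40),
        n_coordinates=72, n_planted_features=20, signal=0.9,
        background_identity=3, gap_rate=0.05, seed=_sub_seed(seed, 1),
    )


def _benchmark_matrix(seed: int):
    aln, cmap, _ = generate_dataset(benchmark_design(seed))
    part = partition_by_clade(aln, cmap)
    return part, build_training_matrix(part)


def loocv_benchmark(seed: int) -> dict:
    """LOOCV accuracy on the benchmark, plus the chance-level control with
    randomly permuted clade labels."""
    part, tm = _benchmark_matrix(seed)
    spec = NetworkSpec(hidden_layers=(13,), seed=_sub_seed(seed, 2))
    accuracy, _ = loocv_accuracy(tm, spec)
    rng = np.random.default_rng(_sub_seed(seed, 3))
    permuted = [tm.labels[i] for i in rng.permutation(len(tm.labels))]
    chance_accuracy, _ = loocv_accuracy(tm, spec, labels=permuted)
    return {
        "accuracy": accuracy,
        "permuted_accuracy": chance_accuracy,
        "n_genomes": tm.S.shape[0],
        "n_clades": tm.S.shape[1],
        "part": part,
        "tm": tm,
    }


def leave_clade_out_benchmark(seed: int, part=None) -> dict:
    """Exclude one benchmark clade from training and classify its genomes
    as queries: their mean top probability should drop well below that of
    in-model genomes ("none-of-the-above" behavior)."""
    if part is None:
        part, _ = _benchmark_matrix(seed)
    spec = NetworkSpec(hidden_layers=(13,), seed=_sub_seed(seed, 4))
    excluded_clade = sorted(part.clade_genes)[0]
    res = leave_clade_out_variant(part, excluded_clade, spec)
    mean_in = float(np.mean([r.top_probability for r in res.in_model_reports]))
    mean_out = float(np.mean([r.top_probability for r in res.excluded_reports]))
    return {
        "excluded_clade": excluded_clade,
        "mean_top_probability_in_model": mean_in,
        "mean_top_probability_excluded": mean_out,
        "gap": mean_in - mean_out,
        "excluded_equivocal_fraction": float(
            np.mean([r.equivocal for r in res.excluded_reports])
        ),
    }


# ---------------------------------------------------------------------------
# permutation-test calibration

def _calibration_design(seed: int, signal: float, strong: bool) -> SyntheticDesign:
    if strong:
        # three clades keep the space of label arrangements large enough
        # that no null permutation can recreate a learnable labeling
        return SyntheticDesign(
            n_clades=3, genomes_per_clade=4, genes_per_genome=(20, 20),
            n_coordinates=16, classes=CLASSES[:8], n_planted_features=6,
            background_identity=2, signal=signal, seed=seed,
        )
    # the null design keeps single-genome removal a small fraction of each
    # clade and the per-genome feature count low, so the leave-one-out
    # sample-size asymmetry (see methods) is negligible
    return SyntheticDesign(
        n_clades=2, genomes_per_clade=10, genes_per_genome=(4, 4),
        n_coordinates=6, classes=CLASSES[:8], n_planted_features=2,
        background_identity=1, signal=signal, seed=seed,
    )


def permutation_calibration(seed: int, runs: int = 20, B: int = 200) -> dict:
    """Calibration of the permutation test.

    ``runs`` seeded datasets with no clade signal each get a B-replicate
    permutation test; under the null the p-value should rarely fall below
    0.05. One high-signal dataset checks that a real effect attains the
    minimal attainable p-value 1/(B+1).
    """
    spec_cap = 25  # chance-level fits need no deep optimization
    p_values = []
    for r in range(runs):
        s = _sub_seed(seed, 100 + r)
        aln, cmap, _ = generate_dataset(_calibration_design(s, 0.0, strong=False))
        tm = build_training_matrix(partition_by_clade(aln, cmap))
        spec = NetworkSpec(hidden_layers=(8,), max_epochs=spec_cap, seed=s)
        p_values.append(permutation_test(tm, spec, B=B, seed=s).p_value)
    s = _sub_seed(seed, 99)
    aln, cmap, _ = generate_dataset(_calibration_design(s, 0.9, strong=True))
    tm = build_training_matrix(partition_by_clade(aln, cmap))
    spec = NetworkSpec(hidden_layers=(8,), max_epochs=50, seed=s)
    strong = permutation_test(tm, spec, B=B, seed=s)
    return {
        "null_p_values": p_values,
        "fraction_p_above_0.05": float(np.mean([p > 0.05 for p in p_values])),
        "high_signal_p": strong.p_value,
        "high_signal_observed": strong.observed,
        "minimal_p": 1.0 / (B + 1),
        "runs": runs,
        "B": B,
    }


# ---------------------------------------------------------------------------
# site-bootstrap consistency

def bootstrap_consistency(seed: int, R: int = 100) -> dict:
    """R column-resampling replicates on a high-signal dataset: every
    genome should recover its true clade in nearly every replicate."""
    design = SyntheticDesign(
        n_clades=4, genomes_per_clade=6, genes_per_genome=(30, 30),
        n_coordinates=40, n_planted_features=10, signal=0.9,
        background_identity=3, seed=_sub_seed(seed, 5),
    )
    aln, cmap, _ = generate_dataset(design)
    part = partition_by_clade(aln, cmap)
    spec = NetworkSpec(hidden_layers=(13,), seed=_sub_seed(seed, 6))
    summary = site_bootstrap(part, None, spec=spec, R=R, seed=_sub_seed(seed, 7))
    counts = [c for c in summary.per_genome.values() if c is not None]
    return {
        "replicates": R,
        "min_correct": int(min(counts)),
        "median_correct": float(np.median(counts)),
        "n_genomes": len(counts),
    }


# ---------------------------------------------------------------------------
# oversampling-balance study

def balance_design(seed: int) -> SyntheticDesign:
    """Imbalanced 4-clade design (30/27/11/5 genomes) in a moderately
    confusable regime: sparse clade-specific determinants at signal 0.7
    over a shared-identity background, so clade clusters overlap and the
    classifier's majority-clade prior costs under-sampled clades recall."""
    return SyntheticDesign(
        n_clades=4, genomes_per_clade=(30, 27, 11, 5),
        genes_per_genome=(12, 12), n_coordinates=20, classes=CLASSES[:10],
        n_planted_features=3, background_identity=2, signal=0.7, seed=seed,
    )


def balance_study(seed: int, runs: int = 10) -> dict:
    """Unbalanced vs clade-balanced (oversampled) LOOCV on ``runs`` seeded
    imbalanced datasets; reports how often balancing improves the mean
    recall of the two under-sampled clades."""
    wins = 0
    details = []
    for r in range(runs):
        s = _sub_seed(seed, 200 + r)
        aln, cmap, _ = generate_dataset(balance_design(s))
        tm = build_training_matrix(partition_by_clade(aln, cmap))
        spec = NetworkSpec(hidden_layers=(13,), max_epochs=500, seed=s)
        rec = {}
        for bal in (False, True):
            _, tab = loocv_accuracy(tm, spec, balance=bal)
            cs = confusion_metrics(
                tab.true_clade, tab.predicted_clade, labels=list(tm.clade_order)
            )
            minority = sorted(tm.clade_order)[-2:]  # the 11- and 5-genome clades
            rec[bal] = float(cs.per_clade.recall.loc[minority].mean())
        details.append((rec[False], rec[True]))
        wins += rec[True] > rec[False]
    return {"runs": runs, "wins": wins, "minority_recalls": details}


# ---------------------------------------------------------------------------
# formula-level oracles

def _brute_heights(genes, coordinates):
    """Scalar re-derivation of logo heights with clade-frequency background
    and no correction (plain math, no shared code with the estimator)."""
    classes = sorted({g.functional_type for g in genes}, key=CLASSES.index)
    q = {c: sum(g.functional_type == c for g in genes) / len(genes) for c in classes}
    out = {}
    for ci, coord in enumerate(coordinates):
        for b in BASES:
            carriers = [g for g in genes if g.aligned_seq[ci] == b]
            if not carriers:
                continue
            n = len(carriers)
            p = {c: sum(g.functional_type == c for g in carriers) / n for c in classes}
            D = sum(pi * math.log2(pi / q[c]) for c, pi in p.items() if pi > 0)
            D = max(D, 0.0)
            denom = sum(pi / q[c] for c, pi in p.items())
            out[(b, coord)] = {
                c: (D * (pi / q[c]) / denom if denom else 0.0)
                for c, pi in p.items()
            }
    return out


def oracle_equivalence(seed: int, n_instances: int = 20) -> dict:
    """Max absolute deviation between the vectorized pipeline and direct
    scalar evaluation of the height and genome-score formulas on random
    micro-instances (<= 5 genes per clade x <= 4 coordinates)."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    max_h = 0.0
    max_s = 0.0
    for _ in range(n_instances):
        n_cols = int(rng.integers(2, 5))
        coords = tuple(str(i + 1) for i in range(n_cols))
        clade_genes = {}
        for k in range(int(rng.integers(2, 4))):
            genes = []
            for g in range(int(rng.integers(2, 4))):
                for t in range(int(rng.integers(1, 3))):
                    seq = "".join(rng.choice(list("ACGU-"), size=n_cols))
                    from trnacif.trna_io import TRNAGeneRecord

                    genes.append(
                        TRNAGeneRecord(
                            f"c{k}g{g}|t{t}", f"c{k}g{g}", seq,
                            str(rng.choice(["L", "F", "X"])),
                        )
                    )
            clade_genes[f"K{k}"] = genes
        logos = estimate_clade_logos(
            clade_genes, background="clade_frequencies", correction="none",
            coordinates=coords,
        )
        for clade, genes in clade_genes.items():
            expect = _brute_heights(genes, coords)
            logo = logos[clade]
            for (b, coord), per_class in expect.items():
                for c, h in per_class.items():
                    max_h = max(max_h, abs(logo.height(b, coord, c) - h))
            by_genome: dict[str, list] = {}
            for g in genes:
                by_genome.setdefault(g.genome_id, []).append(g)
            for gid, gg in by_genome.items():
                comp = GenomeComplement(gid, gg)
                vec = score_complement(comp, logos)
                for clade2, val in zip(vec.clade_order, vec.scores):
                    brute = 0.0
                    heights2 = _brute_heights(clade_genes[clade2], coords)
                    for gene in gg:
                        for ci, coord in enumerate(coords):
                            base = gene.aligned_seq[ci]
                            if base == "-":
                                continue
                            brute += heights2.get((base, coord), {}).get(
                                gene.functional_type, 0.0
                            )
                    brute /= len(gg)
                    max_s = max(max_s, abs(val - brute))
    return {
        "n_instances": n_instances,
        "max_height_abs_diff": max_h,
        "max_score_abs_diff": max_s,
    }


def height_normalization_check(seed: int, n_datasets: int = 100) -> dict:
    """Max deviation of sum_i h^i_f from D_f across ``n_datasets`` random
    synthetic datasets and all correction modes."""
    max_dev = 0.0
    n_features = 0
    for r in range(n_datasets):
        s = _sub_seed(seed, 300 + r)
        rng = np.random.default_rng(s)
        design = SyntheticDesign(
            n_clades=int(rng.integers(2, 4)),
            genomes_per_clade=int(rng.integers(2, 4)),
            genes_per_genome=(6, 12),
            n_coordinates=int(rng.integers(8, 16)),
            n_planted_features=3,
            background_identity=1,
            signal=float(rng.uniform(0, 1)),
            gap_rate=float(rng.uniform(0, 0.2)),
            seed=s,
        )
        aln, cmap, _ = generate_dataset(design)
        part = partition_by_clade(aln, cmap)
        correction = ("none", "miller_madow", "exact_small_n")[r % 3]
        for logo in estimate_clade_logos(part, correction=correction).values():
            dev = np.abs(logo.heights.sum(axis=0) - logo.info).max()
            max_dev = max(max_dev, float(dev))
            n_features += int((logo.support > 0).sum())
    return {"n_datasets": n_datasets, "n_features": n_features, "max_deviation": max_dev}
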