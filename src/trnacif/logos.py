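"""Per-clade tRNA function logos: Gorodkin heights over sequence features.

A *feature* f is a (base, Sprinzl coordinate) pair; the feature set is
F = {A, C, G, U} x SC. For a clade's pooled gene set, each feature carried
by at least one gene gets

* a class-conditional distribution p(i | f) over the functional classes of
  the genes carrying it, with sample size n_f;
* a corrected feature information D_f = KL(p || q) - correction(n_f), in
  bits, clamped at zero, where q is a background class distribution;
* Gorodkin heights h^i_f = D_f * (p_i/q_i) / sum_j (p_j/q_j), apportioning
  D_f across classes by background-normalized odds, so that
  sum_i h^i_f = D_f.

High heights mark class-informative features (CIFs): bases at structural
coordinates whose presence in a gene is informative about its functional
class within that clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from trnacif.alphabet import BASES, CLASSES
from trnacif.trna_io import CladePartition, TRNAGeneRecord

__all__ = [
    "ClassBackground",
    "FunctionLogo",
    "class_conditional_profile",
    "feature_information",
    "gorodkin_heights",
    "estimate_clade_logos",
    "export_logo_table",
    "read_logo_table",
]

_LN2 = math.log(2.0)
_EXACT_N_MAX = 8

CORRECTIONS = ("none", "miller_madow", "exact_small_n")
BACKGROUNDS = ("uniform", "clade_frequencies", "pooled_frequencies")


@dataclass(frozen=True)
class ClassBackground:
    """Background class distribution q over a clade's supported classes."""

    classes: tuple[str, ...]
    q: np.ndarray
    source: str = "clade_frequencies"

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if len(q) != len(self.classes):
            raise ValueError("background length does not match class list")
        if (q < 0).any() or not math.isclose(q.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a probability distribution")
        if (q == 0).any():
            raise ValueError("background must give positive mass to every supported class")

    def prob(self, cls: str) -> float:
        return float(self.q[self.classes.index(cls)])

    @classmethod
    def uniform(cls, classes: Sequence[str]) -> "ClassBackground":
        k = len(classes)
        return cls(tuple(classes), np.full(k, 1.0 / k), "uniform")

    @classmethod
    def from_class_counts(
        cls, classes: Sequence[str], counts: Sequence[float], source: str
    ) -> "ClassBackground":
        counts = np.asarray(counts, dtype=float)
        return cls(tuple(classes), counts / counts.sum(), source)


@dataclass
class FunctionLogo:
    """A clade's function logo: heights, information, and support per feature.

    Arrays are indexed ``[class, coordinate, base]`` (classes restricted to
    those present in the clade's gene set) or ``[coordinate, base]``.
    Features never observed in the clade have support 0 and height 0.
    """

    clade: str
    classes: tuple[str, ...]
    coordinates: tuple[str, ...]
    heights: np.ndarray  # (n_classes, L, 4)
    info: np.ndarray  # (L, 4)
    support: np.ndarray  # (L, 4) int
    background: ClassBackground | None = None
    _coord_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._coord_index = {c: i for i, c in enumerate(self.coordinates)}

    def _feature_idx(self, base: str, coordinate: str) -> tuple[int, int]:
        if coordinate not in self._coord_index:
            raise KeyError(f"coordinate {coordinate!r} not in logo frame")
        return self._coord_index[coordinate], BASES.index(base)

    def height(self, base: str, coordinate: str, cls: str) -> float:
        ci, bi = self._feature_idx(base, coordinate)
        if cls not in self.classes:
            return 0.0
        return float(self.heights[self.classes.index(cls), ci, bi])

    def information(self, base: str, coordinate: str) -> float:
        ci, bi = self._feature_idx(base, coordinate)
        return float(self.info[ci, bi])

    def feature_support(self, base: str, coordinate: str) -> int:
        ci, bi = self._feature_idx(base, coordinate)
        return int(self.support[ci, bi])

    def features(self) -> list[tuple[str, str]]:
        """(base, coordinate) pairs observed in the clade's gene set."""
        out = []
        for ci, coord in enumerate(self.coordinates):
            for bi, b in enumerate(BASES):
                if self.support[ci, bi] > 0:
                    out.append((b, coord))
        return out

    def heights_global(self) -> np.ndarray:
        """Heights lifted to the global class order, with a zero gap column:
        shape (len(CLASSES), L, 5). Classes outside the clade's support and
        gap symbols score zero."""
        H = np.zeros((len(CLASSES), len(self.coordinates), 5))
        for k, cls in enumerate(self.classes):
            H[CLASSES.index(cls), :, :4] = self.heights[k]
        return H

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, coord in enumerate(self.coordinates):
            for bi, b in enumerate(BASES):
                if self.support[ci, bi] == 0:
                    continue
                for k, cls in enumerate(self.classes):
                    h = self.heights[k, ci, bi]
                    if h > 0 or self.info[ci, bi] == 0:
                        rows.append(
                            (coord, b, cls, h, self.info[ci, bi], int(self.support[ci, bi]))
                        )
        return pd.DataFrame(
            rows, columns=["coordinate", "base", "class", "height", "info", "support"]
        )


# ---------------------------------------------------------------------------
# scalar reference operations

def class_conditional_profile(
    genes: Sequence[TRNAGeneRecord],
    feature: tuple[str, str],
    coordinates: Sequence[str],
) -> tuple[int, dict[str, float]]:
    """Count genes carrying ``feature`` = (base, coordinate) and return the
    class distribution among them. Gaps never match."""
    if not genes:
        raise ValueError("gene set is empty")
    base, coord = feature
    coords = list(coordinates)
    if coord not in coords:
        raise KeyError(f"coordinate {coord!r} not in alignment")
    ci = coords.index(coord)
    hits = [g for g in genes if g.aligned_seq[ci] == base]
    if not hits:
        return 0, {}
    counts = {}
    for g in hits:
        if g.functional_type is None:
            raise ValueError(f"gene {g.gene_id} has no functional type")
        counts[g.functional_type] = counts.get(g.functional_type, 0) + 1
    n = len(hits)
    return n, {c: k / n for c, k in counts.items()}


def _exact_small_n_bias(n: int, q: np.ndarray) -> float:
    """Exact E[KL(p_hat || q)] under class draws from q itself.

    The plug-in KL estimate is separable over classes, and each class count
    is Binomial(n, q_i), so the exact null expectation is a sum of binomial
    expectations — no enumeration of multinomial outcomes is needed.
    """
    ks = np.arange(1, n + 1)
    bias = 0.0
    for qi in q:
        pmf = binom.pmf(ks, n, qi)
        bias += float(np.sum(pmf * (ks / n) * np.log2(ks / (n * qi))))
    return bias


def _correction_value(
    correction: str, n: int, support_size: int, q: np.ndarray
) -> float:
    if correction == "none":
        return 0.0
    if correction == "miller_madow":
        return (support_size - 1) / (2.0 * _LN2 * n)
    if correction == "exact_small_n":
        if n <= _EXACT_N_MAX:
            return _exact_small_n_bias(n, q)
        return (support_size - 1) / (2.0 * _LN2 * n)
    raise ValueError(f"correction must be one of {CORRECTIONS}")


def feature_information(
    p: Mapping[str, float],
    n_f: int,
    q: ClassBackground,
    correction: str = "miller_madow",
) -> float:
    """Corrected feature information D_f in bits.

    Raw information is KL(p || q) = sum_i p_i log2(p_i / q_i) with
    0 log 0 := 0; a sample-size bias correction is subtracted and the
    result clamped at zero.
    """
    if n_f < 1:
        raise ValueError("n_f must be >= 1")
    raw = 0.0
    for cls, pi in p.items():
        if pi == 0:
            continue
        if cls not in q.classes:
            raise ValueError(
                f"class {cls!r} has conditional frequency {pi} but no background support"
            )
        raw += pi * math.log2(pi / q.prob(cls))
    support_size = sum(1 for pi in p.values() if pi > 0)
    corr = _correction_value(correction, n_f, support_size, q.q)
    return max(raw - corr, 0.0)


def gorodkin_heights(
    p: Mapping[str, float], q: ClassBackground, D: float
) -> dict[str, float]:
    """Apportion feature information D across classes by background-normalized
    odds: h^i = D * (p_i/q_i) / sum_j (p_j/q_j). Heights sum to D."""
    if D < 0:
        raise ValueError("D must be >= 0")
    ratios = {c: (pi / q.prob(c)) for c, pi in p.items() if pi > 0}
    denom = sum(ratios.values())
    if denom == 0:
        return {c: 0.0 for c in p}
    return {c: D * ratios.get(c, 0.0) / denom for c in p}


# ---------------------------------------------------------------------------
# vectorized clade-level estimation

def _heights_from_counts(
    C: np.ndarray, q: np.ndarray, correction: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heights, info, support from a class x coordinate x base count tensor.

    ``C`` has shape (m, L, 4) over the clade's m supported classes; ``q`` is
    the background over the same classes.
    """
    n = C.sum(axis=0)  # (L, 4)
    carried = n > 0
    n_safe = np.where(carried, n, 1)
    p = C / n_safe
    ratio = p / q[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(C > 0, p * np.log2(np.where(C > 0, ratio, 1.0)), 0.0)
    raw = terms.sum(axis=0)
    support_size = (C > 0).sum(axis=0)
    if correction == "none":
        corr = np.zeros_like(raw)
    else:
        corr = (support_size - 1) / (2.0 * _LN2 * n_safe)
        if correction == "exact_small_n":
            small = carried & (n <= _EXACT_N_MAX)
            if small.any():
                exact = {int(nv): _exact_small_n_bias(int(nv), q) for nv in np.unique(n[small])}
                corr = corr.copy()
                for nv, cv in exact.items():
                    corr[small & (n == nv)] = cv
        elif correction != "miller_madow":
            raise ValueError(f"correction must be one of {CORRECTIONS}")
    D = np.clip(raw - corr, 0.0, None)
    D[~carried] = 0.0
    denom = ratio.sum(axis=0)
    denom_safe = np.where(denom > 0, denom, 1.0)
    H = D * ratio / denom_safe
    H[:, ~carried] = 0.0
    return H, D, n.astype(np.int64)


def _count_tensor(
    codes: np.ndarray, class_idx: np.ndarray, n_classes: int
) -> np.ndarray:
    """(n_classes, L, 4) counts of genes of each class with each base at
    each coordinate. Gaps (code 4) are dropped."""
    n, L = codes.shape
    flat = class_idx[:, None] * (L * 5) + np.arange(L)[None, :] * 5 + codes
    counts = np.bincount(flat.ravel(), minlength=n_classes * L * 5)
    return counts.reshape(n_classes, L, 5)[:, :, :4]


def _background_vector(
    source: str,
    clade_class_counts: np.ndarray,
    pooled_class_counts: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Support mask (over global CLASSES) and q restricted to the support."""
    support = clade_class_counts > 0
    if not support.any():
        raise ValueError("clade has no genes")
    if source == "uniform":
        q = np.full(support.sum(), 1.0 / support.sum())
    elif source == "clade_frequencies":
        c = clade_class_counts[support].astype(float)
        q = c / c.sum()
    elif source == "pooled_frequencies":
        if pooled_class_counts is None:
            raise ValueError("pooled background requires pooled class counts")
        c = pooled_class_counts[support].astype(float)
        if (c == 0).any():
            raise ValueError("pooled background gives zero mass to a supported class")
        q = c / c.sum()
    else:
        raise ValueError(f"background must be one of {BACKGROUNDS}")
    return support, q


def logo_from_counts(
    clade: str,
    coordinates: Sequence[str],
    C_global: np.ndarray,
    class_gene_counts: np.ndarray,
    background: str = "clade_frequencies",
    correction: str = "miller_madow",
    pooled_class_counts: np.ndarray | None = None,
) -> FunctionLogo:
    """Build a :class:`FunctionLogo` from precomputed count tensors.

    ``C_global`` is (len(CLASSES), L, 4); ``class_gene_counts`` is the
    per-class gene count vector (len(CLASSES),) of the clade's set.
    """
    support, q = _background_vector(background, class_gene_counts, pooled_class_counts)
    C = C_global[support]
    H, D, n = _heights_from_counts(C, q, correction)
    classes = tuple(c for c, s in zip(CLASSES, support) if s)
    return FunctionLogo(
        clade=clade,
        classes=classes,
        coordinates=tuple(coordinates),
        heights=H,
        info=D,
        support=n,
        background=ClassBackground(classes, q, background),
    )


def _encode_gene_set(
    genes: Sequence[TRNAGeneRecord],
) -> tuple[np.ndarray, np.ndarray]:
    from trnacif.alphabet import encode_sequence

    codes = np.vstack([encode_sequence(g.aligned_seq) for g in genes])
    idx = np.empty(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        if g.functional_type is None:
            raise ValueError(f"gene {g.gene_id} has no functional type")
        idx[i] = CLASSES.index(g.functional_type)
    return codes, idx


def estimate_clade_logos(
    partition: CladePartition | Mapping[str, Sequence[TRNAGeneRecord]],
    background: str = "clade_frequencies",
    correction: str = "miller_madow",
    coordinates: Sequence[str] | None = None,
) -> dict[str, FunctionLogo]:
    """One function logo per clade gene set. Deterministic given inputs."""
    if isinstance(partition, CladePartition):
        clade_genes = partition.clade_genes
        coordinates = partition.coordinates
    else:
        clade_genes = dict(partition)
        if coordinates is None:
            raise ValueError("coordinates required when passing a bare clade->genes map")
    pooled = np.zeros(len(CLASSES), dtype=np.int64)
    per_clade: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for clade, genes in clade_genes.items():
        if not genes:
            raise ValueError(f"clade {clade}: empty gene set")
        codes, idx = _encode_gene_set(genes)
        per_clade[clade] = (codes, idx)
        pooled += np.bincount(idx, minlength=len(CLASSES))
    logos = {}
    for clade, (codes, idx) in per_clade.items():
        C = _count_tensor(codes, idx, len(CLASSES))
        counts = np.bincount(idx, minlength=len(CLASSES))
        logos[clade] = logo_from_counts(
            clade, coordinates, C, counts, background, correction, pooled
        )
    return logos


# ---------------------------------------------------------------------------
# logo table export / import

def export_logo_table(logo: FunctionLogo, path: str | Path) -> None:
    """Write a logo as TSV (coordinate, base, class, height, info, support).

    Header comment lines preserve the clade label, coordinate frame, and
    class order so that :func:`read_logo_table` reproduces the height,
    information, and support arrays exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"#clade\t{logo.clade}\n")
        fh.write("#coordinates\t" + " ".join(logo.coordinates) + "\n")
        fh.write("#classes\t" + " ".join(logo.classes) + "\n")
        logo.to_frame().to_csv(fh, sep="\t", index=False)


def read_logo_table(path: str | Path) -> FunctionLogo:
    """Inverse of :func:`export_logo_table` (background metadata is not
    reconstructed; the logo is fully usable for scoring)."""
    clade, coords, classes = None, None, None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                tag, _, rest = line.rstrip("\n").partition("\t")
                if tag == "#clade":
                    clade = rest
                elif tag == "#coordinates":
                    coords = tuple(rest.split())
                elif tag == "#classes":
                    classes = tuple(rest.split())
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(
            fh, sep="\t", float_precision="round_trip",
            dtype={"coordinate": str, "base": str, "class": str},
        )
    if clade is None or coords is None or classes is None:
        raise ValueError(f"{path}: missing logo header lines")
    L = len(coords)
    H = np.zeros((len(classes), L, 4))
    D = np.zeros((L, 4))
    n = np.zeros((L, 4), dtype=np.int64)
    ci = {c: i for i, c in enumerate(coords)}
    ki = {c: i for i, c in enumerate(classes)}
    for row in df.to_dict("records"):
        i, b = ci[str(row["coordinate"])], BASES.index(row["base"])
        H[ki[row["class"]], i, b] = row["height"]
        D[i, b] = row["info"]
        n[i, b] = row["support"]
    return FunctionLogo(clade, classes, coords, H, D, n, None)
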