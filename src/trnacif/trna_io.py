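"""Read, type, filter, and partition Sprinzl-aligned tRNA gene complements.

The alignment frame is a list of Sprinzl coordinate labels (opaque strings;
insertion codes such as "20a" and "e11" are allowed) shared by every gene.
Two on-disk formats are supported:

* **tabular** — a TSV whose first line is
  ``#coordinates<TAB>label1 label2 ...`` followed by a header row
  ``gene_id genome_id functional_type anticodon has_intron aligned_seq``
  (``functional_type``, ``anticodon`` and ``has_intron`` may be empty);
* **stockholm** — a Stockholm alignment carrying a
  ``#=GF SPRINZL label1 label2 ...`` line for the coordinate frame and
  per-gene metadata in ``#=GS <gene> DE key=value ...`` lines
  (keys ``genome``, ``type``, ``anticodon``, ``intron``).

All sequence input is normalized to the RNA alphabet (T -> U, case folded);
IUPAC ambiguity codes are treated as gaps because features are defined only
over {A, C, G, U}.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from trnacif.alphabet import CLASSES, encode_sequence, normalize_sequence

__all__ = [
    "TRNAGeneRecord",
    "SprinzlAlignment",
    "GenomeComplement",
    "CladeMap",
    "CladePartition",
    "FilterRules",
    "read_aligned_genes",
    "write_aligned_genes",
    "assign_functional_types",
    "filter_predictions",
    "prune_columns",
    "partition_by_clade",
    "leave_one_out_sets",
    "complement_summary",
    "summary_from_counts",
]


class FormatError(ValueError):
    """Raised when an input file violates the alignment format contract."""


class TypingError(ValueError):
    """Raised when a gene cannot be assigned a functional class."""


class MappingError(ValueError):
    """Raised when genomes and clade assignments do not line up."""


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One aligned tRNA gene.

    ``functional_type`` is one of the 22 class symbols (or ``None`` before
    typing); ``anticodon`` is the 5'->3' anticodon triplet when known.
    """

    gene_id: str
    genome_id: str
    aligned_seq: str
    functional_type: str | None = None
    anticodon: str | None = None
    has_intron: bool = False

    def __post_init__(self) -> None:
        if self.functional_type is not None and self.functional_type not in CLASSES:
            raise TypingError(
                f"gene {self.gene_id}: functional type {self.functional_type!r} "
                f"is not one of the {len(CLASSES)} recognized classes"
            )


@dataclass
class SprinzlAlignment:
    """A Sprinzl-coordinate-aligned set of tRNA genes."""

    coordinates: tuple[str, ...]
    genes: list[TRNAGeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = tuple(str(c) for c in self.coordinates)
        if len(set(self.coordinates)) != len(self.coordinates):
            raise FormatError("Sprinzl coordinate labels must be unique")
        width = len(self.coordinates)
        for g in self.genes:
            if len(g.aligned_seq) != width:
                raise FormatError(
                    f"gene {g.gene_id}: aligned sequence length {len(g.aligned_seq)} "
                    f"does not match the {width} coordinate labels"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def genome_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.genome_id, None)
        return list(seen)

    def encoded(self) -> np.ndarray:
        """uint8 matrix (n_genes, n_coordinates); A=0..U=3, gap=4."""
        if not self.genes:
            return np.empty((0, len(self.coordinates)), dtype=np.uint8)
        return np.vstack([encode_sequence(g.aligned_seq) for g in self.genes])

    def complements(self) -> list["GenomeComplement"]:
        by_genome: dict[str, list[TRNAGeneRecord]] = {}
        for g in self.genes:
            by_genome.setdefault(g.genome_id, []).append(g)
        return [GenomeComplement(gid, genes) for gid, genes in by_genome.items()]


@dataclass
class GenomeComplement:
    """The tRNA gene complement of one genome."""

    genome_id: str
    genes: list[TRNAGeneRecord]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"genome {self.genome_id}: empty tRNA gene complement")
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} belongs to genome {g.genome_id}, "
                    f"not {self.genome_id}"
                )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CladeMap:
    """Genome -> clade assignments with a minimum pooled-gene threshold.

    ``aliases`` supports clade fusion (e.g. mapping both B2 and B3 to B2+3)
    and is applied when the map is constructed.
    """

    assignments: dict[str, str]
    min_gene_count: int = 120
    aliases: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.aliases:
            self.assignments = {
                g: self.aliases.get(c, c) for g, c in self.assignments.items()
            }

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c, None)
        return list(seen)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        min_gene_count: int = 120,
        aliases: Mapping[str, str] | None = None,
    ) -> "CladeMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None,
                         names=["genome_id", "clade"])
        if df.empty:
            raise MappingError(f"clade map {path} is empty")
        return cls(dict(zip(df.genome_id, df.clade)), min_gene_count, aliases)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g, c in self.assignments.items():
                fh.write(f"{g}\t{c}\n")


@dataclass
class CladePartition:
    """Clade-partitioned training gene sets T_X plus the shared coordinate frame."""

    coordinates: tuple[str, ...]
    clade_genes: dict[str, list[TRNAGeneRecord]]
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def clades(self) -> list[str]:
        return list(self.clade_genes)

    def genome_clade(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for clade, genes in self.clade_genes.items():
            for g in genes:
                out[g.genome_id] = clade
        return out


# ---------------------------------------------------------------------------
# reading and writing


def _parse_coordinate_line(line: str, path: str | Path) -> tuple[str, ...]:
    if "\t" not in line:
        raise FormatError(f"{path}: first line must be '#coordinates<TAB>labels'")
    tag, labels = line.rstrip("\n").split("\t", 1)
    if tag.lstrip("#").strip().lower() != "coordinates":
        raise FormatError(f"{path}: missing '#coordinates' header line")
    return tuple(labels.split())


def _read_tabular(path: str | Path) -> SprinzlAlignment:
    with open(path) as fh:
        first = fh.readline()
        coords = _parse_coordinate_line(first, path)
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "genome_id", "aligned_seq"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            seq = normalize_sequence(row.aligned_seq)
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
        if len(seq) != len(coords):
            raise FormatError(
                f"{path}: gene {row.gene_id}: sequence length {len(seq)} != "
                f"{len(coords)} coordinates"
            )
        ftype = getattr(row, "functional_type", "") or None
        anticodon = getattr(row, "anticodon", "") or None
        if anticodon:
            anticodon = anticodon.upper().replace("T", "U")
        intron = str(getattr(row, "has_intron", "")).strip().lower() in {"1", "true", "yes"}
        genes.append(
            TRNAGeneRecord(row.gene_id, row.genome_id, seq, ftype, anticodon, intron)
        )
    return SprinzlAlignment(coords, genes)


def _read_stockholm(path: str | Path) -> SprinzlAlignment:
    coords: tuple[str, ...] | None = None
    meta: dict[str, dict[str, str]] = {}
    seqs: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//":
                continue
            if line.startswith("#=GF SPRINZL"):
                coords = tuple(line.split(None, 2)[2].split())
            elif line.startswith("#=GS"):
                parts = line.split(None, 3)
                if len(parts) == 4 and parts[2] == "DE":
                    kv = {}
                    for tok in parts[3].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            kv[k] = v
                    meta.setdefault(parts[1], {}).update(kv)
            elif not line.startswith("#"):
                name, seq = line.split(None, 1)
                if name not in seqs:
                    order.append(name)
                seqs[name] = seqs.get(name, "") + seq.replace(" ", "")
    if coords is None:
        raise FormatError(f"{path}: no '#=GF SPRINZL' coordinate line found")
    genes = []
    for name in order:
        try:
            seq = normalize_sequence(seqs[name])
        except ValueError as exc:
            raise FormatError(f"{path}: gene {name}: {exc}") from exc
        if len(seq) != len(coords):
            raise FormatError(
                f"{path}: gene {name}: sequence length {len(seq)} != "
                f"{len(coords)} coordinates"
            )
        kv = meta.get(name, {})
        genome = kv.get("genome") or name.split("|")[0]
        anticodon = kv.get("anticodon")
        if anticodon:
            anticodon = anticodon.upper().replace("T", "U")
        genes.append(
            TRNAGeneRecord(
                name,
                genome,
                seq,
                kv.get("type") or None,
                anticodon,
                kv.get("intron", "").lower() in {"1", "true", "yes"},
            )
        )
    return SprinzlAlignment(coords, genes)


def read_aligned_genes(path: str | Path, format: str = "tabular") -> SprinzlAlignment:
    """Read a Sprinzl-aligned tRNA gene set from ``tabular`` or ``stockholm``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path)
    if format == "stockholm":
        return _read_stockholm(path)
    raise ValueError(f"unknown format {format!r}")


def write_aligned_genes(
    aln: SprinzlAlignment, path: str | Path, format: str = "tabular"
) -> None:
    """Write an alignment; :func:`read_aligned_genes` round-trips exactly."""
    if format == "tabular":
        with open(path, "w") as fh:
            fh.write("#coordinates\t" + " ".join(aln.coordinates) + "\n")
            fh.write("gene_id\tgenome_id\tfunctional_type\tanticodon\thas_intron\taligned_seq\n")
            for g in aln.genes:
                fh.write(
                    f"{g.gene_id}\t{g.genome_id}\t{g.functional_type or ''}\t"
                    f"{g.anticodon or ''}\t{'1' if g.has_intron else ''}\t{g.aligned_seq}\n"
                )
    elif format == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            fh.write("#=GF SPRINZL " + " ".join(aln.coordinates) + "\n")
            for g in aln.genes:
                kv = [f"genome={g.genome_id}"]
                if g.functional_type:
                    kv.append(f"type={g.functional_type}")
                if g.anticodon:
                    kv.append(f"anticodon={g.anticodon}")
                if g.has_intron:
                    kv.append("intron=1")
                fh.write(f"#=GS {g.gene_id} DE " + " ".join(kv) + "\n")
            for g in aln.genes:
                fh.write(f"{g.gene_id} {g.aligned_seq}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# functional typing

_RNA_TABLE = CodonTable.unambiguous_rna_by_name["Standard"]
_RC = str.maketrans("ACGU", "UGCA")


def _anticodon_to_class(anticodon: str) -> str:
    """Map an anticodon to its elongator isotype via the standard genetic code."""
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or any(b not in "ACGU" for b in ac):
        raise TypingError(f"invalid anticodon {anticodon!r}")
    codon = ac.translate(_RC)[::-1]
    if codon in _RNA_TABLE.stop_codons:
        raise TypingError(f"anticodon {ac} decodes a stop codon ({codon})")
    return _RNA_TABLE.forward_table[codon]


def assign_functional_types(
    aln: SprinzlAlignment, cau_policy: str = "labels_required"
) -> SprinzlAlignment:
    """Assign functional classes from anticodons.

    Non-CAU genes are typed by reverse-complementing the anticodon to its
    codon and translating with the standard genetic code. Genes with the CAU
    anticodon (initiator Met "X", elongator Met "M", or Ile-CAU "J") cannot
    be discriminated from the anticodon alone; an explicit label is always
    kept, otherwise ``cau_policy`` (``labels_required`` errors,
    ``default_M``/``default_X``/``default_J`` assign that class).
    """
    policies = {"labels_required", "default_M", "default_X", "default_J"}
    if cau_policy not in policies:
        raise ValueError(f"cau_policy must be one of {sorted(policies)}")
    typed = []
    for g in aln.genes:
        if g.functional_type is not None:
            typed.append(g)
            continue
        if g.anticodon is None:
            raise TypingError(f"gene {g.gene_id}: no anticodon and no explicit label")
        if g.anticodon == "CAU":
            if cau_policy == "labels_required":
                raise TypingError(
                    f"gene {g.gene_id}: CAU anticodon requires an explicit "
                    "X/M/J label under labels_required"
                )
            typed.append(replace(g, functional_type=cau_policy[-1]))
        else:
            typed.append(replace(g, functional_type=_anticodon_to_class(g.anticodon)))
    return SprinzlAlignment(aln.coordinates, typed)


# ---------------------------------------------------------------------------
# prediction filtering

@dataclass
class FilterRules:
    """False-positive filters for externally predicted tRNA genes.

    * ``anticodon_whitelist`` — keep only genes whose anticodon is listed;
    * ``intron_isotype_blacklist`` — drop intron-flagged genes of these
      isotypes (isotypes never described as intron-containing);
    * ``exclude_gene_ids`` — explicit manual exclusions (e.g. sequences with
      unusual secondary structure).
    """

    anticodon_whitelist: set[str] | None = None
    intron_isotype_blacklist: set[str] | None = None
    exclude_gene_ids: set[str] | None = None

    @classmethod
    def from_config(cls, path: str | Path) -> "FilterRules":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ValueError(f"filter config {path} must be a key-value mapping")
        def norm(values):
            if values is None:
                return None
            return {str(v).upper().replace("T", "U") for v in values}
        return cls(
            anticodon_whitelist=norm(cfg.get("anticodon_whitelist")),
            intron_isotype_blacklist=(
                set(cfg["intron_isotype_blacklist"])
                if cfg.get("intron_isotype_blacklist") is not None
                else None
            ),
            exclude_gene_ids=(
                set(cfg["exclude_gene_ids"])
                if cfg.get("exclude_gene_ids") is not None
                else None
            ),
        )


def filter_predictions(
    aln: SprinzlAlignment, rules: FilterRules
) -> tuple[SprinzlAlignment, list[tuple[str, str]]]:
    """Apply false-positive filters; returns the kept alignment and a
    rejection log of ``(gene_id, rule_name)`` pairs."""
    kept, log = [], []
    for g in aln.genes:
        if rules.exclude_gene_ids and g.gene_id in rules.exclude_gene_ids:
            log.append((g.gene_id, "exclude_gene_ids"))
            continue
        if rules.anticodon_whitelist is not None and g.anticodon is not None:
            if g.anticodon not in rules.anticodon_whitelist:
                log.append((g.gene_id, "anticodon_whitelist"))
                continue
        if (
            rules.intron_isotype_blacklist is not None
            and g.has_intron
            and g.functional_type in rules.intron_isotype_blacklist
        ):
            log.append((g.gene_id, "intron_isotype_blacklist"))
            continue
        kept.append(g)
    return SprinzlAlignment(aln.coordinates, kept), log


# ---------------------------------------------------------------------------
# column pruning

def prune_columns(
    aln: SprinzlAlignment,
    gap_threshold: float = 0.99,
    drop_coordinates: Iterable[str] = (),
) -> SprinzlAlignment:
    """Remove columns with gap fraction >= ``gap_threshold`` (inclusive,
    matching a "99% or more gaps" rule), then drop explicitly listed
    coordinate labels (variable arm, CCA tail, ...)."""
    if not 0 < gap_threshold <= 1:
        raise ValueError("gap_threshold must be in (0, 1]")
    drop = {str(c) for c in drop_coordinates}
    codes = aln.encoded()
    if len(aln.genes):
        gap_frac = (codes == 4).mean(axis=0)
    else:
        gap_frac = np.zeros(len(aln.coordinates))
    keep = [
        i
        for i, c in enumerate(aln.coordinates)
        if gap_frac[i] < gap_threshold and c not in drop
    ]
    if not keep:
        raise FormatError("pruning removed every alignment column")
    coords = tuple(aln.coordinates[i] for i in keep)
    genes = [
        replace(g, aligned_seq="".join(g.aligned_seq[i] for i in keep))
        for g in aln.genes
    ]
    return SprinzlAlignment(coords, genes)


# ---------------------------------------------------------------------------
# partitioning

def partition_by_clade(
    aln: SprinzlAlignment,
    clade_map: CladeMap,
    query_only: Iterable[str] = (),
) -> CladePartition:
    """Pool genes into per-clade training sets T_X.

    Clades whose pooled gene count falls below ``clade_map.min_gene_count``
    are excluded and reported in ``partition.excluded``. Genomes listed in
    ``query_only`` are skipped; any other unmapped genome is an error.
    """
    if not clade_map.assignments:
        raise MappingError("clade map is empty")
    query = set(query_only)
    by_clade: dict[str, list[TRNAGeneRecord]] = {}
    for g in aln.genes:
        if g.genome_id in query:
            continue
        clade = clade_map.assignments.get(g.genome_id)
        if clade is None:
            raise MappingError(
                f"genome {g.genome_id} has no clade assignment and is not query-flagged"
            )
        by_clade.setdefault(clade, []).append(g)
    excluded = {
        c: len(genes)
        for c, genes in by_clade.items()
        if len(genes) < clade_map.min_gene_count
    }
    kept = {c: genes for c, genes in by_clade.items() if c not in excluded}
    return CladePartition(aln.coordinates, kept, excluded)


def leave_one_out_sets(
    partition: CladePartition, genome_id: str
) -> dict[str, list[TRNAGeneRecord]]:
    """Training sets T_X^g: the partition with genome ``genome_id``'s genes
    removed from its own clade. Other clades are returned unchanged."""
    out: dict[str, list[TRNAGeneRecord]] = {}
    for clade, genes in partition.clade_genes.items():
        reduced = [g for g in genes if g.genome_id != genome_id]
        if len(reduced) < len(genes) and not reduced:
            raise MappingError(
                f"removing genome {genome_id} empties clade {clade}"
            )
        out[clade] = reduced
    return out


# ---------------------------------------------------------------------------
# summaries

def summary_from_counts(genomes: int, genes: int, bases: int) -> dict[str, float]:
    """Display ratios from raw counts: genes per genome (T/G) and non-gap
    bases per gene (N/T), rounded to two decimals."""
    return {
        "genes_per_genome": round(genes / genomes, 2),
        "bases_per_gene": round(bases / genes, 2),
    }


def complement_summary(
    groups: Mapping[str, Sequence[TRNAGeneRecord]] | CladePartition,
) -> pd.DataFrame:
    """Per-group summary: genomes (G), genes (T), T/G, non-gap bases (N),
    N/T, and base composition percentages of non-gap bases.

    Ratios are rounded to two decimals for display; compositions to one.
    """
    if isinstance(groups, CladePartition):
        groups = groups.clade_genes
    rows = []
    for name, genes in groups.items():
        if not genes:
            raise ValueError(f"group {name}: empty gene set")
        n_genomes = len({g.genome_id for g in genes})
        counts = Counter()
        for g in genes:
            counts.update(g.aligned_seq)
        n_bases = sum(counts[b] for b in "ACGU")
        ratios = summary_from_counts(n_genomes, len(genes), n_bases)
        row = {
            "group": name,
            "genomes": n_genomes,
            "genes": len(genes),
            "genes_per_genome": ratios["genes_per_genome"],
            "bases": n_bases,
            "bases_per_gene": ratios["bases_per_gene"],
        }
        for b in "AUGC":
            row[f"pct_{b}"] = round(100.0 * counts[b] / n_bases, 1) if n_bases else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
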