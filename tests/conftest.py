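"""Shared fixtures: tiny hand-built alignments and small synthetic designs."""

from __future__ import annotations

import numpy as np
import pytest

from trnacif.trna_io import CladeMap, SprinzlAlignment, TRNAGeneRecord


def make_gene(gene_id, genome_id, seq, ftype=None, anticodon=None, intron=False):
    return TRNAGeneRecord(gene_id, genome_id, seq, ftype, anticodon, intron)


@pytest.fixture
def tiny_alignment():
    """3 genomes x 2 genes, 5 coordinates, 3 classes."""
    coords = ("1", "2", "3", "20a", "21")
    genes = [
        make_gene("g1|t1", "g1", "ACGUA", "L"),
        make_gene("g1|t2", "g1", "AC-UA", "F"),
        make_gene("g2|t1", "g2", "GCGUA", "L"),
        make_gene("g2|t2", "g2", "ACGU-", "X"),
        make_gene("g3|t1", "g3", "GAGUA", "L"),
        make_gene("g3|t2", "g3", "ACGUC", "F"),
    ]
    return SprinzlAlignment(coords, genes)


@pytest.fixture
def tiny_clade_map():
    return CladeMap({"g1": "A", "g2": "A", "g3": "B"}, min_gene_count=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
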