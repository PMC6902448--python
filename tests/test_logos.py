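"""Function-logo estimation: profiles, information, Gorodkin heights.

The vectorized clade-level estimator is cross-checked against an
independent brute-force implementation that enumerates gene counts and
evaluates the defining formulas directly on micro-alignments.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnacif.alphabet import BASES, CLASSES
from trnacif.logos import (
    ClassBackground,
    class_conditional_profile,
    estimate_clade_logos,
    export_logo_table,
    feature_information,
    gorodkin_heights,
    read_logo_table,
)
from trnacif.trna_io import SprinzlAlignment

from conftest import make_gene


# ---------------------------------------------------------------------------
# independent brute-force oracle

def brute_force_logo(genes, coordinates, background="clade_frequencies",
                     correction="none"):
    """Direct evaluation of the logo formulas by explicit enumeration."""
    classes = sorted({g.functional_type for g in genes},
                     key=CLASSES.index)
    if background == "uniform":
        q = {c: 1 / len(classes) for c in classes}
    else:
        q = {c: sum(g.functional_type == c for g in genes) / len(genes)
             for c in classes}
    out = {}
    for ci, coord in enumerate(coordinates):
        for b in BASES:
            carriers = [g for g in genes if g.aligned_seq[ci] == b]
            n = len(carriers)
            if n == 0:
                continue
            p = {c: sum(g.functional_type == c for g in carriers) / n
                 for c in classes}
            raw = sum(pi * math.log2(pi / q[c]) for c, pi in p.items() if pi > 0)
            if correction == "miller_madow":
                m = sum(1 for pi in p.values() if pi > 0)
                raw -= (m - 1) / (2 * math.log(2) * n)
            D = max(raw, 0.0)
            denom = sum(pi / q[c] for c, pi in p.items())
            heights = {c: (D * (pi / q[c]) / denom if denom > 0 else 0.0)
                       for c, pi in p.items()}
            out[(b, coord)] = (n, D, heights)
    return out


def micro_alignment(seed, n_genes=5, n_cols=4):
    rng = np.random.default_rng(seed)
    coords = tuple(str(i + 1) for i in range(n_cols))
    classes = ["L", "F", "X"]
    genes = []
    for i in range(n_genes):
        seq = "".join(rng.choice(list("ACGU-"), size=n_cols))
        if set(seq) == {"-"}:
            seq = "A" + seq[1:]
        genes.append(
            make_gene(f"g{i}|t", f"g{i}", seq, classes[i % len(classes)])
        )
    return SprinzlAlignment(coords, genes)


# ---------------------------------------------------------------------------
# scalar operations

class TestProfile:
    def test_single_class_profile(self):
        genes = [make_gene(f"g{i}|t", f"g{i}", "A", "L") for i in range(10)]
        n, p = class_conditional_profile(genes, ("A", "1"), ("1",))
        assert n == 10 and p == {"L": 1.0}

    def test_counting(self):
        genes = [make_gene(f"g{i}|t", f"g{i}", "G", c)
                 for i, c in enumerate("LLFX")]
        n, p = class_conditional_profile(genes, ("G", "1"), ("1",))
        assert n == 4 and p == {"L": 0.5, "F": 0.25, "X": 0.25}

    def test_absent_feature_and_gap_never_matches(self):
        genes = [make_gene("g|t", "g", "-", "L")]
        n, p = class_conditional_profile(genes, ("A", "1"), ("1",))
        assert n == 0 and p == {}

    def test_unknown_coordinate_is_lookup_error(self):
        genes = [make_gene("g|t", "g", "A", "L")]
        with pytest.raises(KeyError):
            class_conditional_profile(genes, ("A", "99"), ("1",))


class TestFeatureInformation:
    def test_p_equals_q_gives_zero(self):
        q = ClassBackground.uniform(("L", "F"))
        assert feature_information({"L": 0.5, "F": 0.5}, 10, q, "none") == 0.0

    def test_concentrated_class_gives_log2_k(self):
        q = ClassBackground.uniform(CLASSES)
        D = feature_information({"L": 1.0}, 5, q, "none")
        assert D == pytest.approx(math.log2(22), abs=1e-12)

    def test_two_of_four_classes_gives_one_bit(self):
        q = ClassBackground.uniform(("A", "C", "G", "L"))
        D = feature_information({"A": 0.5, "G": 0.5}, 8, q, "none")
        assert D == pytest.approx(1.0, abs=1e-12)

    def test_missing_background_support_is_error(self):
        q = ClassBackground(("L",), np.array([1.0]))
        with pytest.raises(ValueError, match="background support"):
            feature_information({"F": 1.0}, 3, q, "none")

    def test_miller_madow_shrinks_and_vanishes(self):
        q = ClassBackground.uniform(("L", "F", "X"))
        p = {"L": 0.6, "F": 0.4}
        raw = feature_information(p, 10, q, "none")
        for n in (5, 50, 500):
            corrected = feature_information(p, n, q, "miller_madow")
            assert corrected <= raw
        assert feature_information(p, 10**6, q, "miller_madow") == pytest.approx(
            raw, abs=1e-5
        )

    def test_exact_small_n_matches_binomial_expectation(self):
        # n=2, uniform q over 2 classes: outcomes (2,0),(1,1),(0,2) with
        # probs 1/4,1/2,1/4 and plug-in KL 1,0,1 -> expected bias 0.5
        q = ClassBackground.uniform(("L", "F"))
        D = feature_information({"L": 1.0}, 2, q, "exact_small_n")
        assert D == pytest.approx(1.0 - 0.5, abs=1e-12)

    def test_correction_clamped_at_zero(self):
        q = ClassBackground.uniform(("L", "F", "X"))
        assert feature_information({"L": 1 / 3, "F": 1 / 3, "X": 1 / 3}, 2, q,
                                   "miller_madow") == 0.0


class TestGorodkinHeights:
    def test_zero_information_gives_zero_heights(self):
        q = ClassBackground.uniform(("L", "F"))
        assert gorodkin_heights({"L": 0.5, "F": 0.5}, q, 0.0) == {"L": 0.0, "F": 0.0}

    def test_symmetric_split(self):
        q = ClassBackground.uniform(("A", "C", "G", "L"))
        h = gorodkin_heights({"A": 0.5, "G": 0.5}, q, 1.0)
        assert h["A"] == pytest.approx(0.5) and h["G"] == pytest.approx(0.5)

    def test_single_class_limit(self):
        q = ClassBackground.uniform(CLASSES)
        h = gorodkin_heights({"L": 1.0}, q, math.log2(22))
        assert h["L"] == pytest.approx(math.log2(22))

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.floats(0.0, 5.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_heights_sum_to_information_and_scale_linearly(self, weights, D):
        classes = tuple(CLASSES[: len(weights)])
        p_arr = np.array(weights) / sum(weights)
        p = dict(zip(classes, p_arr))
        q = ClassBackground.uniform(classes)
        h = gorodkin_heights(p, q, D)
        assert sum(h.values()) == pytest.approx(D, abs=1e-9)
        assert all(v >= 0 for v in h.values())
        h2 = gorodkin_heights(p, q, 2 * D)
        for c in classes:
            assert h2[c] == pytest.approx(2 * h[c], abs=1e-9)


# ---------------------------------------------------------------------------
# clade-level estimation vs brute force

class TestEstimateCladeLogos:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("background", ["uniform", "clade_frequencies"])
    def test_matches_brute_force_on_micro_alignments(self, seed, background):
        aln = micro_alignment(seed)
        logos = estimate_clade_logos(
            {"X": aln.genes}, background=background, correction="none",
            coordinates=aln.coordinates,
        )
        expected = brute_force_logo(aln.genes, aln.coordinates, background, "none")
        logo = logos["X"]
        assert set(logo.features()) == set(expected)
        for (b, coord), (n, D, heights) in expected.items():
            assert logo.feature_support(b, coord) == n
            assert logo.information(b, coord) == pytest.approx(D, abs=1e-12)
            for c, h in heights.items():
                assert logo.height(b, coord, c) == pytest.approx(h, abs=1e-12)

    def test_miller_madow_matches_brute_force(self):
        aln = micro_alignment(3)
        logo = estimate_clade_logos(
            {"X": aln.genes}, correction="miller_madow",
            coordinates=aln.coordinates,
        )["X"]
        expected = brute_force_logo(
            aln.genes, aln.coordinates, "clade_frequencies", "miller_madow"
        )
        for (b, coord), (n, D, heights) in expected.items():
            assert logo.information(b, coord) == pytest.approx(D, abs=1e-12)

    def test_degenerate_single_gene_clade(self):
        genes = [make_gene("g|t", "g", "ACGU", "L")]
        logo = estimate_clade_logos(
            {"X": genes}, coordinates=("1", "2", "3", "4")
        )["X"]
        for b, coord in logo.features():
            # one class only: p concentrates on it
            assert logo.height(b, coord, "L") == logo.information(b, coord)

    def test_deterministic(self, tiny_alignment):
        genes = tiny_alignment.genes
        a = estimate_clade_logos({"X": genes}, coordinates=tiny_alignment.coordinates)
        b = estimate_clade_logos({"X": genes}, coordinates=tiny_alignment.coordinates)
        assert np.array_equal(a["X"].heights, b["X"].heights)

    def test_clades_differing_at_one_coordinate(self):
        coords = ("1", "2", "3")
        base1 = [make_gene(f"a{i}|t", f"a{i}", "ACG", "L") for i in range(4)]
        base2 = [make_gene(f"b{i}|t", f"b{i}", "ACU", "L") for i in range(4)]
        logos = estimate_clade_logos(
            {"P": base1, "Q": base2}, coordinates=coords
        )
        # identical at coordinates 1-2, different only at coordinate 3
        for coord in ("1", "2"):
            for b in BASES:
                assert logos["P"].information(b, coord) == pytest.approx(
                    logos["Q"].information(b, coord)
                )
        assert logos["P"].feature_support("G", "3") == 4
        assert logos["Q"].feature_support("U", "3") == 4

    def test_height_normalization_on_random_synthetic_data(self):
        from trnacif.simulate import SyntheticDesign, generate_dataset
        from trnacif.trna_io import partition_by_clade

        for seed in range(5):
            d = SyntheticDesign(
                n_clades=3, genomes_per_clade=3, genes_per_genome=(8, 15),
                n_coordinates=12, n_planted_features=4, signal=0.7, seed=seed,
            )
            aln, cmap, _ = generate_dataset(d)
            part = partition_by_clade(aln, cmap)
            for corr in ("none", "miller_madow", "exact_small_n"):
                for logo in estimate_clade_logos(part, correction=corr).values():
                    assert (logo.heights >= 0).all()
                    np.testing.assert_allclose(
                        logo.heights.sum(axis=0), logo.info, atol=1e-9
                    )

    def test_corrected_information_never_exceeds_uncorrected(self):
        aln = micro_alignment(7, n_genes=5, n_cols=4)
        raw = estimate_clade_logos({"X": aln.genes}, correction="none",
                                   coordinates=aln.coordinates)["X"]
        for corr in ("miller_madow", "exact_small_n"):
            fixed = estimate_clade_logos({"X": aln.genes}, correction=corr,
                                         coordinates=aln.coordinates)["X"]
            assert (fixed.info <= raw.info + 1e-12).all()


# ---------------------------------------------------------------------------
# export / import

class TestLogoTable:
    def test_round_trip_exact(self, tmp_path):
        aln = micro_alignment(2)
        logo = estimate_clade_logos({"X": aln.genes},
                                    coordinates=aln.coordinates)["X"]
        p = tmp_path / "logo.tsv"
        export_logo_table(logo, p)
        back = read_logo_table(p)
        assert back.clade == logo.clade
        assert back.coordinates == logo.coordinates
        np.testing.assert_array_equal(back.heights, logo.heights)
        np.testing.assert_array_equal(back.info, logo.info)
        np.testing.assert_array_equal(back.support, logo.support)

    def test_single_feature_logo_row_budget(self, tmp_path):
        genes = [make_gene(f"g{i}|t", f"g{i}", "A", CLASSES[i % 22])
                 for i in range(30)]
        logo = estimate_clade_logos({"X": genes}, coordinates=("1",))["X"]
        df = logo.to_frame()
        assert 1 <= len(df) <= 22
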