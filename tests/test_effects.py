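"""Allele-window construction and motif scanning over SNVs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from postgwas import (
    CandidateVariant,
    GenomeSequence,
    PositionFrequencyMatrix,
    allele_deltas,
    allele_windows,
    scan_variant,
)
from postgwas.effects import AlleleWindowPair, RefAlleleMismatch
from postgwas.pwm import DegenerateMatrixError

from conftest import naive_best_placement, random_pwm


def variant_at(genome: GenomeSequence, contig: str, pos: int, alt: str) -> CandidateVariant:
    ref = genome.base_at(contig, pos)
    return CandidateVariant(f"v{pos}", contig, pos, ref, alt, 1e-6, 0.3, 0.9)


class TestAlleleWindows:
    def test_length_one_gives_one_pair_per_strand(self):
        g = GenomeSequence({"c": "ACGTACGTAC"})
        pairs, dropped = allele_windows(g, variant_at(g, "c", 5, "C"), 1)
        assert len(pairs) == 2 and dropped == 0
        plus = [p for p in pairs if p.strand == "+"][0]
        assert plus.ref_window == "A" and plus.alt_window == "C" and plus.offset == 0

    def test_interior_placement_count(self):
        g = GenomeSequence({"c": "ACGTACGTAC"})
        pairs, dropped = allele_windows(g, variant_at(g, "c", 5, "C"), 3)
        assert len(pairs) == 6 and dropped == 0  # 3 placements x 2 strands

    def test_boundary_placements_dropped(self):
        g = GenomeSequence({"c": "ACGTACGTAC"})
        pairs, dropped = allele_windows(g, variant_at(g, "c", 1, "C"), 3)
        assert len(pairs) == 2 and dropped == 2

    def test_placement_count_law(self):
        # valid pairs = 2 * (L - dropped) on every fixture
        g = GenomeSequence({"c": "ACGTACGTACGTACG"})
        for pos in (1, 2, 8, 14, 15):
            for L in (1, 2, 4, 6):
                v = variant_at(g, "c", pos, "C" if g.base_at("c", pos) != "C" else "G")
                pairs, dropped = allele_windows(g, v, L)
                assert len(pairs) == 2 * (L - dropped)

    def test_windows_containing_n_dropped(self):
        g = GenomeSequence({"c": "ANGTA"})
        pairs, dropped = allele_windows(g, variant_at(g, "c", 4, "C"), 3)
        # placements starting at 2..4 (1-based): [NGT], [GTA], [TA+off-contig]
        assert dropped == 2
        assert all("N" not in p.ref_window for p in pairs)

    def test_ref_mismatch_is_row_error(self):
        g = GenomeSequence({"c": "ACGTA"})
        v = CandidateVariant("v", "c", 3, "A", "C", 1e-6, 0.3, 0.9)  # genome has G
        with pytest.raises(RefAlleleMismatch):
            allele_windows(g, v, 2)

    def test_minus_strand_offset_reindexed(self):
        g = GenomeSequence({"c": "ACGTACGTAC"})
        pairs, _ = allele_windows(g, variant_at(g, "c", 5, "C"), 3)
        for plus in (p for p in pairs if p.strand == "+"):
            minus = next(
                m for m in pairs
                if m.strand == "-" and m.offset == 2 - plus.offset
                and m.ref_window == plus.ref_window[::-1].translate(
                    str.maketrans("ACGT", "TGCA")
                )
            )
            assert minus.alt_window[minus.offset] != minus.ref_window[minus.offset]


class TestScanVariant:
    def test_worked_example(self, ttaat_scene):
        genome, variant, motif = ttaat_scene
        (hit,) = scan_variant(genome, variant, [motif])
        assert hit.is_match
        assert hit.strand == "+"
        assert hit.mss_ref == pytest.approx(0.5)
        assert hit.mss_alt == pytest.approx(1.0)
        assert hit.delta_nrm == pytest.approx(0.5)

    def test_disrupting_alt_gives_negative_deltas(self, two_col_motif):
        # genome carries the consensus AC at 3-4; the alt destroys its A
        genome = GenomeSequence({"c": "TTACT"})
        v = CandidateVariant("v", "c", 3, "A", "T", 1e-6, 0.3, 0.9)
        (hit,) = scan_variant(genome, v, [two_col_motif])
        assert hit.mss_ref == pytest.approx(1.0)
        assert hit.delta_nrm < 0 and hit.delta_abs < 0

    def test_exact_threshold_equality_is_not_a_match(self, two_col_motif):
        # set the threshold to the scene's best attainable mSS exactly:
        # the strict "greater than" rule must not fire at equality
        genome = GenomeSequence({"c": "TTAAT"})
        v = CandidateVariant("v", "c", 4, "A", "T", 1e-6, 0.3, 0.9)
        from postgwas import allele_windows, matrix_similarity

        pairs, _ = allele_windows(genome, v, len(two_col_motif))
        best = max(
            max(matrix_similarity(two_col_motif, p.ref_window),
                matrix_similarity(two_col_motif, p.alt_window))
            for p in pairs
        )
        (hit,) = scan_variant(genome, v, [two_col_motif], threshold=best)
        assert max(hit.mss_ref, hit.mss_alt) == best
        assert not hit.is_match
        (hit_lo,) = scan_variant(genome, v, [two_col_motif], threshold=best - 1e-9)
        assert hit_lo.is_match

    def test_uninformative_motif_skipped(self):
        uniform = PositionFrequencyMatrix("u", np.full((2, 4), 0.25))
        genome = GenomeSequence({"c": "TTAAT"})
        v = CandidateVariant("v", "c", 4, "A", "C", 1e-6, 0.3, 0.9)
        assert scan_variant(genome, v, [uniform]) == []

    def test_all_placements_emits_every_pair(self, ttaat_scene):
        genome, variant, motif = ttaat_scene
        hits = scan_variant(genome, variant, [motif], all_placements=True)
        pairs, _ = allele_windows(genome, variant, len(motif))
        assert len(hits) == len(pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_brute_force_oracle_equivalence(self, seed):
        """The kept report equals an exhaustive enumeration of placements/strands."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(1, 6))
        n = int(rng.integers(length + 2, 30))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        pos = int(rng.integers(1, n + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        f = random_pwm(rng, length)
        pfm = PositionFrequencyMatrix("m", f)
        genome = GenomeSequence({"c": seq})
        v = CandidateVariant("v", "c", pos, ref, alt, 1e-6, 0.3, 0.9)
        hits = scan_variant(genome, v, [pfm])
        expected = naive_best_placement(seq, pos, ref, alt, f)
        if expected is None:
            assert hits == []
            return
        _, _, _, strand, offset, mss_r, mss_a = expected
        (hit,) = hits
        assert (hit.strand, hit.offset) == (strand, offset)
        assert hit.mss_ref == pytest.approx(mss_r, abs=1e-9)
        assert hit.mss_alt == pytest.approx(mss_a, abs=1e-9)


class TestAlleleDeltas:
    def test_hand_evaluated_deltas(self, two_col_motif):
        pair = AlleleWindowPair("c", 2, 1, "+", "AA", "AC")
        d_nrm, d_abs = allele_deltas(two_col_motif, pair)
        assert d_nrm == pytest.approx(0.5)
        assert d_abs == pytest.approx(0.3859, abs=1e-4)

    def test_antisymmetry_on_swap(self, two_col_motif):
        fwd = AlleleWindowPair("c", 2, 1, "+", "AA", "AC")
        rev = AlleleWindowPair("c", 2, 1, "+", "AC", "AA")
        d1 = allele_deltas(two_col_motif, fwd)
        d2 = allele_deltas(two_col_motif, rev)
        assert d1[0] == pytest.approx(-d2[0], abs=1e-12)
        assert d1[1] == pytest.approx(-d2[1], abs=1e-12)

    def test_uniform_column_kills_delta_abs(self):
        pfm = PositionFrequencyMatrix(
            "m", np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
        )
        pair = AlleleWindowPair("c", 2, 1, "+", "AA", "AC")
        _, d_abs = allele_deltas(pfm, pair)
        assert d_abs == pytest.approx(0.0, abs=1e-12)

    def test_uninformative_motif_raises(self):
        uniform = PositionFrequencyMatrix("u", np.full((2, 4), 0.25))
        pair = AlleleWindowPair("c", 2, 1, "+", "AA", "AC")
        with pytest.raises(DegenerateMatrixError):
            allele_deltas(uniform, pair)

    def test_window_pair_invariant_enforced(self):
        with pytest.raises(ValueError, match="exactly the offset"):
            AlleleWindowPair("c", 2, 0, "+", "AA", "AC")  # differ at 1, not 0
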