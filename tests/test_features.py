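import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operon_voter.features import (
    AdjacentPair,
    compute_features,
    enumerate_adjacent_pairs,
    extract_windows,
    filter_expressed,
    kruskal_wallis,
)
from operon_voter.io import CoverageTrack, GeneRecord

from kw_oracle import kw_oracle, kw_permutation_p


def track_of(depths, sample_id="s1", seqid="chr1"):
    return CoverageTrack(sample_id, {seqid: np.asarray(depths, dtype=np.int64)})


def genes_plus_plus():
    return [
        GeneRecord("chr1", 101, 400, "g1", "+"),
        GeneRecord("chr1", 451, 800, "g2", "+"),
    ]


class TestAdjacency:
    def test_plus_plus_orientation(self):
        (pair,) = enumerate_adjacent_pairs(genes_plus_plus())
        assert pair.geneA.gene_id == "g1" and pair.geneB.gene_id == "g2"
        assert (pair.intergenic_start, pair.intergenic_end) == (401, 450)
        assert pair.intergenic_length == 50 and pair.strand_match == 1

    def test_minus_minus_five_prime_gene_is_right(self):
        genes = [
            GeneRecord("chr1", 100, 400, "g1", "-"),
            GeneRecord("chr1", 451, 800, "g2", "-"),
        ]
        (pair,) = enumerate_adjacent_pairs(genes)
        # minus-strand transcription runs right-to-left: g2 is 5'-most
        assert pair.geneA.gene_id == "g2" and pair.geneB.gene_id == "g1"
        assert pair.intergenic_length == 50 and pair.strand_match == 1

    def test_opposite_strands_left_gene_is_A(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "-"),
            GeneRecord("chr1", 151, 300, "g2", "+"),
        ]
        (pair,) = enumerate_adjacent_pairs(genes)
        assert pair.geneA.gene_id == "g1" and pair.strand_match == 0

    def test_overlapping_genes_negative_length(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "+"),
            GeneRecord("chr1", 95, 200, "g2", "+"),
        ]
        (pair,) = enumerate_adjacent_pairs(genes)
        assert pair.intergenic_length == -6

    def test_seqids_independent(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "+"),
            GeneRecord("chr2", 200, 300, "g2", "+"),
        ]
        assert enumerate_adjacent_pairs(genes) == []

    def test_same_strand_only_flag(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "-"),
            GeneRecord("chr1", 151, 300, "g2", "+"),
            GeneRecord("chr1", 400, 500, "g3", "+"),
        ]
        pairs = enumerate_adjacent_pairs(genes, same_strand_only=True)
        assert [p.pair_id for p in pairs] == ["g2|g3"]


class TestExpressionFilter:
    def build(self, mean_a, mean_b):
        genes = [
            GeneRecord("chr1", 1, 10, "ga", "+"),
            GeneRecord("chr1", 21, 30, "gb", "+"),
        ]
        depth = np.zeros(40, dtype=int)
        depth[0:10] = mean_a
        depth[20:30] = mean_b
        return enumerate_adjacent_pairs(genes), track_of(depth)

    def test_or_rule_keeps(self):
        pairs, track = self.build(12, 3)
        assert len(filter_expressed(pairs, track)) == 1

    def test_strict_threshold_drops(self):
        pairs, track = self.build(9, 9)
        assert filter_expressed(pairs, track) == []

    def test_boundary_exactly_ten_kept(self):
        pairs, track = self.build(10, 0)
        assert len(filter_expressed(pairs, track)) == 1

    def test_all_zero_coverage_drops_all(self):
        pairs, track = self.build(0, 0)
        assert filter_expressed(pairs, track) == []


class TestWindows:
    def test_plus_plus_window_coordinates(self):
        depth = np.arange(1, 1001)  # depth == position, makes slices legible
        (pair,) = enumerate_adjacent_pairs(genes_plus_plus())
        w = extract_windows(pair, track_of(depth))
        assert w.covA.tolist() == list(range(351, 401))
        assert w.covI.tolist() == list(range(401, 451))
        assert w.covB.tolist() == list(range(451, 501))

    def test_minus_minus_windows_mirror(self):
        depth = np.arange(1, 1001)
        genes = [
            GeneRecord("chr1", 101, 400, "g1", "-"),
            GeneRecord("chr1", 451, 800, "g2", "-"),
        ]
        (pair,) = enumerate_adjacent_pairs(genes)
        w = extract_windows(pair, track_of(depth))
        # gene A is g2; its 3' end is its genomic left edge
        assert w.covA.tolist() == list(range(451, 501))
        assert w.covB.tolist() == list(range(351, 401))
        assert w.covI.tolist() == list(range(401, 451))

    def test_minus_layout_equals_flipped_plus_layout(self):
        """Orientation oracle: reverse the genome and strands; the window
        multisets must be identical."""
        rng = np.random.default_rng(5)
        depth = rng.integers(0, 60, size=1000)
        genes = [
            GeneRecord("chr1", 101, 400, "g1", "+"),
            GeneRecord("chr1", 451, 800, "g2", "+"),
        ]
        (pair,) = enumerate_adjacent_pairs(genes)
        w_fwd = extract_windows(pair, track_of(depth))
        # flipped layout: coordinate x -> 1001 - x, strands to minus
        flipped = depth[::-1].copy()
        genes_rev = [
            GeneRecord("chr1", 1001 - 400, 1001 - 101, "g1", "-"),
            GeneRecord("chr1", 1001 - 800, 1001 - 451, "g2", "-"),
        ]
        (pair_rev,) = enumerate_adjacent_pairs(genes_rev)
        assert pair_rev.geneA.gene_id == "g1"
        w_rev = extract_windows(pair_rev, track_of(flipped))
        assert sorted(w_fwd.covA) == sorted(w_rev.covA)
        assert sorted(w_fwd.covI) == sorted(w_rev.covI)
        assert sorted(w_fwd.covB) == sorted(w_rev.covB)

    def test_short_intergenic_uses_whole_region(self):
        genes = [
            GeneRecord("chr1", 101, 400, "g1", "+"),
            GeneRecord("chr1", 408, 700, "g2", "+"),
        ]
        depth = np.arange(1, 801)
        (pair,) = enumerate_adjacent_pairs(genes)
        assert pair.intergenic_length == 7
        w = extract_windows(pair, track_of(depth))
        assert w.covI.tolist() == list(range(401, 408))

    def test_central_window_left_biased(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "+"),
            GeneRecord("chr1", 172, 300, "g2", "+"),
        ]
        depth = np.arange(1, 301)
        (pair,) = enumerate_adjacent_pairs(genes)
        assert pair.intergenic_length == 71
        w = extract_windows(pair, track_of(depth))
        # offset floor((71-50)/2) = 10 from the left intergenic bound (101)
        assert w.covI.tolist() == list(range(111, 161))

    def test_overlap_single_boundary_base(self):
        genes = [
            GeneRecord("chr1", 1, 100, "g1", "+"),
            GeneRecord("chr1", 95, 200, "g2", "+"),
        ]
        depth = np.arange(1, 301)
        (pair,) = enumerate_adjacent_pairs(genes)
        w = extract_windows(pair, track_of(depth))
        assert w.covI.tolist() == [100]  # left gene's end position

    def test_short_gene_uses_whole_gene(self):
        genes = [
            GeneRecord("chr1", 10, 20, "g1", "+"),
            GeneRecord("chr1", 60, 300, "g2", "+"),
        ]
        depth = np.arange(1, 301)
        (pair,) = enumerate_adjacent_pairs(genes)
        w = extract_windows(pair, track_of(depth))
        assert w.covA.tolist() == list(range(10, 21))

    def test_window_outside_track_names_pair(self):
        genes = genes_plus_plus()
        (pair,) = enumerate_adjacent_pairs(genes)
        with pytest.raises(IndexError, match="g1\\|g2"):
            extract_windows(pair, track_of(np.zeros(420, dtype=int)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lenA=st.integers(1, 120),
        lenB=st.integers(1, 120),
        gap=st.integers(-20, 150),
        strandA=st.sampled_from("+-"),
        strandB=st.sampled_from("+-"),
    )
    def test_window_length_invariants(self, lenA, lenB, gap, strandA, strandB):
        startA = 50
        endA = startA + lenA - 1
        startB = endA + gap + 1
        if startB < 1 or (gap < 0 and -gap >= lenB):
            return  # impossible layout: gene B would end before it starts
        endB = startB + lenB - 1
        genes = sorted(
            [
                GeneRecord("chr1", startA, endA, "gA", strandA),
                GeneRecord("chr1", startB, endB, "gB", strandB),
            ],
            key=lambda g: g.start,
        )
        (pair,) = enumerate_adjacent_pairs(genes)
        track = track_of(np.ones(max(endA, endB) + 100, dtype=int))
        w = extract_windows(pair, track)
        assert len(w.covA) == min(50, pair.geneA.length)
        assert len(w.covB) == min(50, pair.geneB.length)
        assert len(w.covI) == min(50, max(1, pair.intergenic_length))


class TestKruskalWallis:
    def test_degenerate_identical(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p == 1.0

    @pytest.mark.parametrize(
        "groups,h_exp,p_exp",
        [
            # frozen from the brute-force rank-formula oracle
            ([[1, 2, 3], [4, 5, 6]], 3.8571428571428568, 0.049534613435626),
            ([[1, 2], [3, 4], [5, 6]], 4.571428571428571, 0.101701392304226),
        ],
    )
    def test_frozen_examples(self, groups, h_exp, p_exp):
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(h_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_exact_permutation_two_groups_of_three(self):
        # all 20 assignments; only the 2 extreme splits reach the observed H
        assert kw_permutation_p([[1, 2, 3], [4, 5, 6]], n_perm=5000, seed=3) == (
            pytest.approx(0.1, abs=0.02)
        )

    @pytest.mark.parametrize("bad", [[[1, 2, 3]], [[1, 2], []]])
    def test_invalid_groups_rejected(self, bad):
        with pytest.raises(ValueError):
            kruskal_wallis(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 4))
    def test_rank_invariances(self, seed, k):
        """Within-group permutation and adding a constant never change H."""
        rng = np.random.default_rng(seed)
        groups = [
            rng.integers(0, 100, size=int(rng.integers(1, 61))).astype(float)
            for _ in range(k)
        ]
        if all(np.all(g == groups[0][0]) for g in groups):
            return
        base = kruskal_wallis(groups)
        shuffled = [rng.permutation(g) for g in groups]
        shifted = [g + 17.0 for g in groups]
        assert kruskal_wallis(shuffled).H == pytest.approx(base.H, abs=1e-12)
        assert kruskal_wallis(shifted).H == pytest.approx(base.H, abs=1e-9)


class TestComputeFeatures:
    def pair_and_track(self, depth):
        genes = genes_plus_plus()
        (pair,) = enumerate_adjacent_pairs(genes)
        return pair, track_of(depth)

    def test_constant_coverage_all_zero_features(self):
        pair, track = self.pair_and_track(np.full(1000, 9, dtype=int))
        w = extract_windows(pair, track)
        row = compute_features(pair, w, "s1")
        for name in ("AI", "BI", "AB", "AIB"):
            assert row[f"kw_{name}_H"] == 0.0
            assert row[f"kw_{name}_logp"] == 0.0

    def test_logp_floor(self):
        from operon_voter.features import P_FLOOR

        assert np.log10(P_FLOOR) == -300.0

    def test_composition_matches_standalone_kw(self):
        rng = np.random.default_rng(11)
        pair, track = self.pair_and_track(rng.integers(0, 80, size=1000))
        w = extract_windows(pair, track)
        row = compute_features(pair, w, "s1")
        direct = kruskal_wallis([w.covA, w.covI])
        assert row["kw_AI_H"] == pytest.approx(direct.H, abs=1e-12)
        assert row["kw_AI_logp"] == pytest.approx(np.log10(direct.p), abs=1e-12)
        three = kruskal_wallis([w.covA, w.covI, w.covB])
        assert row["kw_AIB_H"] == pytest.approx(three.H, abs=1e-12)
        assert row["lenA"] == 300 and row["lenB"] == 350
        assert row["strand_match"] == 1
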