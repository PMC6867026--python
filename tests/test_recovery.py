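"""Genome recovery from non-genomic medians: matching, closest-genome, brute force."""

import logging

import numpy as np
import pytest

from rankmedian import (
    brute_force_best_genomes,
    closest_genome_heuristic,
    compute_median,
    enumerate_involutions,
    fractional_rows,
    generate_triple,
    genome_to_matrix,
    invariants,
    involution_count,
    matching_heuristic,
    matching_weight,
    parse_cycles,
    rank_distance_matrices,
    score,
)


class TestMatchingHeuristic:
    def test_printed_median_recovers_printed_matching(self, printed_median, reduced_triple):
        g = matching_heuristic(printed_median)
        assert g.adjacencies == [(2, 7), (3, 4), (5, 8)]
        assert g.telomeres == [1, 6]
        assert score(g, *reduced_triple) == 10

    def test_genomic_matrix_recovered_exactly(self):
        g = parse_cycles("(1 4)(2 3)", 6)
        assert matching_heuristic(genome_to_matrix(g)).pairing == g.pairing

    @pytest.mark.parametrize("seed", range(6))
    def test_matching_weight_is_optimal_small_n(self, seed):
        """Blossom output matches exhaustive max matching weight for n <= 8."""
        t = generate_triple(4, 0.4, "dcj", seed=2000 + seed)
        m = compute_median(t.a, t.b, t.c).as_float
        got = matching_weight(m, matching_heuristic(m))
        best = max(matching_weight(m, g) for g in enumerate_involutions(t.n))
        assert got == pytest.approx(best, abs=1e-5)


class TestFractionalRows:
    def test_printed_median_rows(self, printed_median):
        assert fractional_rows(printed_median) == [1, 2, 5, 6, 7, 8]

    def test_genomic_matrix_has_no_fractional_rows(self):
        g = parse_cycles("(1 2)", 4)
        assert fractional_rows(genome_to_matrix(g)) == []

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            fractional_rows(m)

    def test_minus_one_entry_rejected(self):
        m = np.eye(3)
        m[0, 0] = -1.0
        with pytest.raises(AssertionError, match="-1"):
            fractional_rows(m)


class TestEnumerateInvolutions:
    @pytest.mark.parametrize("k, count", [(0, 1), (1, 1), (6, 76), (8, 764)])
    def test_enumeration_count(self, k, count):
        gs = list(enumerate_involutions(k))
        assert len(gs) == count
        assert len({g.pairing for g in gs}) == count  # distinct, each once

    def test_count_recurrence(self):
        # I(k) = I(k-1) + (k-1) I(k-2); the paper's search-space sizes
        assert involution_count(6) == 76
        assert involution_count(10) == 9496
        assert involution_count(12) == 140152
        for k in range(2, 15):
            assert involution_count(k) == involution_count(k - 1) + (
                k - 1
            ) * involution_count(k - 2)

    def test_deterministic_order_starts_with_identity(self):
        first = next(enumerate_involutions(4))
        assert first.telomeres == [1, 2, 3, 4]


class TestClosestGenome:
    def test_reduced_example_recovery(self, reduced_triple, printed_median):
        a, b, c = reduced_triple
        out = closest_genome_heuristic(printed_median, a, b, c)
        assert out.genome.pairing == b.pairing  # (16)(27)(34)(58) == B'
        assert out.score == 9 and out.gap == 1
        assert out.blocks == (6,)

    def test_unique_block_at_distance_one(self, printed_median):
        """Exactly one involution on 6 extremities is at rank distance 1 from M^R."""
        idx = [0, 1, 4, 5, 6, 7]
        sub = printed_median[np.ix_(idx, idx)]
        dists = [
            (rank_distance_matrices(genome_to_matrix(g), sub), g)
            for g in enumerate_involutions(6)
        ]
        dmin = min(d for d, _ in dists)
        argmin = [g for d, g in dists if d == dmin]
        assert dmin == 1
        assert len(argmin) == 1
        assert argmin[0].adjacencies == [(1, 4), (2, 5), (3, 6)]

    def test_genomic_median_returned_unchanged(self):
        g = parse_cycles("(1 2)(3 4)", 4)
        out = closest_genome_heuristic(genome_to_matrix(g), g, g, g)
        assert out.genome.pairing == g.pairing and out.gap == 0

    def test_component_too_large_raises(self, reduced_triple, printed_median):
        with pytest.raises(ValueError, match="component too large"):
            closest_genome_heuristic(printed_median, *reduced_triple, max_block=4)

    def test_agrees_with_median_outside_fractional_rows(self, reduced_triple, printed_median):
        out = closest_genome_heuristic(printed_median, *reduced_triple)
        assert out.genome.partner(3) == 4  # the binary part (34) is preserved

    @pytest.mark.parametrize("seed", [9, 15, 24, 42, 47])
    def test_block_distance_matches_unrestricted_oracle(self, seed):
        """Block-diagonal search attains the unrestricted minimum for |R| <= 8."""
        t = generate_triple(5, 0.4, "dcj", seed=seed)
        res = compute_median(t.a, t.b, t.c)
        if res.is_genomic:
            pytest.skip("median genomic for this draw; nothing to recover")
        m = res.as_float
        rows = fractional_rows(m)
        if not (0 < len(rows) <= 8):
            pytest.skip("fractional block too large for the oracle")
        idx = [i - 1 for i in rows]
        sub = m[np.ix_(idx, idx)]
        unrestricted = min(
            rank_distance_matrices(genome_to_matrix(g), sub)
            for g in enumerate_involutions(len(rows))
        )
        out = closest_genome_heuristic(m, t.a, t.b, t.c)
        block = genome_to_matrix(out.genome)[np.ix_(idx, idx)]
        assert rank_distance_matrices(block, sub) == unrestricted


class TestBruteForce:
    def test_reduced_example_three_best_genomes(self, reduced_triple):
        best, genomes = brute_force_best_genomes(*reduced_triple)
        assert best == 9
        cycles = sorted(g.to_cycles() for g in genomes)
        assert cycles == [
            "(1 6)(2 5)(3 4)(7 8)",
            "(1 6)(2 7)(3 4)(5 8)",
            "(1 6)(2 8)(3 4)(5 7)",
        ]

    def test_identical_triple(self):
        g = parse_cycles("(1 2)", 4)
        best, genomes = brute_force_best_genomes(g, g, g)
        assert best == 0 and [x.pairing for x in genomes] == [g.pairing]

    def test_large_n_guarded(self):
        g = parse_cycles("", 13)
        with pytest.raises(ValueError, match="too large"):
            brute_force_best_genomes(g, g, g)

    @pytest.mark.parametrize("seed", range(4))
    def test_best_score_never_below_beta(self, seed):
        t = generate_triple(4, 0.3, "dcj", seed=3000 + seed)
        best, _ = brute_force_best_genomes(t.a, t.b, t.c)
        beta = invariants(t.a, t.b, t.c).beta
        assert best >= beta

    def test_closest_genome_conjecture_spot_check(self, caplog):
        """Genomes attaining the minimum score also minimize the rank distance
        to M_I (spot check; counterexamples are logged, not raised)."""
        checked = failures = 0
        for seed in range(6):
            t = generate_triple(4, 0.4, "dcj", seed=4000 + seed)
            res = compute_median(t.a, t.b, t.c)
            best, genomes = brute_force_best_genomes(t.a, t.b, t.c)
            dists = {
                g.pairing: rank_distance_matrices(genome_to_matrix(g), res.as_float)
                for g in enumerate_involutions(t.n)
            }
            dmin = min(dists.values())
            checked += 1
            if any(dists[g.pairing] != dmin for g in genomes):
                failures += 1
                logging.getLogger("rankmedian").warning(
                    "conjecture counterexample at seed %d", 4000 + seed
                )
        assert checked == 6  # the sweep ran; failures are informational only
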