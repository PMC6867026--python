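"""The median M_I: reduction, the closed-form assembly, and its guarantees."""

from fractions import Fraction

import numpy as np
import pytest

from rankmedian import (
    check_conservation,
    compute_median,
    generate_triple,
    genome_to_matrix,
    invariants,
    matrix_to_genome,
    optimality_diagnostics,
    parse_cycles,
    reduce_unanimous,
    restore,
    restore_genome,
    subspace_bases,
)
from conftest import SIX_MEDIAN


class TestReduceUnanimous:
    def test_worked_example_reduction(self, worked_triple, reduced_triple):
        ar, br, cr, kept, fixed = reduce_unanimous(*worked_triple)
        assert (ar.pairing, br.pairing, cr.pairing) == tuple(
            g.pairing for g in reduced_triple
        )
        assert ar.n == 8
        assert kept == [2, 3, 4, 5, 6, 7, 8, 9]
        assert fixed == [(1,), (10, 11), (12,)]

    def test_identical_triple_reduces_to_empty(self):
        g = parse_cycles("(1 2)", 4)
        ar, br, cr, kept, fixed = reduce_unanimous(g, g, g)
        assert ar.n == 0 and kept == []
        assert fixed == [(1, 2), (3,), (4,)]

    def test_disjoint_triple_unchanged(self):
        a = parse_cycles("(1 2)", 6)
        b = parse_cycles("(3 4)", 6)
        c = parse_cycles("(5 6)", 6)
        ar, br, cr, kept, fixed = reduce_unanimous(a, b, c)
        assert fixed == [] and kept == list(range(1, 7))
        assert ar.pairing == a.pairing

    def test_restore_round_trips(self, worked_triple):
        a, b, c = worked_triple
        ar, br, cr, kept, fixed = reduce_unanimous(a, b, c)
        assert restore_genome(ar, kept, fixed).pairing == a.pairing
        m = restore(genome_to_matrix(br), kept, fixed)
        assert np.array_equal(m, genome_to_matrix(b))

    def test_restore_printed_recovery_example(self):
        # the recovered block genome (14)(25)(36) on kept labels
        # [1,2,5,6,7,8] plus the fixed adjacency (34) gives (16)(27)(34)(58)
        g = parse_cycles("(1 4)(2 5)(3 6)", 6)
        full = restore_genome(g, [1, 2, 5, 6, 7, 8], [(3, 4)])
        assert full.pairing == parse_cycles("(1 6)(2 7)(3 4)(5 8)", 8).pairing

    def test_restore_label_collision_rejected(self):
        g = parse_cycles("", 2)
        with pytest.raises(ValueError, match="collision"):
            restore_genome(g, [1, 2], [(2, 3)])


class TestComputeMedian:
    def test_printed_matrix_of_reduced_example(self, reduced_triple, printed_median):
        res = compute_median(*reduced_triple)
        assert np.allclose(res.as_float, printed_median, atol=1e-9)
        assert res.score == 8
        assert not res.is_genomic
        assert res.diagnostics == (1, 1, 1)
        assert (3, 4) in res.conserved

    def test_exact_mode_is_bit_exact(self, reduced_triple):
        res = compute_median(*reduced_triple, exact=True)
        assert res.m.dtype == object
        expected = SIX_MEDIAN.astype(int)
        for i in range(8):
            for j in range(8):
                assert res.m[i, j] == Fraction(int(expected[i, j]), 6)

    def test_full_instance_restores_printed_block(self, worked_triple, printed_median):
        res = compute_median(*worked_triple)
        assert res.score == 8
        mf = res.as_float
        kept = [1, 2, 3, 4, 5, 6, 7, 8, 9][1:]  # original labels 2..9
        idx = [i - 1 for i in [2, 3, 4, 5, 6, 7, 8, 9]]
        assert np.allclose(mf[np.ix_(idx, idx)], printed_median, atol=1e-9)
        # fixed features reinstated
        assert mf[0, 0] == 1 and mf[11, 11] == 1 and mf[9, 10] == 1

    def test_no_reduce_gives_same_matrix(self, worked_triple):
        r1 = compute_median(*worked_triple)
        r2 = compute_median(*worked_triple, reduce=False)
        assert np.allclose(r1.as_float, r2.as_float, atol=1e-8)

    def test_identical_triple_median_is_the_genome(self):
        g = parse_cycles("(1 2)(3 6)", 6, "g")
        res = compute_median(g, g, g)
        assert res.is_genomic and res.genome.pairing == g.pairing
        assert res.score == 0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_median(parse_cycles("", 2), parse_cycles("", 2), parse_cycles("", 4))


class TestGuaranteedProperties:
    @pytest.mark.parametrize("model", ["scj", "dcj"])
    @pytest.mark.parametrize("seed", range(4))
    def test_median_properties_on_simulated_triples(self, model, seed):
        t = generate_triple(12, 0.25, model, seed=1000 + seed)
        res = compute_median(t.a, t.b, t.c)
        m = res.as_float
        n = t.n
        inv = invariants(t.a, t.b, t.c)
        assert np.allclose(m, m.T, atol=1e-8)
        assert np.allclose(m.T @ m, np.eye(n), atol=1e-8)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-8)
        assert res.score == inv.beta
        conserved, ok, bad = check_conservation(t.a, t.b, t.c, m)
        assert ok, f"violated feature {bad}"

    def test_exact_and_float_agree_on_simulated_triple(self):
        t = generate_triple(6, 0.3, "dcj", seed=77)
        rf = compute_median(t.a, t.b, t.c)
        rx = compute_median(t.a, t.b, t.c, exact=True)
        assert np.allclose(rf.as_float, rx.as_float, atol=1e-9)

    def test_diagnostics_equal_delta(self, reduced_triple):
        a, b, c = reduced_triple
        assert optimality_diagnostics(a, b, c) == (1, 1, 1)
        g = parse_cycles("(1 2)", 4)
        assert optimality_diagnostics(g, g, g) == (0, 0, 0)


class TestConservation:
    def test_adjacency_34_present_in_printed_median(self, reduced_triple, printed_median):
        conserved, ok, bad = check_conservation(*reduced_triple, printed_median)
        assert ok and bad is None
        assert (3, 4) in conserved

    def test_violation_detected(self, reduced_triple):
        m = np.eye(8)  # identity conserves no shared adjacency
        conserved, ok, bad = check_conservation(*reduced_triple, m)
        assert not ok and bad == (3, 4)

    def test_identical_triple_everything_conserved(self):
        g = parse_cycles("(1 2)", 4)
        conserved, ok, _ = check_conservation(g, g, g, genome_to_matrix(g))
        assert ok
        assert conserved == [(1, 2), (3,), (4,)]
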