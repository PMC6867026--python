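"""Turning a non-genomic median matrix back into a genome.

Two heuristics, mirroring how the median is used in practice:

* **Maximum-weight matching.**  Build a weighted graph on the extremities with
  edge weight ``2|M_ij|`` and telomere (self-loop) weight ``|M_ii|``; a
  maximum-weight matching, computed by the blossom algorithm, is read off as a
  genome.  This is the convex (Frobenius) relaxation of the rank problem.
* **Closest genome by rank distance.**  A symmetric orthogonal median is
  binary outside the set R of rows containing a fractional entry.  The
  submatrix ``M^R`` decomposes into small connected blocks; within each block
  the genome minimizing the rank distance to the block is found exhaustively
  over all involutions, and the blocks are reassembled with the binary part
  of the median.  Exhaustive search is feasible for blocks of up to ~10
  extremities (9496 involutions).

Self-loops are not supported by the blossom matching implementation, so each
vertex ``i`` gets a twin vertex joined only to ``i`` carrying the telomere
weight; matching ``i`` to its twin encodes the telomere, which is
weight-equivalent to the self-loop formulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

from .genomes import DEFAULT_ENTRY_TOL, Genome, genome_to_matrix, matrix_to_genome
from .rank_algebra import (
    DEFAULT_RANK_TOL,
    invariants,
    rank_distance_genomes,
    rank_distance_matrices,
    score,
)


@dataclass(frozen=True)
class RecoveryOutcome:
    """A genome recovered from a median matrix, with its score and gap to beta."""

    genome: Genome
    score: int
    gap: int
    method: str
    blocks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise AssertionError("recovered genome scores below the lower bound")


def matching_heuristic(
    m: np.ndarray, eps: float = DEFAULT_ENTRY_TOL, name: str | None = None
) -> Genome:
    """Genome given by a maximum-weight matching on the entries of ``m``.

    Edges ``(i, j)`` carry weight ``2|M_ij|`` and telomere gadgets ``|M_ii|``;
    weights not exceeding ``eps`` are omitted as numerically insignificant.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    h = nx.Graph()
    h.add_nodes_from(range(1, n + 1))
    for i in range(n):
        w = abs(m[i, i])
        if w > eps:
            h.add_edge(i + 1, ("t", i + 1), weight=w)
        for j in range(i + 1, n):
            w = 2 * abs(m[i, j])
            if w > eps:
                h.add_edge(i + 1, j + 1, weight=w)
    matching = nx.max_weight_matching(h)
    pairs = []
    for u, v in matching:
        if isinstance(u, tuple) or isinstance(v, tuple):
            continue  # vertex matched to its telomere gadget
        pairs.append((u, v))
    return Genome.from_pairs(n, pairs, name or "matching")


def matching_weight(m: np.ndarray, g: Genome) -> float:
    """Weight of the matching encoded by ``g`` in the graph of ``m``."""
    m = np.asarray(m, dtype=float)
    w = sum(2 * abs(m[i - 1, j - 1]) for i, j in g.adjacencies)
    w += sum(abs(m[i - 1, i - 1]) for i in g.telomeres)
    return float(w)


def fractional_rows(m: np.ndarray, tol: float = DEFAULT_ENTRY_TOL) -> list[int]:
    """1-based indices of rows of ``m`` containing a non-integer entry.

    The complement of the result indexes a binary submatrix (asserted); a
    symmetric orthogonal median with unit row sums cannot contain an entry
    near -1, which is also checked.
    """
    m = np.asarray(m, dtype=float)
    if np.max(np.abs(m - m.T), initial=0.0) > tol:
        raise ValueError("matrix is not symmetric")
    if np.any(np.abs(m + 1) <= tol):
        raise AssertionError("median contains a -1 entry; input is not a valid median")
    frac = np.abs(m - np.round(m)) > tol
    rows = sorted(int(i) + 1 for i in np.flatnonzero(frac.any(axis=1)))
    comp = [i - 1 for i in range(1, m.shape[0] + 1) if i not in rows]
    sub = m[np.ix_(comp, comp)]
    if sub.size and np.max(np.abs(sub - np.round(sub))) > tol:
        raise AssertionError("binary complement check failed")
    return rows


def involution_count(k: int) -> int:
    """Number of involutions on k elements: I(k) = I(k-1) + (k-1) I(k-2)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    prev2, prev1 = 1, 1  # I(0), I(1)
    if k <= 1:
        return 1
    for j in range(2, k + 1):
        prev2, prev1 = prev1, prev1 + (j - 1) * prev2
    return prev1


def _involution_pairs(avail: tuple[int, ...]) -> Iterator[tuple[tuple[int, int], ...]]:
    if not avail:
        yield ()
        return
    first, rest = avail[0], avail[1:]
    for sub in _involution_pairs(rest):  # first is a telomere
        yield sub
    for idx, j in enumerate(rest):  # first paired with j
        remaining = rest[:idx] + rest[idx + 1 :]
        for sub in _involution_pairs(remaining):
            yield ((first, j),) + sub


def enumerate_involutions(k: int) -> Iterator[Genome]:
    """Yield every genome (involution) on {1..k} once, in deterministic order.

    The order is: the smallest unplaced extremity is first a telomere, then
    paired with each larger partner in increasing order.  The total count
    satisfies the telephone-number recurrence I(k) = I(k-1) + (k-1) I(k-2).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    for pairs in _involution_pairs(tuple(range(1, k + 1))):
        yield Genome.from_pairs(k, list(pairs))


def closest_genome_heuristic(
    m: np.ndarray,
    a: Genome,
    b: Genome,
    c: Genome,
    max_block: int = 10,
    tol: float = DEFAULT_ENTRY_TOL,
    rank_tol: float = DEFAULT_RANK_TOL,
    max_combinations: int = 4096,
) -> RecoveryOutcome:
    """Replace the fractional block of a median by its closest genome.

    Restricts the search to genomes block-diagonal over the connected
    components of the nonzero pattern of ``M^R``; each block is solved
    exhaustively over all involutions of its size.  Ties in block rank
    distance are broken by the score of the assembled genome against
    ``(a, b, c)``, then by enumeration order.

    Raises ``ValueError`` if a component exceeds ``max_block`` extremities
    (callers may fall back to the matching heuristic).
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    rows = fractional_rows(m, tol)
    if not rows:
        g = matrix_to_genome(m, tol, name="closest")
        s = score(g, a, b, c)
        beta = invariants(a, b, c).beta
        return RecoveryOutcome(g, s, s - beta, "closest", ())

    ridx = [i - 1 for i in rows]
    sub = m[np.ix_(ridx, ridx)]
    h = nx.Graph()
    h.add_nodes_from(range(len(rows)))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if abs(sub[i, j]) > tol:
                h.add_edge(i, j)
    comps = [sorted(cc) for cc in nx.connected_components(h)]
    comps.sort(key=lambda cc: cc[0])
    sizes = tuple(len(cc) for cc in comps)
    for cc in comps:
        if len(cc) > max_block:
            raise ValueError(
                f"component too large for exhaustive search: size {len(cc)} > {max_block}"
            )

    # Per component, all involutions minimizing rank distance to the block.
    candidates: list[list[Genome]] = []
    for cc in comps:
        block = sub[np.ix_(cc, cc)]
        best_d: int | None = None
        best: list[Genome] = []
        for g in enumerate_involutions(len(cc)):
            d = rank_distance_matrices(genome_to_matrix(g), block, rank_tol)
            if best_d is None or d < best_d:
                best_d, best = d, [g]
            elif d == best_d:
                best.append(g)
        candidates.append(best)

    # Binary scaffold outside R
    base_pairs = []
    rowset = set(rows)
    rounded = np.round(m)
    for i in range(1, n + 1):
        if i in rowset:
            continue
        j = int(np.argmax(rounded[i - 1])) + 1
        if j >= i:
            base_pairs.append((i, j))

    def assemble(choice: tuple[Genome, ...]) -> Genome:
        pairs = list(base_pairs)
        for cc, g in zip(comps, choice):
            local_to_global = [rows[i] for i in cc]
            pairs.extend(
                (local_to_global[i - 1], local_to_global[j - 1])
                for i, j in g.adjacencies
            )
        return Genome.from_pairs(n, pairs, "closest")

    n_comb = 1
    for cands in candidates:
        n_comb *= len(cands)
    beta = invariants(a, b, c).beta
    best_g = None
    best_s = None
    pool = (
        itertools.product(*candidates)
        if n_comb <= max_combinations
        else iter([tuple(cands[0] for cands in candidates)])
    )
    for choice in pool:
        g = assemble(choice)
        s = score(g, a, b, c)
        if best_s is None or s < best_s:
            best_g, best_s = g, s
    assert best_g is not None and best_s is not None
    return RecoveryOutcome(best_g, best_s, best_s - beta, "closest", sizes)


def brute_force_best_genomes(
    a: Genome, b: Genome, c: Genome, max_n: int = 12
) -> tuple[int, list[Genome]]:
    """Exact argmin of the median score over every involution on {1..n}.

    Only feasible for small instances (guarded at ``n <= max_n``; n = 12
    already means over 140,000 candidates).
    """
    n = a.n
    if n > max_n:
        raise ValueError(f"n={n} too large for brute force (limit {max_n})")
    best_s: int | None = None
    best: list[Genome] = []
    for g in enumerate_involutions(n):
        s = sum(rank_distance_genomes(g, x) for x in (a, b, c))
        if best_s is None or s < best_s:
            best_s, best = s, [g]
        elif s == best_s:
            best.append(g)
    assert best_s is not None
    return best_s, best
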