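"""Rank distance, the three median invariants, and the median score.

The rank distance between two matrices is ``d(A, B) = rank(A - B)``.  For
permutation matrices this coincides with the Cayley distance: ``n`` minus the
number of cycles (fixed points included) of ``A^{-1}B``.  Genomes are
involutions, so ``A^{-1} = A`` and genome–genome distances are computed by
exact integer cycle counting; matrix-valued candidates fall back to an SVD
numerical rank.

Three quantities govern the median-of-three problem for genomes A, B, C:

* ``beta = (d(A,B) + d(B,C) + d(C,A)) / 2`` — a lower bound on the median
  score, integral for orthogonal inputs;
* ``alpha = dim V1`` — the dimension of the triple-agreement subspace
  ``{x : Ax = Bx = Cx}``, equal to the number of weakly connected components
  of the union of the graphs of the products AB and BC;
* ``delta = alpha + beta - n`` — the *deficiency*, nonnegative for genomic
  inputs; ``delta = 0`` instances have a unique, easily found median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import Genome

#: Relative threshold on singular values for numerical matrix rank.
DEFAULT_RANK_TOL = 1e-9


def compose(a: Genome, b: Genome) -> tuple[int, ...]:
    """Product permutation ``x -> a(b(x))`` as a 1-based image tuple."""
    if a.n != b.n:
        raise ValueError(f"size mismatch: {a.n} vs {b.n}")
    return tuple(a.pairing[b.pairing[i] - 1] for i in range(a.n))


def cycle_count(p: tuple[int, ...] | list[int]) -> int:
    """Number of cycles of a permutation, fixed points included.

    ``p`` is a 1-based image map: ``p[i-1]`` is the image of ``i``.
    """
    n = len(p)
    if sorted(p) != list(range(1, n + 1)):
        raise ValueError("not a bijection on 1..n")
    seen = [False] * n
    count = 0
    for start in range(n):
        if seen[start]:
            continue
        count += 1
        i = start
        while not seen[i]:
            seen[i] = True
            i = p[i] - 1
    return count


def permutation_cycles(p: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Cycles of a permutation (fixed points included), smallest element first.

    Cycles are listed in increasing order of their minimum element; each cycle
    starts at its minimum and follows the permutation.
    """
    n = len(p)
    seen = [False] * n
    cycles = []
    for start in range(n):
        if seen[start]:
            continue
        cyc = []
        i = start
        while not seen[i]:
            seen[i] = True
            cyc.append(i + 1)
            i = p[i] - 1
        cycles.append(tuple(cyc))
    return cycles


def rank_distance_genomes(a: Genome, b: Genome) -> int:
    """Rank distance between two genomes by exact cycle counting."""
    return a.n - cycle_count(compose(a, b))


def rank_distance_matrices(
    x: np.ndarray, y: np.ndarray, tol: float = DEFAULT_RANK_TOL
) -> int:
    """Numerical rank of ``x - y``: singular values above ``tol * max(1, s_max)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x - y
    if d.size == 0 or not np.any(d):
        return 0
    s = np.linalg.svd(d, compute_uv=False)
    return int(np.sum(s > tol * max(1.0, float(s[0]))))


def triple_agreement_dimension(a: Genome, b: Genome, c: Genome) -> int:
    """``alpha``: weakly connected components of the union of the AB and BC graphs.

    A vector satisfies ``Ax = Bx = Cx`` iff it is constant on every cycle of
    AB and of BC, i.e. constant on each component of the union graph.
    """
    n = a.n
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    ab = compose(a, b)
    bc = compose(b, c)
    for i in range(n):
        union(i, ab[i] - 1)
        union(i, bc[i] - 1)
    return len({find(i) for i in range(n)})


def triple_agreement_components(a: Genome, b: Genome, c: Genome) -> list[tuple[int, ...]]:
    """Components of the union graph of AB and BC, each sorted, ordered by minimum."""
    n = a.n
    ab = compose(a, b)
    bc = compose(b, c)
    comp_of = [-1] * n
    comps: list[list[int]] = []
    for start in range(n):
        if comp_of[start] >= 0:
            continue
        cid = len(comps)
        stack = [start]
        comp_of[start] = cid
        members = []
        while stack:
            i = stack.pop()
            members.append(i + 1)
            for j in (ab[i] - 1, bc[i] - 1):
                if comp_of[j] < 0:
                    comp_of[j] = cid
                    stack.append(j)
        comps.append(sorted(members))
    return [tuple(c) for c in comps]


@dataclass(frozen=True)
class Invariants:
    """The three median invariants ``alpha``, ``beta``, ``delta`` of a triple."""

    alpha: int
    beta: int
    delta: int
    d_ab: int
    d_bc: int
    d_ca: int


def invariants(a: Genome, b: Genome, c: Genome) -> Invariants:
    """Compute ``alpha``, ``beta``, ``delta`` and pairwise distances for a triple."""
    if not (a.n == b.n == c.n):
        raise ValueError(f"size mismatch: {a.n}, {b.n}, {c.n}")
    d_ab = rank_distance_genomes(a, b)
    d_bc = rank_distance_genomes(b, c)
    d_ca = rank_distance_genomes(c, a)
    total = d_ab + d_bc + d_ca
    if total % 2:
        raise AssertionError(
            "pairwise distances have odd sum; beta is integral for genomic inputs"
        )
    beta = total // 2
    alpha = triple_agreement_dimension(a, b, c)
    delta = alpha + beta - a.n
    if delta < 0:
        raise AssertionError(f"negative deficiency delta={delta} for genomic inputs")
    return Invariants(alpha, beta, delta, d_ab, d_bc, d_ca)


def score(
    m: np.ndarray | Genome,
    a: Genome,
    b: Genome,
    c: Genome,
    tol: float = DEFAULT_RANK_TOL,
) -> int:
    """Median score ``d(A,M) + d(B,M) + d(C,M)`` of a candidate ``m``.

    ``m`` may be a genome (exact cycle counting) or an arbitrary real matrix
    (SVD rank).  The result is checked against the lower bound ``beta``.
    """
    if isinstance(m, Genome):
        s = (
            rank_distance_genomes(m, a)
            + rank_distance_genomes(m, b)
            + rank_distance_genomes(m, c)
        )
    else:
        from .genomes import genome_to_matrix

        m = np.asarray(m, dtype=float)
        if m.shape != (a.n, a.n):
            raise ValueError(f"candidate shape {m.shape} does not match n={a.n}")
        s = sum(
            rank_distance_matrices(m, genome_to_matrix(g), tol) for g in (a, b, c)
        )
    beta = invariants(a, b, c).beta
    if s < beta:
        raise AssertionError(f"score {s} below the lower bound beta={beta}")
    return s
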