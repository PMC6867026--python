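"""The five-subspace decomposition induced by three genomes.

Three genomic matrices A, B, C split R^n into a direct sum of five subspaces:
the triple-agreement subspace V1 (``Ax = Bx = Cx``), three pairwise-agreement
subspaces V2 (``Ax = Bx``), V3 (``Bx = Cx``), V4 (``Cx = Ax``), each taken
orthogonal to V1, and the disagreement subspace V5 of dimension ``2*delta``.
Their dimensions are, with ``c()`` counting permutation cycles::

    dim V1 = alpha       dim V2 = c(AB) - alpha     dim V3 = c(BC) - alpha
    dim V4 = c(CA) - alpha                          dim V5 = 2 * delta

This module constructs the *standard bases* B1..B4.  B1 holds the indicator
vectors of the weakly connected components of the union of the AB and BC
graphs; B2..B4 hold, for each cycle of the relevant product permutation, the
cycle indicator minus its orthogonal projection onto span(B1).  After that
subtraction the vectors belonging to one triple-agreement component sum to
zero, so exactly one per component is redundant; we drop, per component, the
longest cycle (ties: larger minimum element), which keeps the sparsest
vectors, and order the kept vectors by cycle minimum.  The basis of V5 is
never needed: the median formula bypasses it.

Vectors are intentionally not normalized; the median formula is invariant to
column scaling because it uses ``(B14^T B14)^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genomes import Genome
from .rank_algebra import (
    compose,
    invariants,
    permutation_cycles,
    triple_agreement_components,
)

#: Euclidean-norm threshold below which a constructed basis vector counts as zero.
ZERO_VECTOR_TOL = 1e-9


@dataclass(frozen=True)
class SubspaceBases:
    """Ordered bases of V1..V4 plus the five dimensions.

    ``b1``..``b4`` are ``(n, dim Vj)`` float arrays (zero columns dropped);
    ``dims`` is ``(dim V1, ..., dim V5)`` and sums to ``n``.
    """

    b1: np.ndarray
    b2: np.ndarray
    b3: np.ndarray
    b4: np.ndarray
    dims: tuple[int, int, int, int, int]
    n: int

    @property
    def b14(self) -> np.ndarray:
        """Column-wise concatenation [B1, B2, B3, B4], an ``(n, n - 2*delta)`` array."""
        return np.hstack([self.b1, self.b2, self.b3, self.b4])


def triple_agreement_basis(a: Genome, b: Genome, c: Genome) -> list[np.ndarray]:
    """Indicator vectors of the union-graph components: the standard basis of V1."""
    if not (a.n == b.n == c.n):
        raise ValueError(f"size mismatch: {a.n}, {b.n}, {c.n}")
    vecs = []
    for comp in triple_agreement_components(a, b, c):
        v = np.zeros(a.n)
        v[[i - 1 for i in comp]] = 1.0
        vecs.append(v)
    return vecs


def _cycle_vectors_exact(
    p: tuple[int, ...], components: list[tuple[int, ...]]
) -> list[tuple[tuple[int, ...], int, list[Fraction]]]:
    """Per kept cycle of ``p``: (cycle, component index, exact basis vector).

    The vector is the cycle indicator minus its projection onto the indicator
    of the containing triple-agreement component, with Fraction entries.
    """
    n = len(p)
    comp_of = {}
    for k, comp in enumerate(components):
        for i in comp:
            comp_of[i] = k
    by_comp: dict[int, list[tuple[int, ...]]] = {}
    for cyc in permutation_cycles(p):
        by_comp.setdefault(comp_of[cyc[0]], []).append(cyc)
    kept: list[tuple[tuple[int, ...], int]] = []
    for k, cycs in by_comp.items():
        # one linear dependency per component: drop the longest cycle,
        # breaking ties toward the larger minimum element
        drop = max(cycs, key=lambda cyc: (len(cyc), cyc[0]))
        kept.extend((cyc, k) for cyc in cycs if cyc is not drop)
    kept.sort(key=lambda t: t[0][0])
    out = []
    for cyc, k in kept:
        comp = components[k]
        coeff = Fraction(len(cyc), len(comp))
        vec = [Fraction(0)] * n
        for i in comp:
            vec[i - 1] -= coeff
        for i in cyc:
            vec[i - 1] += 1
        out.append((cyc, k, vec))
    return out


def pairwise_basis(
    p: tuple[int, ...], b1: list[np.ndarray] | np.ndarray
) -> list[np.ndarray]:
    """Standard basis of a pairwise-agreement subspace from the product ``p``.

    ``p`` is the product permutation of the two genomes that agree on the
    subspace (AB for V2, BC for V3, CA for V4); ``b1`` is the standard basis
    of V1.  Returns ``c(p) - alpha`` vectors, each orthogonal to span(b1).
    """
    if isinstance(b1, np.ndarray):
        b1 = [b1[:, j] for j in range(b1.shape[1])]
    components = [
        tuple(int(i) + 1 for i in np.flatnonzero(v)) for v in b1
    ]
    vecs = [
        np.array([float(x) for x in vec])
        for _, _, vec in _cycle_vectors_exact(p, components)
    ]
    return [v for v in vecs if np.linalg.norm(v) >= ZERO_VECTOR_TOL]


def subspace_dims(a: Genome, b: Genome, c: Genome) -> tuple[int, int, int, int, int]:
    """The five dimensions ``(alpha, c(AB)-alpha, c(BC)-alpha, c(CA)-alpha, 2*delta)``."""
    inv = invariants(a, b, c)
    n = a.n
    d2 = (n - inv.d_ab) - inv.alpha
    d3 = (n - inv.d_bc) - inv.alpha
    d4 = (n - inv.d_ca) - inv.alpha
    d5 = 2 * inv.delta
    dims = (inv.alpha, d2, d3, d4, d5)
    if sum(dims) != n:
        raise AssertionError(f"subspace dimensions {dims} do not sum to n={n}")
    return dims


def _stack(vecs: list, n: int, exact: bool) -> np.ndarray:
    if exact:
        arr = np.empty((n, len(vecs)), dtype=object)
        for j, v in enumerate(vecs):
            for i in range(n):
                arr[i, j] = v[i]
        return arr
    if not vecs:
        return np.zeros((n, 0))
    return np.column_stack(vecs)


def subspace_bases(a: Genome, b: Genome, c: Genome, exact: bool = False) -> SubspaceBases:
    """Build the standard bases B1..B4 and the five dimensions.

    With ``exact=True`` the basis arrays carry ``fractions.Fraction`` entries
    (dtype=object) for use by the exact-rational median path.
    """
    n = a.n
    dims = subspace_dims(a, b, c)
    components = triple_agreement_components(a, b, c)
    if exact:
        b1_vecs: list = [
            [Fraction(1) if (i + 1) in set(comp) else Fraction(0) for i in range(n)]
            for comp in components
        ]
    else:
        b1_vecs = triple_agreement_basis(a, b, c)

    prods = [compose(a, b), compose(b, c), compose(c, a)]
    pair_vecs = []
    for p in prods:
        exactvecs = [vec for _, _, vec in _cycle_vectors_exact(p, components)]
        if exact:
            pair_vecs.append(exactvecs)
        else:
            pair_vecs.append([np.array([float(x) for x in v]) for v in exactvecs])

    bases = SubspaceBases(
        b1=_stack(b1_vecs, n, exact),
        b2=_stack(pair_vecs[0], n, exact),
        b3=_stack(pair_vecs[1], n, exact),
        b4=_stack(pair_vecs[2], n, exact),
        dims=dims,
        n=n,
    )
    for mat, d in zip((bases.b1, bases.b2, bases.b3, bases.b4), dims[:4]):
        if mat.shape[1] != d:
            raise AssertionError(
                f"basis has {mat.shape[1]} columns, expected dimension {d}"
            )
    return bases
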