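"""The generalized rank-distance median M_I of three genomes.

The median candidate acts as the majority input on the four agreement
subspaces and as the identity on the disagreement subspace V5:

    M_I v = Av on V1 and V2,  Bv on V3,  Cv on V4,  v on V5.

With the standard bases stacked as ``B14 = [B1, B2, B3, B4]`` this linear map
is assembled in closed form, without ever constructing a basis of V5::

    M_I = I + ([A B1, A B2, B B3, C B4] - B14) (B14^T B14)^{-1} B14^T

M_I is always symmetric, orthogonal, has unit row sums, contains every
adjacency and telomere shared by at least two of the inputs, and attains the
score lower bound ``beta`` exactly — all of which are asserted at run time.
It need not be binary; when it is not, the recovery heuristics turn it back
into a genome.

Instances are first reduced by removing adjacencies and telomeres common to
all three inputs (they can be assumed present in a median), renumbering the
remaining extremities; results are restored to the original labels afterward.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.linalg

from .genomes import (
    DEFAULT_ENTRY_TOL,
    Genome,
    NotGenomicError,
    genome_to_matrix,
    matrix_to_genome,
)
from .rank_algebra import DEFAULT_RANK_TOL, Invariants, invariants, score
from .subspaces import SubspaceBases, subspace_bases

#: A feature is a telomere ``(i,)`` or an adjacency ``(i, j)`` with i < j.
Feature = tuple[int, ...]


@dataclass(frozen=True)
class MedianResult:
    """Median matrix M_I with its score, invariants and diagnostics."""

    m: np.ndarray
    invariants_abc: Invariants
    score: int
    is_genomic: bool
    genome: Genome | None
    conserved: list[Feature]
    diagnostics: tuple[int, int, int]
    bases: SubspaceBases
    exact: bool = False

    @property
    def as_float(self) -> np.ndarray:
        """M_I as a float array (exact-mode results carry Fraction entries)."""
        return np.asarray(self.m, dtype=float)


def genome_features(g: Genome) -> set[Feature]:
    """Adjacencies and telomeres of a genome as a set of feature tuples."""
    feats: set[Feature] = {(i,) for i in g.telomeres}
    feats.update(g.adjacencies)
    return feats


# ---------------------------------------------------------------------------
# Reduction by unanimous features and restoration
# ---------------------------------------------------------------------------

def reduce_unanimous(
    a: Genome, b: Genome, c: Genome
) -> tuple[Genome, Genome, Genome, list[int], list[Feature]]:
    """Strip features common to all three genomes and renumber to 1..n'.

    Returns ``(a', b', c', kept, fixed)`` where ``kept`` lists the original
    labels of the surviving extremities in increasing order (``kept[i-1]`` is
    the original label of new extremity ``i``) and ``fixed`` the removed
    features in original labels.  A median of the reduced instance extended by
    the fixed features is a median of the original instance.
    """
    if not (a.n == b.n == c.n):
        raise ValueError(f"size mismatch: {a.n}, {b.n}, {c.n}")
    fixed = sorted(genome_features(a) & genome_features(b) & genome_features(c))
    removed = {i for f in fixed for i in f}
    kept = [i for i in range(1, a.n + 1) if i not in removed]
    new_of = {orig: k + 1 for k, orig in enumerate(kept)}
    reduced = []
    for g in (a, b, c):
        pairs = [
            (new_of[i], new_of[j]) for i, j in g.adjacencies if i in new_of
        ]
        reduced.append(
            Genome.from_pairs(len(kept), pairs, f"{g.name}'" if g.name else None)
        )
    return reduced[0], reduced[1], reduced[2], kept, fixed


def restore_genome(g: Genome, kept: list[int], fixed: list[Feature]) -> Genome:
    """Embed a genome on reduced labels back into the original labelling."""
    n = len(kept) + sum(len(f) for f in fixed)
    labels = {i for f in fixed for i in f} | set(kept)
    if len(labels) != n or max(labels, default=0) > n:
        raise ValueError("label collision between kept extremities and fixed features")
    if g.n != len(kept):
        raise ValueError(f"genome has n={g.n}, expected {len(kept)}")
    pairs = [(kept[i - 1], kept[j - 1]) for i, j in g.adjacencies]
    pairs += [f for f in fixed if len(f) == 2]
    return Genome.from_pairs(n, pairs, g.name)


def restore_matrix(
    m: np.ndarray, kept: list[int], fixed: list[Feature]
) -> np.ndarray:
    """Embed a reduced median matrix back, reinstating the fixed features."""
    n = len(kept) + sum(len(f) for f in fixed)
    exact = m.dtype == object
    full = (
        np.full((n, n), Fraction(0), dtype=object) if exact else np.zeros((n, n))
    )
    one = Fraction(1) if exact else 1.0
    idx = np.array([i - 1 for i in kept], dtype=int)
    full[np.ix_(idx, idx)] = m
    for f in fixed:
        if len(f) == 1:
            full[f[0] - 1, f[0] - 1] = one
        else:
            i, j = f
            full[i - 1, j - 1] = one
            full[j - 1, i - 1] = one
    return full


def restore(obj, kept: list[int], fixed: list[Feature]):
    """Restore a reduced genome or matrix to the original instance labels."""
    if isinstance(obj, Genome):
        return restore_genome(obj, kept, fixed)
    return restore_matrix(np.asarray(obj), kept, fixed)


# ---------------------------------------------------------------------------
# Assembly of M_I
# ---------------------------------------------------------------------------

def _median_matrix_float(a: Genome, b: Genome, c: Genome, bases: SubspaceBases) -> np.ndarray:
    n = a.n
    ma, mb, mc = (genome_to_matrix(g) for g in (a, b, c))
    b14 = bases.b14
    if b14.shape[1] == 0:  # n == 0 or pathological; M_I is the identity
        return np.eye(n)
    target = np.hstack([ma @ bases.b1, ma @ bases.b2, mb @ bases.b3, mc @ bases.b4])
    gram = b14.T @ b14
    # (B14^T B14)^{-1} B14^T via a solve; the Gram matrix is PD by construction
    coeff = scipy.linalg.solve(gram, b14.T, assume_a="pos")
    return np.eye(n) + (target - b14) @ coeff


def _median_matrix_exact(a: Genome, b: Genome, c: Genome, bases: SubspaceBases) -> np.ndarray:
    import sympy

    n = a.n
    b14 = sympy.Matrix(
        [[sympy.Rational(x.numerator, x.denominator) for x in row] for row in bases.b14]
    ) if n else sympy.zeros(0, 0)
    if n == 0 or b14.cols == 0:
        return np.full((n, n), Fraction(0), dtype=object)

    def apply(g: Genome, block) -> "sympy.Matrix":
        rows = [block.row(g.pairing[i] - 1) for i in range(n)]
        return sympy.Matrix.vstack(*rows) if rows else block

    cols = []
    for g, mat in ((a, bases.b1), (a, bases.b2), (b, bases.b3), (c, bases.b4)):
        block = sympy.Matrix(
            [[sympy.Rational(x.numerator, x.denominator) for x in row] for row in mat]
        ) if mat.shape[1] else sympy.zeros(n, 0)
        cols.append(apply(g, block) if block.cols else block)
    target = sympy.Matrix.hstack(*cols)
    gram = b14.T * b14
    coeff = gram.LUsolve(b14.T)
    mi = sympy.eye(n) + (target - b14) * coeff
    out = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            r = sympy.Rational(mi[i, j])
            out[i, j] = Fraction(int(r.p), int(r.q))
    return out


def optimality_diagnostics(
    a: Genome,
    b: Genome,
    c: Genome,
    bases: SubspaceBases | None = None,
    tol: float = DEFAULT_RANK_TOL,
) -> tuple[int, int, int]:
    """Dimensions of the optimality-certificate subspaces V_I^A, V_I^B, V_I^C.

    ``V_I^A = {x + y : x in V3, y in V5, A(x+y) = Bx + y}`` and cyclic
    analogues; the median attains the lower bound iff all three dimensions
    equal ``delta``.  Each is computed as the nullity of the corresponding
    linear map on V3 (+) V5, with V5 realized as the orthogonal complement of
    span(B14).
    """
    if bases is None:
        bases = subspace_bases(a, b, c)
    n = a.n
    ma, mb, mc = (genome_to_matrix(g) for g in (a, b, c))
    b14 = np.asarray(bases.b14, dtype=float)
    w5 = scipy.linalg.null_space(b14.T) if b14.shape[1] else np.eye(n)
    eye = np.eye(n)
    dims = []
    for (m1, m2, bx) in (
        (ma, mb, np.asarray(bases.b3, dtype=float)),
        (mb, mc, np.asarray(bases.b4, dtype=float)),
        (mc, ma, np.asarray(bases.b2, dtype=float)),
    ):
        # columns: the map (x, y) -> M1(x+y) - (M2 x + y) on V_pair (+) V5
        cols = np.hstack([(m1 - m2) @ bx, (m1 - eye) @ w5])
        k = cols.shape[1]
        if k == 0:
            dims.append(0)
            continue
        s = np.linalg.svd(cols, compute_uv=False)
        rank = int(np.sum(s > tol * max(1.0, float(s[0]))))
        dims.append(k - rank)
    return tuple(dims)  # type: ignore[return-value]


def check_conservation(
    a: Genome,
    b: Genome,
    c: Genome,
    m: np.ndarray,
    tol: float = DEFAULT_ENTRY_TOL,
) -> tuple[list[Feature], bool, Feature | None]:
    """Verify that every feature shared by >= 2 inputs is present in ``m``.

    A feature is *present* when its 1-entries are exact and the rest of the
    involved rows and columns vanish.  Returns the sorted feature list, a
    success flag, and the first violated feature (None when all hold).
    """
    fa, fb, fc = (genome_features(g) for g in (a, b, c))
    conserved = sorted((fa & fb) | (fb & fc) | (fc & fa))
    m = np.asarray(m, dtype=float)

    def present(f: Feature) -> bool:
        i = f[0] - 1
        j = f[-1] - 1
        if abs(m[i, j] - 1) > tol or abs(m[j, i] - 1) > tol:
            return False
        row_i = np.delete(m[i], j)
        col_i = np.delete(m[:, i], j)
        row_j = np.delete(m[j], i)
        col_j = np.delete(m[:, j], i)
        return all(
            np.all(np.abs(v) <= tol) for v in (row_i, col_i, row_j, col_j)
        )

    for f in conserved:
        if not present(f):
            return conserved, False, f
    return conserved, True, None


def compute_median(
    a: Genome,
    b: Genome,
    c: Genome,
    exact: bool = False,
    reduce: bool = True,
    entry_tol: float = DEFAULT_ENTRY_TOL,
    rank_tol: float = DEFAULT_RANK_TOL,
) -> MedianResult:
    """Compute M_I for three genomes and verify its guaranteed properties.

    The instance is first reduced by unanimously shared features (disable with
    ``reduce=False``); the returned matrix is always on the original ``n``
    extremities.  With ``exact=True`` all arithmetic is rational and the
    result carries ``Fraction`` entries.

    Raises ``AssertionError`` if any guaranteed property (symmetry,
    orthogonality, unit row sums, score == beta, 2-of-3 conservation,
    diagnostics == delta) fails — which would indicate a bug, not bad input.
    """
    inv = invariants(a, b, c)
    n = a.n

    if reduce:
        ar, br, cr, kept, fixed = reduce_unanimous(a, b, c)
    else:
        ar, br, cr, kept, fixed = a, b, c, list(range(1, n + 1)), []

    if ar.n == 0:
        m_red = np.full((0, 0), Fraction(0), dtype=object) if exact else np.zeros((0, 0))
        bases = subspace_bases(a, b, c, exact=False)
    else:
        bases = subspace_bases(ar, br, cr, exact=exact)
        if exact:
            m_red = _median_matrix_exact(ar, br, cr, bases)
        else:
            m_red = _median_matrix_float(ar, br, cr, bases)
        b14f = np.asarray(bases.b14, dtype=float)
        mf = np.asarray(m_red, dtype=float)
        maf, mbf, mcf = (genome_to_matrix(g) for g in (ar, br, cr))
        tgt = np.hstack(
            [
                maf @ np.asarray(bases.b1, float),
                maf @ np.asarray(bases.b2, float),
                mbf @ np.asarray(bases.b3, float),
                mcf @ np.asarray(bases.b4, float),
            ]
        )
        if not np.allclose(mf @ b14f, tgt, atol=1e-8):
            raise AssertionError("M_I does not act as the majority on B14")

    m_full = restore(m_red, kept, fixed) if reduce else m_red
    mf = np.asarray(m_full, dtype=float)

    if np.max(np.abs(mf - mf.T), initial=0.0) > entry_tol:
        raise AssertionError("M_I is not symmetric")
    if np.max(np.abs(mf.T @ mf - np.eye(n)), initial=0.0) > entry_tol:
        raise AssertionError("M_I is not orthogonal")
    if n and np.max(np.abs(mf.sum(axis=1) - 1)) > entry_tol:
        raise AssertionError("M_I row sums differ from 1")

    s = score(mf, a, b, c, rank_tol) if n else 0
    if s != inv.beta:
        raise AssertionError(f"score {s} != beta {inv.beta}: M_I not optimal")

    conserved, ok, bad = check_conservation(a, b, c, mf, entry_tol)
    if not ok:
        raise AssertionError(f"conserved feature {bad} missing from M_I")

    if ar.n:
        diag = optimality_diagnostics(ar, br, cr, bases, rank_tol)
        inv_red = invariants(ar, br, cr)
        if diag != (inv_red.delta,) * 3:
            raise AssertionError(
                f"optimality diagnostics {diag} != delta {inv_red.delta}"
            )
    else:
        diag = (0, 0, 0)

    try:
        genome = matrix_to_genome(mf, entry_tol, name="median")
        genomic = True
    except NotGenomicError:
        genome, genomic = None, False

    return MedianResult(
        m=m_full,
        invariants_abc=inv,
        score=s,
        is_genomic=genomic,
        genome=genome,
        conserved=conserved,
        diagnostics=diag,
        bases=bases,
        exact=exact,
    )
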