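# Methods

## Model

A genome on `n` gene extremities is an involution of `{1..n}`: adjacencies
are 2-cycles, telomeres fixed points. Its permutation matrix is binary,
symmetric and orthogonal ("genomic"). Distances are rank distances,
`d(A,B) = rank(A − B)`; for two genomes this equals `n − c(AB)` with `c`
counting cycles (fixed points included) of the product permutation — the
package computes genome–genome distances this way, in exact integer
arithmetic, and uses an SVD numerical rank only when one operand is a general
real matrix.

The median of three genomes is sought over *all* matrices (the generalized
median). With β the half-sum of pairwise distances, α the triple-agreement
dimension and δ = α + β − n, the constructed median `M_I` acts as A on V₁ and
V₂, B on V₃, C on V₄, and as the identity on the disagreement space V₅
(dim 2δ), assembled by the closed-form basis formula so that a basis of V₅ is
never needed.

## Basis construction

`B₁` holds the indicator vectors of the weakly connected components of the
union of the graphs of the products AB and BC. For `B₂`–`B₄`, each cycle of
the relevant product contributes its indicator vector minus its orthogonal
projection onto span(B₁); because the projection is onto the containing
component's indicator only, the vectors of one component sum to zero, leaving
exactly one redundant vector per component. Which one to drop is a free
choice (the subspace, and hence `M_I`, is unchanged); we drop the longest
cycle per component, breaking ties toward the larger minimum element, which
keeps the sparsest vectors, and order kept vectors by cycle minimum. Basis
vectors are deliberately not normalized — the formula is scale-invariant
through `(B₁₄ᵀB₁₄)⁻¹`, which is applied as a positive-definite linear solve,
never an explicit inverse.

Instances are first reduced by removing adjacencies and telomeres common to
all three inputs (they may be assumed present in a median) and renumbering;
results are re-embedded afterwards. Features shared by exactly two inputs are
*not* pre-fixed — fixing them would perturb the third genome's distances —
but are verified present in the output, as guaranteed.

## Runtime guarantees as assertions

Every `compute_median` call asserts: symmetry and orthogonality of `M_I`
(entrywise, tolerance 1e-6), unit row sums, `score == β` exactly (integer
comparison after rank computation), presence of every 2-of-3 feature, and
the optimality certificate `dim V_I^A = dim V_I^B = dim V_I^C = δ`, computed
as nullities of the maps `(x, y) ↦ M₁(x+y) − (M₂x + y)` on V_pair ⊕ V₅, with
V₅ realized as the orthogonal complement of span(B₁₄). A failure raises
immediately rather than returning a wrong median.

## Numerical choices

* Entry-level decisions (binary/fractional, conservation, matching edge
  inclusion) use ε = 1e-6; singular-value thresholds for numerical rank use a
  relative 1e-9. The two are kept distinct on purpose: entries of `M_I` are
  rationals with moderate denominators, while rank decisions must survive
  accumulated floating error.
* An exact mode keeps all bases and `M_I` as rationals
  (`fractions.Fraction`, with sympy for the exact solve and ranks); it is
  bit-exact but slower, and off by default.
* Zero basis vectors are dropped below Euclidean norm 1e-9 (exact mode:
  exactly zero).
* Degenerate cases: an empty reduced instance returns the unanimous genome
  with score 0; `n = 0` is legal throughout.

## Recovery heuristics

The matching heuristic maximizes Σ M_ij G_ij over genomes G — the Frobenius
relaxation of the rank objective — via networkx's blossom matching. Blossom
has no self-loops, so each vertex gets a twin joined only to it with the
telomere weight |M_ii|; matching a vertex to its twin encodes a telomere and
is weight-equivalent to the self-loop formulation. Ties among equal-weight
matchings fall to the deterministic blossom traversal order.

The closest-genome heuristic extracts the fractional row set R (the
complement is provably binary for a symmetric orthogonal median, and a −1
entry is impossible — both asserted), splits `M^R` into connected blocks on
its nonzero pattern, and searches each block exhaustively over involutions
(guarded at 10 extremities per block, 9 496 candidates). Restricting to
block-diagonal candidates is a heuristic, not a theorem; tests compare the
achieved block distance against an unrestricted brute-force oracle for
|R| ≤ 8. Ties in block distance are broken by the score of the assembled
genome against the inputs, then by enumeration order (the involution
enumerator places the smallest unplaced extremity first as a telomere, then
pairs it with each larger partner in increasing order).

## Simulator

`generate_triple` draws one ancestor uniformly over involutions (sampled via
the telephone-number recurrence `I(k) = I(k−1) + (k−1)·I(k−2)`), then applies
`round(r · n_genes)` operations independently to three copies. SCJ draws
uniformly from all cuts and joins (rank-distance step exactly 1); DCJ draws
uniformly from all double swaps of two adjacencies, adjacency–telomere
exchanges, telomere joins and single-adjacency cuts (step 1 or 2). Every
operation changes the genome. The uniform-involution ancestor and the uniform
operation law are this package's choices for "random"; they produce realistic
mixes of adjacencies and telomeres but do not model gene content change,
chromosome-count constraints, or hotspot heterogeneity of real genomes —
passing property tests certify the algebraic guarantees of the median, not
biological fidelity.

Default study conditions mirror the benchmark regime the method targets:
rearrangement rates r between 0.05 and 0.3 and genomes up to 1000 genes; the
test suite exercises 200 triples of up to 200 extremities (100 genes), a
problem size at which the full pipeline (bases, solve, rank checks,
diagnostics) completes in a few tens of milliseconds per instance. Low-rate
SCJ instances overwhelmingly have δ = 0 and a genomic `M_I`; DCJ instances
frequently have δ > 0 and a fractional median, which is what the recovery
heuristics are for. Population-level percentages depend on the random draw
and are checked only as loose distributional bands.

## Known limitations

* The specialized O(n²) algorithm for δ = 0 instances is not implemented;
  the general algorithm covers that case.
* Medians are not enumerated — one median (`M_I`) is produced; non-orthogonal
  medians exist for some inputs and are out of scope.
* The closest-genome heuristic fails (with a clear error) when a fractional
  block exceeds the exhaustive-search bound; callers fall back to matching.
* Signed gene-order (GRIMM-style) input is not parsed; inputs are extremity
  matchings.
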