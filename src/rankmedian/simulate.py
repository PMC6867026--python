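"""Random genomes and SCJ/DCJ rearrangement simulation.

Test instances follow the usual protocol for median benchmarks: draw a random
ancestor genome, then apply ``round(r * n_genes)`` random rearrangement
operations independently to three copies to obtain the inputs A, B, C.  Two
operation models are supported:

* **SCJ** (single cut-or-join): break one adjacency into two telomeres, or
  join two telomeres into an adjacency.  Each operation changes the rank
  distance by exactly 1.
* **DCJ** (double cut-and-join): act on the extremities of two elements
  (adjacencies or telomeres) — double swaps of two adjacencies, adjacency/
  telomere exchanges, joins of two telomeres, and the cut of a single
  adjacency.  Each operation changes the rank distance by 1 or 2.

Operations are drawn uniformly from the set of all possible operations of the
model on the current genome; every operation changes the genome.  Random
genomes are uniform over involutions, sampled with the telephone-number
recurrence I(k) = I(k-1) + (k-1) I(k-2): the smallest unplaced extremity is a
telomere with probability I(k-1)/I(k), else paired with a uniform partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import Genome


@dataclass(frozen=True)
class RearrangementTriple:
    """A simulated median instance with its generation parameters."""

    a: Genome
    b: Genome
    c: Genome
    ancestor: Genome
    n: int  # extremities
    n_genes: int
    r: float
    model: str
    ops_applied: int
    seed: int | None


def _telomere_probabilities(n: int) -> list[float]:
    """ratios[k] = I(k-1)/I(k): probability that a fixed element of a uniform
    involution on k elements is a fixed point."""
    # 1/ratio[k] = 1 + (k-1) * ratio[k-1], from the telephone recurrence
    ratios = [1.0, 1.0]
    for k in range(2, n + 1):
        ratios.append(1.0 / (1.0 + (k - 1) * ratios[k - 1]))
    return ratios


def random_genome(n: int, rng: np.random.Generator, name: str | None = None) -> Genome:
    """Uniformly random involution on {1..n}."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    ratios = _telomere_probabilities(n)
    avail = list(range(1, n + 1))
    pairs: list[tuple[int, int]] = []
    while avail:
        k = len(avail)
        i = avail.pop(0)
        if k == 1 or rng.random() < ratios[k]:
            continue  # i is a telomere
        j = avail.pop(int(rng.integers(len(avail))))
        pairs.append((i, j))
    return Genome.from_pairs(n, pairs, name)


def apply_scj(g: Genome, rng: np.random.Generator) -> Genome:
    """One uniform single cut-or-join; rank distance to ``g`` is exactly 1."""
    adj = g.adjacencies
    tel = g.telomeres
    n_cuts = len(adj)
    n_joins = len(tel) * (len(tel) - 1) // 2
    total = n_cuts + n_joins
    if total == 0:
        raise ValueError("no SCJ operation possible on this genome")
    k = int(rng.integers(total))
    pairs = list(adj)
    if k < n_cuts:
        del pairs[k]  # cut: the two extremities become telomeres
    else:
        k -= n_cuts
        # join the k-th unordered telomere pair, lexicographic order
        i, j = _unrank_pair(k, len(tel))
        pairs.append((tel[i], tel[j]))
    return Genome.from_pairs(g.n, pairs, g.name)


def _unrank_pair(k: int, t: int) -> tuple[int, int]:
    """k-th pair (i < j) of {0..t-1} in lexicographic order."""
    for i in range(t - 1):
        block = t - 1 - i
        if k < block:
            return i, i + 1 + k
        k -= block
    raise IndexError("pair index out of range")


def apply_dcj(g: Genome, rng: np.random.Generator) -> Genome:
    """One uniform double cut-and-join; rank distance to ``g`` is 1 or 2.

    The operation set, over the elements (adjacencies and telomeres) of the
    genome: two rewirings for each pair of adjacencies, two for each
    adjacency/telomere pair, the join of each telomere pair, and the cut of
    each single adjacency.
    """
    adj = g.adjacencies
    tel = g.telomeres
    na, nt = len(adj), len(tel)
    n_aa = na * (na - 1) // 2
    n_at = na * nt
    n_tt = nt * (nt - 1) // 2
    total = 2 * n_aa + 2 * n_at + n_tt + na
    if total == 0:
        raise ValueError("no DCJ operation possible on this genome")
    k = int(rng.integers(total))
    pairs = list(adj)
    if k < 2 * n_aa:
        idx, variant = divmod(k, 2)
        i, j = _unrank_pair(idx, na)
        (p, q), (r, s) = adj[i], adj[j]
        del pairs[j], pairs[i]
        # double swap: {p,q},{r,s} -> {p,r},{q,s} or {p,s},{q,r}
        pairs += [(p, r), (q, s)] if variant == 0 else [(p, s), (q, r)]
        return Genome.from_pairs(g.n, pairs, g.name)
    k -= 2 * n_aa
    if k < 2 * n_at:
        idx, variant = divmod(k, 2)
        ai, ti = divmod(idx, nt)
        p, q = adj[ai]
        t = tel[ti]
        del pairs[ai]
        # exchange: {p,q},t -> {p,t} (q telomere) or {q,t} (p telomere)
        pairs.append((p, t) if variant == 0 else (q, t))
        return Genome.from_pairs(g.n, pairs, g.name)
    k -= 2 * n_at
    if k < n_tt:
        i, j = _unrank_pair(k, nt)
        pairs.append((tel[i], tel[j]))
        return Genome.from_pairs(g.n, pairs, g.name)
    k -= n_tt
    del pairs[k]  # cut a single adjacency
    return Genome.from_pairs(g.n, pairs, g.name)


def generate_triple(
    n_genes: int,
    r: float,
    model: str = "dcj",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RearrangementTriple:
    """Simulate a median instance: one ancestor, three independently evolved copies.

    ``n_genes`` genes give ``2 * n_genes`` extremities; each of A, B, C
    results from ``round(r * n_genes)`` operations of the chosen model
    applied to the ancestor.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if r < 0:
        raise ValueError("rate r must be nonnegative")
    model = model.lower()
    if model not in ("scj", "dcj"):
        raise ValueError(f"unknown model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = 2 * n_genes
    ops = int(round(r * n_genes))
    step = apply_scj if model == "scj" else apply_dcj
    ancestor = random_genome(n, rng, "ancestor")
    leaves = []
    for label in "ABC":
        g = Genome(ancestor.n, ancestor.pairing, label)
        for _ in range(ops):
            g = step(g, rng)
        leaves.append(g)
    return RearrangementTriple(
        a=leaves[0],
        b=leaves[1],
        c=leaves[2],
        ancestor=ancestor,
        n=n,
        n_genes=n_genes,
        r=r,
        model=model,
        ops_applied=ops,
        seed=seed,
    )
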