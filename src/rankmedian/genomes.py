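"""Genomes as involutions on gene extremities, and their matrix representations.

A genome on ``n`` gene extremities is modelled as a perfect partial matching:
every extremity is either glued to exactly one other extremity (an *adjacency*)
or left free (a *telomere*).  Formally this is an involution of ``{1..n}`` —
a permutation that is its own inverse, i.e. a product of disjoint 1- and
2-cycles.  Its permutation matrix is binary, symmetric and orthogonal; we call
such matrices *genomic*.

Extremity indices are 1-based everywhere in the public API, file formats and
error messages, matching the standard cycle notation ``(2 4)(3 9)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("rankmedian")

#: Default tolerance for deciding that a matrix entry is (close enough to) 0 or 1.
DEFAULT_ENTRY_TOL = 1e-6


class GenomeError(ValueError):
    """Raised when input does not describe a valid genome (involution)."""


class NotGenomicError(GenomeError):
    """Raised when a matrix is not (close to) a genomic matrix."""

    def __init__(self, message: str, offending: list[tuple[int, int]] | None = None):
        super().__init__(message)
        self.offending = offending or []


@dataclass(frozen=True)
class Genome:
    """An involution on extremities ``{1..n}``.

    Parameters
    ----------
    n:
        Number of gene extremities (two per gene for a bona-fide genome).
    pairing:
        Tuple of length ``n``; ``pairing[i-1]`` is the partner of extremity
        ``i`` (itself for a telomere).  Must be an involution.
    name:
        Optional label carried through I/O and reports.
    """

    n: int
    pairing: tuple[int, ...]
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise GenomeError(f"extremity count must be nonnegative, got {self.n}")
        if len(self.pairing) != self.n:
            raise GenomeError(
                f"pairing has length {len(self.pairing)}, expected n={self.n}"
            )
        for i, j in enumerate(self.pairing, start=1):
            if not 1 <= j <= self.n:
                raise GenomeError(f"extremity {i} maps to {j}, outside 1..{self.n}")
            if self.pairing[j - 1] != i:
                raise GenomeError(
                    f"pairing is not an involution: {i} -> {j} -> {self.pairing[j - 1]}"
                )

    @classmethod
    def from_pairs(
        cls, n: int, pairs: Iterable[tuple[int, int]], name: str | None = None
    ) -> "Genome":
        """Build a genome from adjacency pairs; unlisted extremities are telomeres."""
        pairing = list(range(1, n + 1))
        seen: set[int] = set()
        for i, j in pairs:
            for k in (i, j):
                if not 1 <= k <= n:
                    raise GenomeError(f"extremity {k} out of range 1..{n}")
            if i == j:  # explicit telomere row
                if i in seen:
                    raise GenomeError(f"not a matching: extremity {i} repeated")
                seen.add(i)
                continue
            if i in seen or j in seen:
                dup = i if i in seen else j
                raise GenomeError(f"not a matching: extremity {dup} repeated")
            seen.update((i, j))
            pairing[i - 1] = j
            pairing[j - 1] = i
        return cls(n, tuple(pairing), name)

    def partner(self, i: int) -> int:
        """Partner of extremity ``i`` (1-based); ``i`` itself for a telomere."""
        return self.pairing[i - 1]

    @property
    def adjacencies(self) -> list[tuple[int, int]]:
        """Sorted list of adjacencies as pairs ``(i, j)`` with ``i < j``."""
        return [
            (i, self.pairing[i - 1])
            for i in range(1, self.n + 1)
            if self.pairing[i - 1] > i
        ]

    @property
    def telomeres(self) -> list[int]:
        """Sorted list of telomeric extremities (fixed points)."""
        return [i for i in range(1, self.n + 1) if self.pairing[i - 1] == i]

    def to_cycles(self) -> str:
        """Cycle-notation string of the adjacencies, e.g. ``(2 4)(3 9)``."""
        return "".join(f"({i} {j})" for i, j in self.adjacencies)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        cyc = self.to_cycles() or "()"
        return f"{self.name or 'genome'}[n={self.n}] {cyc}"


_CYCLE_RE = re.compile(r"\(([^()]*)\)")


def parse_cycles(text: str, n: int, name: str | None = None) -> Genome:
    """Parse whitespace/comma-separated disjoint cycle notation into a genome.

    Every cycle must have length 1 or 2 (an involution); extremities absent
    from the text become telomeres.  ``"(2 4)(3 9)"`` with ``n=12`` gives the
    genome with adjacencies {2,4},{3,9} and eight telomeres.
    """
    stripped = _CYCLE_RE.sub("", text)
    if stripped.strip():
        raise GenomeError(f"unexpected text outside cycles: {stripped.strip()!r}")
    pairs: list[tuple[int, int]] = []
    for body in _CYCLE_RE.findall(text):
        tokens = [t for t in re.split(r"[,\s]+", body.strip()) if t]
        if not tokens:
            continue
        try:
            idx = [int(t) for t in tokens]
        except ValueError as exc:
            raise GenomeError(f"non-integer token in cycle ({body})") from exc
        if len(idx) == 1:
            pairs.append((idx[0], idx[0]))
        elif len(idx) == 2:
            pairs.append((idx[0], idx[1]))
        else:
            raise GenomeError(
                f"not genomic: cycle ({body}) has length {len(idx)} > 2"
            )
    return Genome.from_pairs(n, pairs, name)


def genome_to_matrix(g: Genome) -> np.ndarray:
    """Genomic (binary symmetric orthogonal) matrix of a genome.

    ``M[i-1, j-1] = 1`` iff ``j`` is the partner of ``i`` — off-diagonal ones
    encode adjacencies, diagonal ones encode telomeres.
    """
    m = np.zeros((g.n, g.n))
    for i in range(1, g.n + 1):
        m[i - 1, g.pairing[i - 1] - 1] = 1.0
    return m


def matrix_to_genome(
    m: np.ndarray, tol: float = DEFAULT_ENTRY_TOL, name: str | None = None
) -> Genome:
    """Round a near-binary matrix back to a genome, or raise ``NotGenomicError``.

    Succeeds iff every entry is within ``tol`` of {0, 1} and the rounded
    matrix is a symmetric permutation matrix (an involution).  This is the
    test used to decide whether a computed median is itself genomic.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise NotGenomicError(f"matrix is not square: shape {m.shape}")
    n = m.shape[0]
    rounded = np.round(m)
    off = np.argwhere(np.abs(m - rounded) > tol)
    bad = np.argwhere((rounded != 0) & (rounded != 1))
    offending = sorted(
        {(int(i) + 1, int(j) + 1) for i, j in np.vstack([off, bad])}
    )
    if offending:
        raise NotGenomicError(
            f"not genomic: {len(offending)} entries not within {tol} of {{0,1}}, "
            f"first at {offending[:5]}",
            offending,
        )
    b = rounded.astype(int)
    if not np.array_equal(b, b.T):
        raise NotGenomicError("not genomic: rounded matrix is not symmetric")
    if not (np.all(b.sum(axis=0) == 1) and np.all(b.sum(axis=1) == 1)):
        raise NotGenomicError("not genomic: row/column sums differ from 1")
    pairing = tuple(int(np.argmax(b[i])) + 1 for i in range(n))
    return Genome(n, pairing, name)


def is_genomic(m: np.ndarray, tol: float = DEFAULT_ENTRY_TOL) -> bool:
    """True iff ``matrix_to_genome`` succeeds on ``m``."""
    try:
        matrix_to_genome(m, tol)
        return True
    except NotGenomicError:
        return False


# ---------------------------------------------------------------------------
# File I/O.  Cycles format: optional "#n=<int>" header, then one genome per
# line as "name<TAB>cycles".  Adjacency TSV: "#n=<int>" header then rows
# "extremity_a<TAB>extremity_b" (telomere rows repeat the extremity).
# ---------------------------------------------------------------------------

def read_genomes(path: str | Path, format: str = "cycles") -> list[Genome]:
    """Read genomes from a cycles or adjacency-TSV file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n: int | None = None
    body: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            mobj = re.match(r"#\s*n\s*=\s*(\d+)", line)
            if mobj:
                n = int(mobj.group(1))
            continue
        body.append((lineno, raw))
    if n is None:
        raise GenomeError(f"{path}: missing '#n=<int>' header line")
    if n % 2 == 1:
        # a genome has two extremities per gene; odd n is allowed but suspect
        logger.warning("%s: odd extremity count n=%d", path, n)

    genomes: list[Genome] = []
    if format == "cycles":
        for lineno, raw in body:
            parts = raw.split("\t", 1)
            if len(parts) != 2:
                raise GenomeError(f"{path}:{lineno}: expected 'name<TAB>cycles'")
            name, cycles = parts[0].strip(), parts[1]
            try:
                genomes.append(parse_cycles(cycles, n, name))
            except GenomeError as exc:
                raise GenomeError(f"{path}:{lineno}: {exc}") from exc
    elif format == "adjacency-tsv":
        pairs: list[tuple[int, int]] = []
        for lineno, raw in body:
            cols = raw.split()
            if len(cols) != 2:
                raise GenomeError(
                    f"{path}:{lineno}: expected two extremity columns"
                )
            try:
                pairs.append((int(cols[0]), int(cols[1])))
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer extremity") from exc
        genomes.append(Genome.from_pairs(n, pairs, path.stem))
    else:
        raise ValueError(f"unknown genome format {format!r}")
    return genomes


def write_genomes(path: str | Path, genomes: Sequence[Genome], format: str = "cycles") -> None:
    """Write genomes in a format ``read_genomes`` round-trips."""
    path = Path(path)
    if not genomes:
        path.write_text("#n=0\n")
        return
    n = genomes[0].n
    if any(g.n != n for g in genomes):
        raise GenomeError("all genomes in one file must share the same n")
    out = [f"#n={n}"]
    if format == "cycles":
        for k, g in enumerate(genomes):
            out.append(f"{g.name or f'genome{k + 1}'}\t{g.to_cycles()}")
    elif format == "adjacency-tsv":
        if len(genomes) != 1:
            raise GenomeError("adjacency-tsv holds a single genome per file")
        g = genomes[0]
        out.extend(f"{i}\t{j}" for i, j in g.adjacencies)
        out.extend(f"{i}\t{i}" for i in g.telomeres)
    else:
        raise ValueError(f"unknown genome format {format!r}")
    path.write_text("\n".join(out) + "\n")


def write_matrix_tsv(path: str | Path, m: np.ndarray) -> None:
    """Write a matrix as a TSV of decimal floats (or exact p/q for rationals)."""
    rows = []
    for row in np.asarray(m, dtype=object):
        cells = []
        for x in row:
            if isinstance(x, (int, np.integer)):
                cells.append(str(int(x)))
            elif hasattr(x, "numerator") and hasattr(x, "denominator"):
                p, q = x.numerator, x.denominator  # Fraction / sympy Rational
                cells.append(f"{p}/{q}" if q != 1 else str(p))
            else:
                cells.append(repr(float(x)))
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    """Read a float matrix written by ``write_matrix_tsv`` (p/q cells allowed)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cells = []
        for tok in line.split("\t"):
            if "/" in tok:
                p, q = tok.split("/")
                cells.append(float(p) / float(q))
            else:
                cells.append(float(tok))
        rows.append(cells)
    return np.array(rows)
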