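"""Shared fixtures: the 12-extremity worked example and its printed median."""

from __future__ import annotations

import numpy as np
import pytest

from rankmedian import Genome, parse_cycles

# The 12-extremity example triple (extremity 12 is a telomere in all inputs).
CYCLES_A = "(2 4)(3 9)(6 8)(10 11)"
CYCLES_B = "(2 7)(3 8)(4 5)(6 9)(10 11)"
CYCLES_C = "(2 3)(4 5)(6 7)(8 9)(10 11)"

# The same triple after removing unanimously shared features (telomeres 1 and
# 12, adjacency (10 11)) and renumbering the survivors to 1..8.
CYCLES_A_RED = "(1 3)(2 8)(5 7)"
CYCLES_B_RED = "(1 6)(2 7)(3 4)(5 8)"
CYCLES_C_RED = "(1 2)(3 4)(5 6)(7 8)"

# Six times the median matrix M_I of the reduced instance.
SIX_MEDIAN = np.array(
    [
        [4, 2, 0, 0, -2, 2, -2, 2],
        [2, 1, 0, 0, -1, -2, 5, 1],
        [0, 0, 0, 6, 0, 0, 0, 0],
        [0, 0, 6, 0, 0, 0, 0, 0],
        [-2, -1, 0, 0, 1, 2, 1, 5],
        [2, -2, 0, 0, 2, 4, 2, -2],
        [-2, 5, 0, 0, 1, 2, 1, -1],
        [2, 1, 0, 0, 5, -2, -1, 1],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def worked_triple() -> tuple[Genome, Genome, Genome]:
    return (
        parse_cycles(CYCLES_A, 12, "A"),
        parse_cycles(CYCLES_B, 12, "B"),
        parse_cycles(CYCLES_C, 12, "C"),
    )


@pytest.fixture(scope="session")
def reduced_triple() -> tuple[Genome, Genome, Genome]:
    return (
        parse_cycles(CYCLES_A_RED, 8, "A'"),
        parse_cycles(CYCLES_B_RED, 8, "B'"),
        parse_cycles(CYCLES_C_RED, 8, "C'"),
    )


@pytest.fixture(scope="session")
def printed_median() -> np.ndarray:
    return SIX_MEDIAN / 6.0
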