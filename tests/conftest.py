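"""Shared fixtures and the independent exact-enumeration oracle.

The oracle computes settlement-sequence probabilities by brute-force
enumeration of permutations, with the weight formulas written out by hand
— it never calls the package's weight functions, so it is an independent
check of the sequential sampling machinery.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from hypovet import Landscape, simulate_settlement


@pytest.fixture
def abb_landscape() -> Landscape:
    """1x3 landscape with labels A, B, B."""
    return Landscape(np.array([["A", "B", "B"]]))


@pytest.fixture
def square_landscape() -> Landscape:
    """2x2 landscape, top row A, bottom row B."""
    return Landscape(np.array([["A", "A"], ["B", "B"]]))


def enumerate_sequence_probs(labels, family, n_agents, omega=None, s=None):
    """Exact probability of every ordered settlement sequence.

    ``labels`` is a 2-D nested list of 'A'/'B'. Weights are re-derived from
    first principles: 1 for the null model, ``omega`` for A cells under
    habitat preference, ``exp(-s * d_nearest)`` (uniform for the first
    settler) under conspecific attraction.
    """
    labels = [list(row) for row in labels]
    n_rows, n_cols = len(labels), len(labels[0])
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    centers = {(r, c): (c + 0.5, r + 0.5) for r, c in cells}

    def weight(cell, occupied):
        if family == "null":
            return 1.0
        if family == "habitat_preference":
            return float(omega) if labels[cell[0]][cell[1]] == "A" else 1.0
        if family == "conspecific_attraction":
            if not occupied:
                return 1.0
            x, y = centers[cell]
            d = min(
                math.hypot(x - centers[o][0], y - centers[o][1]) for o in occupied
            )
            return math.exp(-s * d)
        raise ValueError(family)

    probs = {}
    for seq in itertools.permutations(cells, n_agents):
        p = 1.0
        occupied = []
        for cell in seq:
            free = [c for c in cells if c not in occupied]
            ws = {c: weight(c, occupied) for c in free}
            p *= ws[cell] / sum(ws.values())
            occupied.append(cell)
        probs[seq] = p
    return probs


@pytest.fixture
def sequence_oracle():
    return enumerate_sequence_probs


def empirical_sequence_freqs(landscape, spec, n_agents, n_sims, seed0=0):
    counts = Counter()
    for i in range(n_sims):
        result = simulate_settlement(landscape, spec, n_agents, seed0 + i)
        counts[result.settled] += 1
    return {seq: n / n_sims for seq, n in counts.items()}


@pytest.fixture
def sequence_empirics():
    return empirical_sequence_freqs
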