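"""Shared fixtures and independent oracle helpers.

The oracle functions below are deliberately naive re-derivations
(explicit loops, no numpy tricks) and share no code with the package;
tests use them as the second route of every dual-route check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import randseq as rs

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles


def oracle_collapse(values):
    out = [values[0]]
    for v in values[1:]:
        if v != out[-1]:
            out.append(v)
    return out


def oracle_turning_points(values):
    """Sign-change scan on the duplicate-collapsed series."""
    c = oracle_collapse(list(values))
    count = 0
    for j in range(1, len(c) - 1):
        if (c[j] - c[j - 1] > 0) != (c[j + 1] - c[j] > 0):
            count += 1
    return count


def oracle_digram_set(tokens):
    return set(zip(tokens, tokens[1:]))


def oracle_vertical_runs(tokens):
    """Brute-force vertical run scan of the exact-match plot, diagonal excluded."""
    n = len(tokens)
    runs = []
    for j in range(n):
        run = 0
        for i in range(n):
            if i != j and tokens[i] == tokens[j]:
                run += 1
            else:
                if run:
                    runs.append(run)
                run = 0
        if run:
            runs.append(run)
    return sorted(runs)


def oracle_recurrent_cells(tokens):
    n = len(tokens)
    return {
        (i + 1, j + 1)
        for i in range(n)
        for j in range(n)
        if i != j and tokens[i] == tokens[j]
    }


def oracle_shannon_entropy_bits(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def digits():
    return rs.Alphabet.from_scale(1, 9)


@pytest.fixture
def coin():
    return rs.Alphabet.from_alternatives(["head", "tail"])


@pytest.fixture
def seq_factory(digits):
    def make(tokens, a=9):
        return rs.make_sequence(list(tokens), min_scale=1, max_scale=a)

    return make


@pytest.fixture
def random_sequences():
    """Deterministic batch of IID sequences over varying n and alphabet size."""

    def make(count, seed=0, n_range=(10, 60), a_range=(2, 9)):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(count):
            n = int(rng.integers(n_range[0], n_range[1] + 1))
            a = int(rng.integers(a_range[0], a_range[1] + 1))
            alphabet = rs.Alphabet.from_scale(1, a)
            out.append(rs.generate_iid(alphabet, n, seed=int(rng.integers(1 << 30))))
        return out

    return make
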