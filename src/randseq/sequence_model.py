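"""Data model for categorical response sequences.

Every measure in this package operates on a :class:`SymbolSequence`: an
ordered series of tokens drawn from a declared, finite :class:`Alphabet`.
Alphabets are built either from an integer min/max scale (numeric
responses such as digits 1..9) or from an explicit ordered list of
response alternatives (letters, ``head``/``tail``, ...).  Non-numeric
alternatives receive ordinal codes ``1..a`` in declaration order so that
difference-based measures remain defined for them.

The module also houses file parsing, a seeded IID generator and a small
family of deterministic fixture constructions (constant, alternating,
tandem-pair, exact-turning-point-count and exact-distinct-digram-count
sequences) used throughout the test-suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "SequenceError",
    "Alphabet",
    "SymbolSequence",
    "FrequencyTable",
    "make_sequence",
    "read_sequences",
    "generate_iid",
    "construct_fixture",
    "FIXTURE_KINDS",
]


class SequenceError(ValueError):
    """Invalid alphabet, token, file or infeasible fixture request."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite set of response alternatives.

    ``ordinal`` is a bijection from the alternatives onto ``1..a`` in
    declaration order; for numeric alphabets built from a min/max scale
    this order is the natural ascending order of the integers.
    """

    alternatives: tuple
    numeric: bool = False

    def __post_init__(self) -> None:
        if len(self.alternatives) < 2:
            raise SequenceError("an alphabet needs at least 2 response alternatives")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise SequenceError("duplicate response alternatives are not allowed")
        object.__setattr__(
            self, "_ordinals", {t: k + 1 for k, t in enumerate(self.alternatives)}
        )

    @classmethod
    def from_scale(cls, min_scale: int, max_scale: int) -> "Alphabet":
        """Every integer in ``[min_scale, max_scale]``, ascending."""
        min_scale, max_scale = int(min_scale), int(max_scale)
        if min_scale >= max_scale:
            raise SequenceError(
                f"min_scale ({min_scale}) must be strictly below max_scale ({max_scale})"
            )
        return cls(tuple(range(min_scale, max_scale + 1)), numeric=True)

    @classmethod
    def from_alternatives(cls, alternatives: Iterable) -> "Alphabet":
        return cls(tuple(str(t).strip() for t in alternatives), numeric=False)

    @property
    def size(self) -> int:
        return len(self.alternatives)

    def __contains__(self, token: object) -> bool:
        return token in self._ordinals  # type: ignore[attr-defined]

    def ordinal(self, token: object) -> int:
        try:
            return self._ordinals[token]  # type: ignore[attr-defined]
        except KeyError:
            raise SequenceError(f"token {token!r} is not in the alphabet") from None


@dataclass(frozen=True)
class SymbolSequence:
    """Validated token series over a declared alphabet."""

    tokens: tuple
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.tokens:
            raise SequenceError("a sequence must contain at least one token")
        for pos, tok in enumerate(self.tokens, start=1):
            if tok not in self.alphabet:
                raise SequenceError(
                    f"token {tok!r} at position {pos} is outside the alphabet"
                )

    @property
    def n(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator:
        return iter(self.tokens)

    def ordinals(self) -> np.ndarray:
        """Tokens mapped to their 1-based alphabet ordinals."""
        return np.array(
            [self.alphabet.ordinal(t) for t in self.tokens], dtype=np.int64
        )


@dataclass
class FrequencyTable:
    """Mapping from a key (symbol, pair, difference, length, gap) to a count."""

    entries: dict

    def __post_init__(self) -> None:
        for key, count in self.entries.items():
            if count < 0:
                raise SequenceError(f"negative count for key {key!r}")
        self.entries = {k: int(c) for k, c in self.entries.items()}

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def __getitem__(self, key) -> int:
        return self.entries.get(key, 0)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self) -> list:
        try:
            return sorted(self.entries.items())
        except TypeError:  # heterogeneous keys
            return sorted(self.entries.items(), key=lambda kv: str(kv[0]))

    def expand(self) -> list:
        """The table as an explicit multiset (keys repeated by count)."""
        return [k for k, c in self.items() for _ in range(c)]

    @classmethod
    def from_counts(cls, counts: Counter) -> "FrequencyTable":
        return cls(dict(counts))


def make_sequence(
    tokens: Iterable,
    min_scale: int | None = None,
    max_scale: int | None = None,
    alternatives: Iterable | None = None,
) -> SymbolSequence:
    """Build a validated sequence from raw tokens plus an alphabet spec.

    Exactly one of ``min_scale``/``max_scale`` (numeric scale) or
    ``alternatives`` (explicit ordered list) must be given.  Numeric
    tokens are canonicalised to integers; other tokens are compared as
    trimmed strings.
    """
    scale_given = min_scale is not None or max_scale is not None
    if scale_given == (alternatives is not None):
        raise SequenceError(
            "provide exactly one of min_scale/max_scale or alternatives"
        )
    toks = list(tokens)
    if not toks:
        raise SequenceError("a sequence must contain at least one token")

    if alternatives is not None:
        alphabet = Alphabet.from_alternatives(alternatives)
        out = [str(t).strip() for t in toks]
    else:
        if min_scale is None or max_scale is None:
            raise SequenceError("both min_scale and max_scale are required")
        alphabet = Alphabet.from_scale(min_scale, max_scale)
        out = []
        for pos, tok in enumerate(toks, start=1):
            try:
                out.append(int(str(tok).strip()))
            except ValueError:
                raise SequenceError(
                    f"token {tok!r} at position {pos} is not an integer"
                ) from None
    return SymbolSequence(tuple(out), alphabet)


def read_sequences(path, delimiter: str = "auto") -> list[list[str]]:
    """Parse a plain-text/CSV file into raw token lists, one per line.

    ``delimiter`` is ``comma``, ``whitespace`` or ``auto`` (comma when
    the line contains one, whitespace otherwise).  Blank lines are
    skipped; tokens are trimmed strings and numeric conversion is left to
    :func:`make_sequence`.
    """
    if delimiter not in ("comma", "whitespace", "auto"):
        raise SequenceError(f"unknown delimiter {delimiter!r}")
    text = Path(path).read_text(encoding="utf-8")
    sequences: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if delimiter == "comma" or (delimiter == "auto" and "," in line):
            toks = [t.strip() for t in line.split(",")]
        else:
            toks = line.split()
        toks = [t for t in toks if t]
        if toks:
            sequences.append(toks)
    if not sequences:
        raise SequenceError(f"no sequences found in {path}")
    return sequences


def generate_iid(alphabet: Alphabet, length: int, seed: int) -> SymbolSequence:
    """Uniform independent draws from the alphabet; pure in (alphabet, length, seed)."""
    if length < 1:
        raise SequenceError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, alphabet.size, size=length)
    return SymbolSequence(tuple(alphabet.alternatives[i] for i in idx), alphabet)


FIXTURE_KINDS = (
    "constant",
    "alternating",
    "tandem_pairs",
    "turning_points",
    "digram_count",
)


def construct_fixture(kind: str, **params) -> SymbolSequence:
    """Deterministic constrained sequences for tests and worked examples.

    kinds:
      * ``constant`` — one symbol repeated (params ``n``, ``symbol``, ``a``)
      * ``alternating`` — two symbols strictly alternated (params ``n``, ``a``)
      * ``tandem_pairs`` — 1,1,2,2,1,1,2,2,... so every off-diagonal
        vertical recurrence run has length exactly 2 (params ``n``)
      * ``turning_points`` — numeric length-``n`` sequence with exactly
        ``tp`` turning points (params ``n``, ``tp``, ``a``)
      * ``digram_count`` — length-``n`` sequence over ``a`` symbols with
        exactly ``d`` distinct ordered adjacent pairs, no end-to-start
        wrap (params ``n``, ``a``, ``d``)
    """
    if kind == "constant":
        n = int(params["n"])
        a = int(params.get("a", 9))
        symbol = int(params.get("symbol", min(5, a)))
        if n < 1:
            raise SequenceError("n must be >= 1")
        return SymbolSequence((symbol,) * n, Alphabet.from_scale(1, a))
    if kind == "alternating":
        n = int(params["n"])
        a = int(params.get("a", 9))
        if n < 2:
            raise SequenceError("n must be >= 2")
        return SymbolSequence(
            tuple(1 if i % 2 == 0 else 2 for i in range(n)), Alphabet.from_scale(1, a)
        )
    if kind == "tandem_pairs":
        n = int(params.get("n", 8))
        if n < 4:
            raise SequenceError("n must be >= 4 for tandem pairs")
        pattern = (1, 1, 2, 2)
        return SymbolSequence(
            tuple(pattern[i % 4] for i in range(n)), Alphabet.from_scale(1, 2)
        )
    if kind == "turning_points":
        return _turning_point_fixture(
            int(params["n"]), int(params["tp"]), int(params.get("a", 9))
        )
    if kind == "digram_count":
        return _digram_count_fixture(
            int(params["n"]), int(params["a"]), int(params["d"])
        )
    raise SequenceError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")


def _turning_point_fixture(n: int, tp: int, a: int) -> SymbolSequence:
    # Alternate 1,2 over tp+2 points (every interior point is a turn),
    # then pad with duplicates of the final value; duplicates collapse
    # before direction analysis and add no turns.
    if n < 3:
        raise SequenceError("n must be >= 3 for a turning-point fixture")
    if not 0 <= tp <= n - 2:
        raise SequenceError(f"tp must be in [0, {n - 2}] for n={n}")
    if a < 2:
        raise SequenceError("a must be >= 2")
    base = [1 if i % 2 == 0 else 2 for i in range(tp + 2)]
    tokens = base + [base[-1]] * (n - len(base))
    return SymbolSequence(tuple(tokens), Alphabet.from_scale(1, a))


def _euler_circuit_nodes(a: int) -> list[int]:
    # Hierholzer over the complete digraph with self-loops on 1..a; every
    # ordered pair appears exactly once as an edge of the circuit.
    remaining = {u: list(range(a, 0, -1)) for u in range(1, a + 1)}
    stack, circuit = [1], []
    while stack:
        v = stack[-1]
        if remaining[v]:
            stack.append(remaining[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def _digram_count_fixture(n: int, a: int, d: int) -> SymbolSequence:
    if n < 2:
        raise SequenceError("n must be >= 2")
    if a < 2:
        raise SequenceError("a must be >= 2")
    d_max = min(n - 1, a * a)
    if not 1 <= d <= d_max:
        raise SequenceError(f"d must be in [1, {d_max}] for n={n}, a={a}")
    circuit = _euler_circuit_nodes(a)
    edges = list(zip(circuit, circuit[1:]))
    k = edges.index((1, 1))  # rotate so the walk starts with the (1,1) loop
    edges = edges[k:] + edges[:k]
    walk = [edges[0][0]] + [v for _, v in edges[:d]]
    # Padding repeats symbol 1, duplicating the already-used (1,1) pair.
    tokens = [1] * (n - 1 - d) + walk
    return SymbolSequence(tuple(tokens), Alphabet.from_scale(1, a))
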