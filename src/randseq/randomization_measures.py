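"""The thirteen classical randomization measures with dual output scaling.

Each operation accepts a ``mode`` of ``"classical"`` (legacy percentage
conventions, with end-to-start digram wrapping for the digram-entropy
index only) or ``"default"`` (modernised proportion scale, never
wrapping).  Measures that a given input cannot support return the
:data:`NA` marker rather than a silent zero.

Scaling bridges (hold for every input):

* classical redundancy / NSQ / adjacency = 100 x their default values
* classical TPI = 100 x (default TPI + 1)
* coupon, repetition gaps, phi and the lag-2 digram index are identical
  across modes
* runs has no classical value (returns :data:`NA` in classical mode)
"""

from __future__ import annotations

import math
from collections import Counter, namedtuple
from dataclasses import dataclass
from functools import lru_cache
from statistics import median

import numpy as np

from .sequence_model import FrequencyTable, SequenceError, SymbolSequence

__all__ = [
    "NA",
    "NotComputable",
    "MODES",
    "MEASURES",
    "DigramTable",
    "Adjacency",
    "RepetitionGap",
    "RandomizationResult",
    "digram_counts",
    "redundancy",
    "rng_index",
    "rng2_index",
    "nsq",
    "coupon",
    "fod_table",
    "adjacency",
    "turning_points",
    "tpi",
    "phase_lengths",
    "runs",
    "repetition_distances",
    "repetition_gap",
    "phi_indices",
    "response_frequencies",
    "all_rng",
    "DEFAULT_PHI_LAGS",
]


class NotComputable:
    """Singleton marker for a measure undefined on the given input."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NA"

    def __bool__(self) -> bool:
        return False


NA = NotComputable()

MODES = ("classical", "default")

MEASURES = (
    "redundancy",
    "rng",
    "rng2",
    "rf",
    "coupon",
    "nsq",
    "fod",
    "adjacency",
    "tpi",
    "phase_lengths",
    "runs",
    "rep_distance",
    "rep_gap",
    "phi",
)

DEFAULT_PHI_LAGS = (2, 3, 4, 5, 6, 7)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _nlog2n(c: int) -> float:
    # 0*log2(0) == 0 by convention
    return c * math.log2(c) if c > 0 else 0.0


@dataclass(frozen=True)
class DigramTable:
    """Ordered-pair counts at a fixed lag plus first-member marginals."""

    lag: int
    wrap: bool
    counts: FrequencyTable
    row_totals: FrequencyTable


def digram_counts(seq: SymbolSequence, lag: int = 1, wrap: bool = False) -> DigramTable:
    """Counts of ordered pairs ``(token[i-lag], token[i])``.

    With ``wrap=True`` the final ``lag`` positions pair cyclically with
    the start of the sequence, so the pair total equals ``n`` instead of
    ``n - lag``.
    """
    if lag < 1:
        raise SequenceError("lag must be >= 1")
    n = seq.n
    if n <= lag:
        raise SequenceError(f"sequence length {n} must exceed lag {lag}")
    t = seq.tokens
    pairs = Counter((t[i - lag], t[i]) for i in range(lag, n))
    if wrap:
        pairs.update((t[n - lag + i], t[i]) for i in range(lag))
    rows: Counter = Counter()
    for (first, _second), c in pairs.items():
        rows[first] += c
    return DigramTable(lag, wrap, FrequencyTable(dict(pairs)), FrequencyTable(dict(rows)))


def redundancy(seq: SymbolSequence, mode: str = "default") -> float:
    """Inequality of single-response usage: 0 = equal use, 1 = one response only."""
    _check_mode(mode)
    n, a = seq.n, seq.alphabet.size
    counts = Counter(seq.tokens)
    observed = math.log2(n) - sum(_nlog2n(c) for c in counts.values()) / n
    value = 1.0 - observed / math.log2(a)
    value = min(max(value, 0.0), 1.0)  # clamp fp noise at the bounds
    return 100.0 * value if mode == "classical" else value


def _digram_entropy_ratio(table: DigramTable):
    numerator = sum(_nlog2n(c) for c in table.counts.entries.values())
    denominator = sum(_nlog2n(c) for c in table.row_totals.entries.values())
    if denominator == 0.0:
        return NA
    return numerator / denominator


def rng_index(seq: SymbolSequence, mode: str = "default"):
    """Inequality of ordered-pair usage at lag 1 (0 = all pairs distinct).

    Classical mode wraps the sequence end to the start before counting
    pairs; default mode does not.  The denominator uses the pair
    first-member marginals, under which a perfectly alternating sequence
    attains the maximum of 1.
    """
    _check_mode(mode)
    if seq.n < 3:
        raise SequenceError("the lag-1 digram index needs n >= 3")
    table = digram_counts(seq, lag=1, wrap=(mode == "classical"))
    return _digram_entropy_ratio(table)


def rng2_index(seq: SymbolSequence, mode: str = "default"):
    """Lag-2 analogue of :func:`rng_index`; never wraps in either mode."""
    _check_mode(mode)
    if seq.n < 4:
        raise SequenceError("the lag-2 digram index needs n >= 4")
    table = digram_counts(seq, lag=2, wrap=False)
    return _digram_entropy_ratio(table)


def nsq(seq: SymbolSequence, mode: str = "default") -> float:
    """Share of possible ordered pairs never produced: NS / (a^2 - 1)."""
    _check_mode(mode)
    if seq.n < 2:
        raise SequenceError("NSQ needs n >= 2")
    a = seq.alphabet.size
    table = digram_counts(seq, lag=1, wrap=False)
    ns = a * a - len(table.counts.entries)
    value = ns / (a * a - 1)
    return 100.0 * value if mode == "classical" else value


def coupon(seq: SymbolSequence, mode: str = "default"):
    """Mean number of responses needed to cycle through every alternative.

    Scans left to right; whenever the running symbol set covers the full
    alphabet the segment length is recorded and the set resets.  An
    unfinished trailing segment is discarded.  If no segment completes
    (in particular when some alternative is never used) the score cannot
    be calculated and :data:`NA` is returned.  Identical in both modes.
    """
    _check_mode(mode)
    a = seq.alphabet.size
    seen: set = set()
    count = 0
    lengths: list[int] = []
    for tok in seq.tokens:
        count += 1
        seen.add(tok)
        if len(seen) == a:
            lengths.append(count)
            seen = set()
            count = 0
    if not lengths:
        return NA
    return sum(lengths) / len(lengths)


def fod_table(seq: SymbolSequence) -> FrequencyTable:
    """Frequency table of lag-1 ordinal differences; total = n - 1."""
    if seq.n < 2:
        raise SequenceError("first-order differences need n >= 2")
    diffs = np.diff(seq.ordinals())
    return FrequencyTable(dict(Counter(int(d) for d in diffs)))


Adjacency = namedtuple("Adjacency", ["ascending", "descending", "combined"])


def adjacency(seq: SymbolSequence, mode: str = "default") -> Adjacency:
    """Share of lag-1 pairs that are ordinal neighbours.

    Ascending pairs have ordinal difference +1, descending -1; each count
    is divided by the sequence length n (classical mode multiplies by
    100).
    """
    _check_mode(mode)
    if seq.n < 2:
        raise SequenceError("adjacency needs n >= 2")
    diffs = np.diff(seq.ordinals())
    asc = int(np.sum(diffs == 1))
    desc = int(np.sum(diffs == -1))
    scale = 100.0 if mode == "classical" else 1.0
    n = seq.n
    return Adjacency(scale * asc / n, scale * desc / n, scale * (asc + desc) / n)


def _collapsed_ordinals(seq: SymbolSequence) -> np.ndarray:
    # consecutive duplicates collapse before any direction analysis
    o = seq.ordinals()
    keep = np.concatenate(([True], np.diff(o) != 0))
    return o[keep]


def turning_points(seq: SymbolSequence) -> int:
    """Count of direction changes; endpoints are never turning points."""
    if seq.n < 3:
        raise SequenceError("turning points need n >= 3")
    c = _collapsed_ordinals(seq)
    if len(c) < 3:
        return 0
    signs = np.sign(np.diff(c))
    return int(np.sum(signs[1:] != signs[:-1]))


def tpi(seq: SymbolSequence, mode: str = "default") -> float:
    """Observed turning points against the chance expectation (2/3)(n-2).

    Default mode returns the ratio minus 1 (mean-zero convention);
    classical mode returns 100 x the ratio.
    """
    _check_mode(mode)
    tp = turning_points(seq)
    ratio = tp / ((2.0 / 3.0) * (seq.n - 2))
    return 100.0 * ratio if mode == "classical" else ratio - 1.0


def phase_lengths(seq: SymbolSequence) -> tuple[FrequencyTable, FrequencyTable]:
    """Gaps between consecutive turning points, split by phase direction.

    A phase ending at a peak is ascending, one ending at a trough is
    descending.  Gaps are measured on the duplicate-collapsed series.
    Fewer than two turning points yield two empty tables.
    """
    if seq.n < 3:
        raise SequenceError("phase lengths need n >= 3")
    c = _collapsed_ordinals(seq)
    asc: Counter = Counter()
    desc: Counter = Counter()
    if len(c) >= 3:
        signs = np.sign(np.diff(c))
        turns = [j for j in range(1, len(c) - 1) if signs[j] != signs[j - 1]]
        for p, q in zip(turns, turns[1:]):
            # q is a peak when the step into it rises
            (asc if signs[q - 1] > 0 else desc)[q - p] += 1
    return FrequencyTable(dict(asc)), FrequencyTable(dict(desc))


def runs(seq: SymbolSequence, mode: str = "default"):
    """Population variance of the pooled ascending + descending phase lengths.

    The legacy classical computation is not reproducible, so classical
    mode always returns :data:`NA`; so does any input with fewer than
    two phase lengths.
    """
    _check_mode(mode)
    if mode == "classical":
        return NA
    asc, desc = phase_lengths(seq)
    values = asc.expand() + desc.expand()
    if len(values) < 2:
        return NA
    return float(np.var(values))


def repetition_distances(seq: SymbolSequence) -> FrequencyTable:
    """Distances between successive occurrences of the same symbol.

    Each position whose symbol occurred before tallies the distance to
    its most recent prior occurrence; the total is n minus the number of
    distinct symbols observed.
    """
    if seq.n < 2:
        raise SequenceError("repetition distances need n >= 2")
    last: dict = {}
    counts: Counter = Counter()
    for i, tok in enumerate(seq.tokens):
        if tok in last:
            counts[i - last[tok]] += 1
        last[tok] = i
    return FrequencyTable(dict(counts))


RepetitionGap = namedtuple("RepetitionGap", ["mean", "median", "mode"])


def repetition_gap(seq: SymbolSequence, mode: str = "default"):
    """Mean, median and modal repetition distance (identical in both modes).

    The median of an even count is the midpoint average; modal ties
    resolve to the smallest distance.  No repeats at all yields
    :data:`NA`.
    """
    _check_mode(mode)
    table = repetition_distances(seq)
    values = table.expand()
    if not values:
        return NA
    top = max(table.entries.values())
    modal = min(k for k, c in table.entries.items() if c == top)
    return RepetitionGap(
        float(sum(values) / len(values)), float(median(values)), float(modal)
    )


def _lag_repeat_counts(tokens, lags: tuple[int, ...]) -> dict[int, int]:
    last: dict = {}
    counts = {g: 0 for g in lags}
    for i, tok in enumerate(tokens):
        if tok in last:
            gap = i - last[tok]
            if gap in counts:
                counts[gap] += 1
        last[tok] = i
    return counts


@lru_cache(maxsize=64)
def _phi_null(
    n: int, a: int, lags: tuple[int, ...], reps: int, seed: int
) -> dict[int, tuple[float, float]]:
    """Monte-Carlo mean/sd of per-lag repeat counts under the IID uniform null."""
    rng = np.random.default_rng(seed)
    sims = {g: np.empty(reps) for g in lags}
    for r in range(reps):
        draw = rng.integers(0, a, size=n)
        counts = _lag_repeat_counts(draw.tolist(), lags)
        for g in lags:
            sims[g][r] = counts[g]
    return {g: (float(np.mean(sims[g])), float(np.std(sims[g]))) for g in lags}


def phi_indices(
    seq: SymbolSequence,
    lags: tuple[int, ...] = DEFAULT_PHI_LAGS,
    reps: int = 1000,
    seed: int = 0,
    mode: str = "default",
) -> dict:
    """Standardised repeat count per lag: mean 0 under the IID null, unbounded.

    For each lag ``g`` the observed count of repetition distances equal
    to ``g`` is centred and scaled by a seeded Monte-Carlo estimate of
    its null mean and standard deviation (``reps`` IID uniform draws of
    the same length and alphabet size; the null is cached per
    configuration).  Identical in both modes.  Lags at or beyond the
    sequence length map to :data:`NA`.
    """
    _check_mode(mode)
    lags = tuple(int(g) for g in lags)
    observed = _lag_repeat_counts(list(seq.tokens), lags)
    null = _phi_null(seq.n, seq.alphabet.size, lags, int(reps), int(seed))
    out: dict = {}
    for g in lags:
        if g >= seq.n:
            out[g] = NA
            continue
        mu, sd = null[g]
        out[g] = NA if sd == 0.0 else (observed[g] - mu) / sd
    return out


def response_frequencies(seq: SymbolSequence) -> FrequencyTable:
    """Count per alphabet symbol, including zeros for unused alternatives."""
    counts = Counter(seq.tokens)
    return FrequencyTable({t: counts.get(t, 0) for t in seq.alphabet.alternatives})


@dataclass
class RandomizationResult:
    """All requested measure values for one sequence, in one scaling mode."""

    mode: str
    values: dict

    def __getitem__(self, name: str):
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def keys(self):
        return self.values.keys()


def all_rng(
    seq: SymbolSequence,
    mode: str = "default",
    enabled: tuple[str, ...] | None = None,
    phi_lags: tuple[int, ...] = DEFAULT_PHI_LAGS,
    phi_reps: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Compute every enabled randomization measure for one sequence.

    A per-measure precondition failure records the :data:`NA` marker and
    never aborts the remaining measures.
    """
    _check_mode(mode)
    if enabled is None:
        enabled = MEASURES
    enabled = tuple(enabled)
    unknown = set(enabled) - set(MEASURES)
    if unknown:
        raise ValueError(
            f"unknown measures {sorted(unknown)}; valid names: {', '.join(MEASURES)}"
        )
    if not enabled:
        raise ValueError("at least one measure must be enabled")

    recipes = {
        "redundancy": lambda: redundancy(seq, mode),
        "rng": lambda: rng_index(seq, mode),
        "rng2": lambda: rng2_index(seq, mode),
        "rf": lambda: response_frequencies(seq),
        "coupon": lambda: coupon(seq, mode),
        "nsq": lambda: nsq(seq, mode),
        "fod": lambda: fod_table(seq),
        "adjacency": lambda: adjacency(seq, mode),
        "tpi": lambda: tpi(seq, mode),
        "phase_lengths": lambda: phase_lengths(seq),
        "runs": lambda: runs(seq, mode),
        "rep_distance": lambda: repetition_distances(seq),
        "rep_gap": lambda: repetition_gap(seq, mode),
        "phi": lambda: phi_indices(seq, phi_lags, phi_reps, seed, mode),
    }
    values: dict = {}
    for name in MEASURES:
        if name in enabled:
            try:
                values[name] = recipes[name]()
            except SequenceError:
                values[name] = NA
    return RandomizationResult(mode, values)
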