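"""Categorical auto-recurrence plots and the nine RQA measures.

A recurrence plot marks every cell (i, j), i != j, where the sequence
holds the same token at both positions (exact match — on categorical
data any radius below 1 behaves identically).  The main diagonal is the
trivial line of self-identity: it is excluded from the recurrence rate,
never contributes diagonal lines, and splits vertical runs.

Default parameters follow the categorical-series policy: embedding
dimension 1, delay 1, minimal diagonal and vertical line length 2,
exact-match radius.  Embeddings above 1 are supported as standard delay
embedding over the ordinal codes.

:func:`brute_force_oracle` recomputes all nine measures cell-by-cell
with no shared code, as an independent verification path.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .randomization_measures import NA
from .sequence_model import FrequencyTable, SequenceError, SymbolSequence

__all__ = [
    "RQAParams",
    "RecurrencePlot",
    "LineHistogram",
    "RQAResult",
    "recurrence_matrix",
    "rr",
    "diagonal_line_hist",
    "vertical_line_hist",
    "rqa_measures",
    "brute_force_oracle",
    "render_text",
    "render_plot",
    "RQA_COLUMNS",
]

RQA_COLUMNS = ("RR", "DET", "Lmax", "L", "Lentr", "LAM", "Vmax", "TT", "Ventr")


@dataclass(frozen=True)
class RQAParams:
    """Recurrence parameters; the defaults are the supported, tested path."""

    embedding_dim: int = 1
    delay: int = 1
    min_diag: int = 2
    min_vert: int = 2
    radius: float = 0.1

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.delay < 1:
            raise SequenceError("embedding_dim and delay must be >= 1")
        if self.min_diag < 1 or self.min_vert < 1:
            raise SequenceError("minimal line lengths must be >= 1")
        if not self.radius < 1:
            raise SequenceError(
                "radius must be < 1 so only exact matches count as recurrent"
            )


@dataclass
class RecurrencePlot:
    """Boolean N x N recurrence structure, symmetric, main diagonal excluded."""

    matrix: np.ndarray
    diagonal_excluded: bool = True

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_recurrent(self) -> int:
        return int(self.matrix.sum())

    def cells(self) -> set[tuple[int, int]]:
        """Recurrent cells as 1-based (row, column) pairs."""
        rows, cols = np.nonzero(self.matrix)
        return {(int(i) + 1, int(j) + 1) for i, j in zip(rows, cols)}


@dataclass
class LineHistogram:
    """Counts of maximal diagonal or vertical recurrent run lengths."""

    orientation: str
    counts: FrequencyTable


def recurrence_matrix(seq: SymbolSequence, params: RQAParams | None = None) -> RecurrencePlot:
    """Exact-match auto-recurrence plot of the (optionally embedded) sequence."""
    params = params or RQAParams()
    codes = seq.ordinals()
    m, tau = params.embedding_dim, params.delay
    span = (m - 1) * tau
    n_emb = len(codes) - span
    if n_emb < 2:
        raise SequenceError(
            f"sequence too short (n={len(codes)}) for embedding m={m}, delay={tau}"
        )
    embedded = np.stack([codes[k * tau : k * tau + n_emb] for k in range(m)], axis=1)
    matrix = (embedded[:, None, :] == embedded[None, :, :]).all(axis=2)
    np.fill_diagonal(matrix, False)
    return RecurrencePlot(matrix, diagonal_excluded=True)


def rr(rp: RecurrencePlot) -> float:
    """Off-diagonal recurrent cells divided by N^2."""
    return rp.n_recurrent / (rp.size * rp.size)


def _run_lengths(mask: np.ndarray) -> list[int]:
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask.astype(bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return (edges[1::2] - edges[::2]).tolist()


def diagonal_line_hist(rp: RecurrencePlot) -> LineHistogram:
    """Maximal runs parallel to the main diagonal, both triangles, diagonal excluded."""
    counts: Counter = Counter()
    n = rp.size
    for offset in range(-(n - 1), n):
        if offset == 0:
            continue
        counts.update(_run_lengths(np.diagonal(rp.matrix, offset)))
    return LineHistogram("diagonal", FrequencyTable(dict(counts)))


def vertical_line_hist(rp: RecurrencePlot) -> LineHistogram:
    """Maximal runs of consecutive recurrent rows per column; the diagonal splits runs."""
    counts: Counter = Counter()
    for j in range(rp.size):
        counts.update(_run_lengths(rp.matrix[:, j]))
    return LineHistogram("vertical", FrequencyTable(dict(counts)))


@dataclass
class RQAResult:
    """The nine recurrence measures; NA marks empty above-threshold histograms."""

    rr: float
    det: float
    lmax: object
    lmean: object
    lentr: object
    lam: float
    vmax: object
    tt: object
    ventr: object

    def as_dict(self) -> dict:
        return {
            "RR": self.rr,
            "DET": self.det,
            "Lmax": self.lmax,
            "L": self.lmean,
            "Lentr": self.lentr,
            "LAM": self.lam,
            "Vmax": self.vmax,
            "TT": self.tt,
            "Ventr": self.ventr,
        }


def _line_stats(hist: LineHistogram, min_len: int):
    """(proportion on lines >= min_len, max, mean, natural-log entropy)."""
    lengths = hist.counts.entries
    all_points = sum(l * c for l, c in lengths.items())
    selected = {l: c for l, c in lengths.items() if l >= min_len}
    sel_points = sum(l * c for l, c in selected.items())
    sel_lines = sum(selected.values())
    proportion = sel_points / all_points if all_points else 0.0
    if sel_lines == 0:
        return proportion, NA, NA, NA
    longest = float(max(selected))
    mean = sel_points / sel_lines
    entropy = -sum(
        (c / sel_lines) * math.log(c / sel_lines) for c in selected.values()
    ) or 0.0  # avoid -0.0 for point masses
    return proportion, longest, mean, entropy


def rqa_measures(seq: SymbolSequence, params: RQAParams | None = None) -> RQAResult:
    """All nine recurrence measures of a sequence under the given parameters."""
    params = params or RQAParams()
    rp = recurrence_matrix(seq, params)
    det, lmax, lmean, lentr = _line_stats(diagonal_line_hist(rp), params.min_diag)
    lam, vmax, tt, ventr = _line_stats(vertical_line_hist(rp), params.min_vert)
    return RQAResult(rr(rp), det, lmax, lmean, lentr, lam, vmax, tt, ventr)


def brute_force_oracle(seq: SymbolSequence, params: RQAParams | None = None) -> RQAResult:
    """Independent reference: full matrix materialised and scanned cell-by-cell.

    Shares no code with :func:`rqa_measures`; intended for verification
    at test scale (N up to a few hundred).
    """
    params = params or RQAParams()
    m, tau = params.embedding_dim, params.delay
    toks = list(seq.tokens)
    span = (m - 1) * tau
    n = len(toks) - span
    if n < 2:
        raise SequenceError("sequence too short for the requested embedding")
    vectors = [tuple(toks[i + k * tau] for k in range(m)) for i in range(n)]
    mat = [[i != j and vectors[i] == vectors[j] for j in range(n)] for i in range(n)]

    recurrent = 0
    for i in range(n):
        for j in range(n):
            if mat[i][j]:
                recurrent += 1
    rate = recurrent / (n * n)

    diag_lengths: list[int] = []
    for offset in range(1, n):
        for start_i, start_j in ((0, offset), (offset, 0)):
            run = 0
            for k in range(n - offset):
                if mat[start_i + k][start_j + k]:
                    run += 1
                else:
                    if run:
                        diag_lengths.append(run)
                    run = 0
            if run:
                diag_lengths.append(run)

    vert_lengths: list[int] = []
    for j in range(n):
        run = 0
        for i in range(n):
            if mat[i][j]:
                run += 1
            else:
                if run:
                    vert_lengths.append(run)
                run = 0
        if run:
            vert_lengths.append(run)

    def stats(lengths: list[int], threshold: int):
        total = sum(lengths)
        kept = [l for l in lengths if l >= threshold]
        prop = sum(kept) / total if total else 0.0
        if not kept:
            return prop, NA, NA, NA
        dist = Counter(kept)
        probs = [c / len(kept) for c in dist.values()]
        ent = -sum(p * math.log(p) for p in probs) or 0.0
        return prop, float(max(kept)), sum(kept) / len(kept), ent

    det, lmax, lmean, lentr = stats(diag_lengths, params.min_diag)
    lam, vmax, tt, ventr = stats(vert_lengths, params.min_vert)
    return RQAResult(rate, det, lmax, lmean, lentr, lam, vmax, tt, ventr)


def render_text(rp: RecurrencePlot, mark: str = "#", blank: str = ".") -> str:
    """Plain-text grid rendering, one character per cell, row 1 on top."""
    return "\n".join(
        "".join(mark if rp.matrix[i, j] else blank for j in range(rp.size))
        for i in range(rp.size)
    )


def render_plot(rp: RecurrencePlot, target=None):
    """Render a recurrence plot as text (default) or an image file.

    With no target the text grid is returned; a ``.txt`` target receives
    the grid, any other extension is saved through matplotlib.
    """
    if target is None:
        return render_text(rp)
    path = Path(target)
    if path.suffix in ("", ".txt"):
        path.write_text(render_text(rp) + "\n", encoding="utf-8")
        return path
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rp.matrix, cmap="binary", origin="lower", interpolation="none")
    ax.set_xlabel("position")
    ax.set_ylabel("position")
    ax.set_title(f"auto-recurrence plot (N={rp.size})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
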