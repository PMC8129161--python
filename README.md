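# randseq

Measurement suite for random-generation task performance on categorical
response sequences: the thirteen classical randomization measures
(redundancy, digram-entropy indices RNG/RNG2, null-score quotient,
coupon score, first-order differences, adjacency, turning-point index,
phase lengths, runs, repetition distance/gap, phi indices) plus nine
auto-recurrence quantification (RQA) measures (RR, DET, Lmax, Lmean,
Lentr, LAM, Vmax, TT, Ventr) computed from exact-match categorical
recurrence plots.

Every measure supports two output conventions:

* **default** — modernised proportion scale (values in [0, 1] where
  applicable, mean-zero turning-point index), never pairing the sequence
  end back to its start;
* **classical** — legacy percentage scale, with end-to-start digram
  wrapping for the lag-1 digram-entropy index only. Runs has no
  reproducible classical value and is reported as `NA` in that mode.

RQA defaults follow the categorical-series policy: embedding dimension
1, delay 1, minimal line length 2, radius below 1 (exact match). The
main diagonal is excluded from the recurrence rate, contributes no
diagonal lines, and splits vertical runs.

## Library

```python
import randseq as rs

seq = rs.make_sequence([3, 1, 4, 1, 5, 9, 2, 6], min_scale=1, max_scale=9)
result = rs.all_rng(seq, mode="default")        # all randomization measures
rqa = rs.rqa_measures(seq)                      # the nine recurrence measures
coin = rs.make_sequence(["head", "tail", "head"], alternatives=["head", "tail"])
```

Deterministic fixtures with exact constraint counts (used by the
acceptance suite) come from `rs.construct_fixture`, e.g. a length-50
digit sequence with exactly 33 turning points:

```python
fx = rs.construct_fixture("turning_points", n=50, tp=33)
rs.tpi(fx, "classical")   # 103.125
```

## Command line

One sequence per input line, comma- or whitespace-delimited tokens:

```sh
randseq run sequences.csv --min-scale 1 --max-scale 9 --rqa --out report.csv
randseq run letters.txt --alternatives letters --results classical --format json
randseq measure coupon "1,2,3" --min-scale 1 --max-scale 3
```

CSV output is a long-format table (one row per sequence per measure
component, 3-decimal rendering, `NA` for not-computable values) plus a
nine-column RQA table (`<out>_rqa.csv`); JSON keeps full precision.
`--seed` fixes the phi-index resampling, making re-runs byte-identical.
`--plot DIR` writes one recurrence-plot image per sequence.

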