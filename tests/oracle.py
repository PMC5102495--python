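"""Independent brute-force oracle for affine-gap global alignment.

Enumerates every monotone alignment path explicitly (no dynamic
programming, no memoisation) and scores it column by column, tracking
gap runs.  Exponential, usable only for sequences of length <= ~7."""

from bovig.align import ScoringScheme, score_pair


def enumerate_alignments(a: str, b: str):
    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            yield cols
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            yield from rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            yield from rec(i, j + 1, cols + [("-", b[j])])

    yield from rec(0, 0, [])


def score_alignment(cols, scheme: ScoringScheme) -> float:
    total = 0.0
    open_gap = None  # which row the current gap run sits in
    for x, y in cols:
        if x == "-":
            total += scheme.gap_extend if open_gap == "a" else scheme.gap_open
            open_gap = "a"
        elif y == "-":
            total += scheme.gap_extend if open_gap == "b" else scheme.gap_open
            open_gap = "b"
        else:
            total += score_pair(x, y, scheme)
            open_gap = None
    return total


def brute_force_best_score(a: str, b: str, scheme: ScoringScheme) -> float:
    return max(score_alignment(c, scheme) for c in enumerate_alignments(a, b))
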