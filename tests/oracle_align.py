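"""Brute-force pairwise-alignment oracles.

Independent of the dynamic-programming implementation under test: every
possible gapped alignment is enumerated recursively and scored directly.
Affine gaps cost ``gap_open`` for the first position of a run and
``gap_extend`` for each further position; in the global (needle
convention) oracle, runs touching either end of the alignment are free.
Exponential — only for short sequences.
"""

from __future__ import annotations

from collections.abc import Iterator


def _enumerate_ops(m: int, n: int) -> Iterator[tuple[str, ...]]:
    """All alignments of lengths (m, n) as op strings over M/A/B.

    M consumes one residue of each; A consumes one of ``a`` (gap in b);
    B consumes one of ``b`` (gap in a).
    """
    if m == 0 and n == 0:
        yield ()
        return
    if m > 0:
        for rest in _enumerate_ops(m - 1, n):
            yield ("A",) + rest
    if n > 0:
        for rest in _enumerate_ops(m, n - 1):
            yield ("B",) + rest
    if m > 0 and n > 0:
        for rest in _enumerate_ops(m - 1, n - 1):
            yield ("M",) + rest


def _score_ops(
    ops, a, b, score_fn, gap_open, gap_extend, free_end_gaps
) -> float:
    total = 0.0
    i = j = 0
    k = 0
    L = len(ops)
    while k < L:
        op = ops[k]
        if op == "M":
            total += score_fn(a[i], b[j])
            i += 1
            j += 1
            k += 1
        else:
            run = 0
            start = k
            while k < L and ops[k] == op:
                run += 1
                k += 1
            if op == "A":
                i += run
            else:
                j += run
            terminal = start == 0 or k == L
            if free_end_gaps and terminal:
                continue
            total -= gap_open + (run - 1) * gap_extend
    return total


def global_score_oracle(a, b, score_fn, gap_open, gap_extend) -> float:
    """Optimal global score, end gaps free, by exhaustive enumeration."""
    return max(
        _score_ops(ops, a, b, score_fn, gap_open, gap_extend, True)
        for ops in _enumerate_ops(len(a), len(b))
    )


def local_score_oracle(a, b, score_fn, gap_open, gap_extend) -> float:
    """Optimal local score (floor 0) over all substring pairs."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for j1 in range(i1, len(a) + 1):
            for i2 in range(len(b) + 1):
                for j2 in range(i2, len(b) + 1):
                    sa, sb = a[i1:j1], b[i2:j2]
                    if not sa or not sb:
                        continue
                    for ops in _enumerate_ops(len(sa), len(sb)):
                        # a local alignment never starts/ends with a gap
                        if ops[0] != "M" or ops[-1] != "M":
                            continue
                        s = _score_ops(
                            ops, sa, sb, score_fn, gap_open, gap_extend, False
                        )
                        best = max(best, s)
    return best
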