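"""Independent oracles used to validate the implementation.

These deliberately share no code with the package: the scanner oracle is a
dynamic-programming enumeration over every (transcript position, seed
offset) pair, and the alignment oracles are a plain Gotoh three-matrix DP
plus, for tiny inputs, exhaustive enumeration of all alignments.
"""

from __future__ import annotations

import numpy as np


def oracle_maximal_matches(
    sequence: str, seed: str, min_match: int
) -> list[tuple[int, int, int]]:
    """All maximal exact matches (start, seed_offset, length) of length >=
    min_match between ``sequence`` and any substring of ``seed``.

    Checks every (i, j) start pair via a suffix-run recurrence
    run[i, j] = eq[i, j] * (1 + run[i+1, j+1]).
    """
    n, k = len(sequence), len(seed)
    if n == 0 or k == 0:
        return []
    t = np.frombuffer(sequence.encode(), dtype=np.uint8)
    s = np.frombuffer(seed.encode(), dtype=np.uint8)
    eq = t[:, None] == s[None, :]
    eq[t == ord("N"), :] = False  # N never matches
    run = np.zeros((n + 1, k + 1), dtype=np.int32)
    for j in range(k - 1, -1, -1):
        run[:n, j] = eq[:, j] * (1 + run[1 : n + 1, j + 1])
    left_maximal = np.ones((n, k), dtype=bool)
    left_maximal[1:, 1:] = ~eq[:-1, :-1]
    starts = np.argwhere(eq & left_maximal & (run[:n, :k] >= min_match))
    return sorted(
        (int(i), int(j), int(run[i, j])) for i, j in starts
    )


def oracle_merge(
    matches: list[tuple[int, int, int]]
) -> list[tuple[int, int, int, int, int]]:
    """Merge overlapping maximal matches into loci.

    Returns (union_start, union_end, best_len, best_seed_offset, best_start)
    per locus; the best constituent is the longest, ties broken by smaller
    seed offset then smaller start.
    """
    loci: list[list] = []
    for i, j, length in sorted(matches):
        if loci and i < loci[-1][1]:
            loci[-1][1] = max(loci[-1][1], i + length)
            cand = (length, -j, -i)
            if cand > loci[-1][2]:
                loci[-1][2] = cand
        else:
            loci.append([i, i + length, (length, -j, -i)])
    return [
        (u0, u1, best[0], -best[1], -best[2]) for u0, u1, best in loci
    ]


def gotoh_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Affine-gap global alignment optimum (score only), three-matrix DP.

    A gap of length L scores gap_open + (L - 1) * gap_extend; end gaps are
    penalized.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def exhaustive_align_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Enumerate every global alignment (exponential; lengths <= ~6 only)."""

    best = float("-inf")

    def walk(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "M")
        if i < len(a):
            walk(i + 1, j, score + (gap_extend if last == "X" else gap_open), "X")
        if j < len(b):
            walk(i, j + 1, score + (gap_extend if last == "Y" else gap_open), "Y")

    walk(0, 0, 0.0, "M")
    return best
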