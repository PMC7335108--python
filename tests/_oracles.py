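"""Independent oracles used by the test suite.

These deliberately use different algorithms from the package: a memoized
top-down recursion and a 0-1 breadth-first search over the edit graph for
the OSA distance, an unrestricted Damerau-Levenshtein for the
triangle-inequality counterexample, and a plain Needleman-Wunsch score DP
for alignment scores.
"""

from __future__ import annotations

import functools
import itertools
from typing import Sequence

import numpy as np
from numba import njit


def osa_recursive(s: Sequence, t: Sequence) -> int:
    """OSA distance by memoized top-down recursion (reference definition)."""
    s, t = tuple(s), tuple(t)

    @functools.lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (s[i - 1] != t[j - 1]),
        )
        if i > 1 and j > 1 and s[i - 1] == t[j - 2] and s[i - 2] == t[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(s), len(t))


def damerau_levenshtein(s: Sequence, t: Sequence) -> int:
    """Unrestricted Damerau-Levenshtein (transpositions may be edited again).

    Distinguishes OSA from the unrestricted distance: for CA vs ABC the
    unrestricted value is 2, OSA is 3.
    """
    s, t = tuple(s), tuple(t)
    alphabet = {c: i for i, c in enumerate(dict.fromkeys(s + t))}
    la, lb = len(s), len(t)
    inf = la + lb
    score = np.zeros((la + 2, lb + 2), dtype=int)
    score[0, :] = inf
    score[:, 0] = inf
    for i in range(la + 1):
        score[i + 1, 1] = i
    for j in range(lb + 1):
        score[1, j + 1] = j
    last_row = {c: 0 for c in alphabet}
    for i in range(1, la + 1):
        last_col = 0
        for j in range(1, lb + 1):
            i1 = last_row[t[j - 1]]
            j1 = last_col
            cost = 0 if s[i - 1] == t[j - 1] else 1
            if cost == 0:
                last_col = j
            score[i + 1, j + 1] = min(
                score[i, j] + cost,
                score[i + 1, j] + 1,
                score[i, j + 1] + 1,
                score[i1, j1] + (i - i1 - 1) + 1 + (j - j1 - 1),
            )
        last_row[s[i - 1]] = i
    return int(score[la + 1, lb + 1])


@njit(cache=False)
def osa_bfs(a: np.ndarray, la: int, b: np.ndarray, lb: int, dist: np.ndarray, dq: np.ndarray) -> int:
    """OSA as a 0-1 BFS shortest path over the edit graph (numba kernel)."""
    INF = 1 << 30
    width = lb + 1
    n = (la + 1) * width
    for s in range(n):
        dist[s] = INF
    head = n
    tail = n
    dist[0] = 0
    dq[tail] = 0
    tail += 1
    goal = n - 1
    while head < tail:
        s = dq[head]
        head += 1
        d = dist[s]
        if s == goal:
            return d
        i = s // width
        j = s - i * width
        if i < la and j < lb and a[i] == b[j]:  # 0-cost match, deque front
            t = s + width + 1
            if d < dist[t]:
                dist[t] = d
                head -= 1
                dq[head] = t
        if i < la and j < lb:
            t = s + width + 1
            if d + 1 < dist[t]:
                dist[t] = d + 1
                dq[tail] = t
                tail += 1
        if i < la:
            t = s + width
            if d + 1 < dist[t]:
                dist[t] = d + 1
                dq[tail] = t
                tail += 1
        if j < lb:
            t = s + 1
            if d + 1 < dist[t]:
                dist[t] = d + 1
                dq[tail] = t
                tail += 1
        if i + 2 <= la and j + 2 <= lb and a[i] == b[j + 1] and a[i + 1] == b[j]:
            t = s + 2 * width + 2
            if d + 1 < dist[t]:
                dist[t] = d + 1
                dq[tail] = t
                tail += 1
    return -1


def all_token_strings(alphabet_size: int, max_length: int) -> tuple[np.ndarray, np.ndarray]:
    """All strings of length <= max_length over an integer alphabet, padded."""
    strings = [
        tup
        for length in range(max_length + 1)
        for tup in itertools.product(range(alphabet_size), repeat=length)
    ]
    padded = np.zeros((len(strings), max(max_length, 1)), dtype=np.int64)
    lengths = np.zeros(len(strings), dtype=np.int64)
    for i, tup in enumerate(strings):
        lengths[i] = len(tup)
        for j, v in enumerate(tup):
            padded[i, j] = v
    return padded, lengths


def exhaustive_osa_disagreements(kernel, alphabet_size: int = 4, max_length: int = 6) -> int:
    """Count disagreements between an OSA kernel and the BFS oracle over
    ALL unordered pairs of token strings up to ``max_length``."""
    padded, lengths = all_token_strings(alphabet_size, max_length)

    @njit(cache=False)
    def sweep(S, L):
        n = S.shape[0]
        maxlen = S.shape[1]
        dist = np.empty((maxlen + 1) * (maxlen + 1), np.int32)
        dq = np.empty(8 * (maxlen + 1) * (maxlen + 1) + 16, np.int64)
        bad = 0
        for i in range(n):
            for j in range(i, n):
                d1 = kernel(S[i][: L[i]], S[j][: L[j]])
                d2 = osa_bfs(S[i], L[i], S[j], L[j], dist, dq)
                if d1 != d2:
                    bad += 1
        return bad

    return int(sweep(padded, lengths))


def nw_score(a: str, b: str, match: int = 1, mismatch: int = 0, gap: int = -1) -> int:
    """Needleman-Wunsch global alignment score under the pipeline's scoring."""
    la, lb = len(a), len(b)
    prev = list(range(0, -(lb + 1), -1))
    for i in range(1, la + 1):
        cur = [-i]
        for j in range(1, lb + 1):
            cur.append(
                max(
                    prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch),
                    prev[j] + gap,
                    cur[j - 1] + gap,
                )
            )
        prev = cur
    return prev[lb]
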