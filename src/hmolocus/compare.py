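"""Landscape comparison: OSA distance, PCoA ordination, representatives.

Gene landscapes are compared with the optimal string alignment (OSA)
distance — the restricted Damerau–Levenshtein distance with unit-cost
insertions, deletions, substitutions and adjacent transpositions, where no
substring is edited more than once. The distance is computed over gene
tokens, not characters, so multi-character tokens cannot alias. OSA
violates the triangle inequality (the classic example: CA -> AC -> ABC
costs 2 via unrestricted edits but OSA(CA, ABC) = 3), which is why the
ordination uses classical scaling (PCoA) with negative-eigenvalue
clamping rather than assuming a metric embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import InvalidInputError, InvalidParameterError
from .landscape import Landscape


@njit(cache=False)
def _osa_kernel(a: np.ndarray, b: np.ndarray) -> int:
    # bottom-up OSA dynamic programme over integer-coded tokens, three rows
    la, lb = a.shape[0], b.shape[0]
    prev2 = np.empty(lb + 1, np.int64)
    prev = np.empty(lb + 1, np.int64)
    cur = np.empty(lb + 1, np.int64)
    for j in range(lb + 1):
        prev[j] = j
    for i in range(1, la + 1):
        cur[0] = i
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = prev[j - 1] + cost
            if prev[j] + 1 < d:
                d = prev[j] + 1
            if cur[j - 1] + 1 < d:
                d = cur[j - 1] + 1
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                if prev2[j - 2] + 1 < d:
                    d = prev2[j - 2] + 1
            cur[j] = d
        tmp = prev2
        prev2 = prev
        prev = cur
        cur = tmp
    return prev[lb]


def _encode_pair(s: Sequence[str], t: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    codes: dict[str, int] = {}
    enc_s = np.array([codes.setdefault(tok, len(codes)) for tok in s], dtype=np.int64)
    enc_t = np.array([codes.setdefault(tok, len(codes)) for tok in t], dtype=np.int64)
    return enc_s, enc_t


def osa_distance(s: Sequence[str], t: Sequence[str]) -> int:
    """Optimal string alignment distance between two token lists."""
    enc_s, enc_t = _encode_pair(list(s), list(t))
    return int(_osa_kernel(enc_s, enc_t))


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal, non-negative ints

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(
    landscapes: Sequence[Landscape], include_other: bool = True
) -> DistanceMatrix:
    """Pairwise OSA distances over landscape token strings.

    With ``include_other=False``, OTHER tokens are dropped from every
    string before comparison (restricting the encoding to recognised
    genes).
    """
    if not landscapes:
        raise InvalidInputError("distance_matrix requires at least one landscape")
    token_lists = [
        list(l.tokens) if include_other else [t for t in l.tokens if t != "OTHER"]
        for l in landscapes
    ]
    codes: dict[str, int] = {}
    encoded = [
        np.array([codes.setdefault(tok, len(codes)) for tok in toks], dtype=np.int64)
        for toks in token_lists
    ]
    n = len(encoded)
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = _osa_kernel(encoded[i], encoded[j])
            values[i, j] = d
            values[j, i] = d
    return DistanceMatrix(ids=[l.landscape_id for l in landscapes], values=values)


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # all n, descending, negatives clamped to zero
    negative_eigenvalues: np.ndarray  # the original negative values, if any


def pcoa(distances: DistanceMatrix, k: int = 2) -> Ordination:
    """Principal coordinates analysis (classical scaling) of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square root of their (clamped) eigenvalues. Negative eigenvalues —
    expected for non-Euclidean distances such as OSA — are clamped to zero
    and reported.
    """
    n = len(distances.ids)
    if not 1 <= k < n:
        raise InvalidParameterError(f"k must satisfy 1 <= k < n items, got k={k}, n={n}")
    d = np.asarray(distances.values, dtype=float)
    d2 = d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    b = (b + b.T) / 2  # guard symmetry against round-off
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # deterministic sign convention: largest-magnitude loading positive
    for col in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, col]))
        if eigvec[pivot, col] < 0:
            eigvec[:, col] = -eigvec[:, col]
    negative = eigval[eigval < 0]
    clamped = np.clip(eigval, 0, None)
    coords = eigvec[:, :k] * np.sqrt(clamped[:k])
    return Ordination(
        ids=list(distances.ids),
        coordinates=coords,
        eigenvalues=clamped,
        negative_eigenvalues=negative,
    )


def representative_landscape(landscapes: Sequence[Landscape]) -> Landscape:
    """Most conserved landscape of a group (e.g. one SGB).

    The landscape whose token string occurs most often; ties broken by
    minimal mean OSA distance to all group members, then by the
    lexicographically smallest token string. Always a member of the group.
    """
    if not landscapes:
        raise InvalidInputError("representative_landscape requires a non-empty group")
    counts: dict[tuple[str, ...], int] = {}
    for l in landscapes:
        counts[l.tokens] = counts.get(l.tokens, 0) + 1
    best_count = max(counts.values())
    candidates = [toks for toks, c in counts.items() if c == best_count]
    if len(candidates) > 1:
        token_lists = [list(l.tokens) for l in landscapes]

        def mean_distance(toks: tuple[str, ...]) -> float:
            return float(
                np.mean([osa_distance(list(toks), other) for other in token_lists])
            )

        scored = sorted(candidates, key=lambda toks: (mean_distance(toks), toks))
        chosen = scored[0]
    else:
        chosen = candidates[0]
    for l in landscapes:
        if l.tokens == chosen:
            return l
    raise AssertionError("unreachable: representative must be a group member")


def representatives_by_group(
    landscapes: Sequence[Landscape], groups: dict[str, str]
) -> dict[str, Landscape]:
    """Representative landscape per group label (landscape_id -> group)."""
    by_group: dict[str, list[Landscape]] = {}
    for l in landscapes:
        group = groups[l.landscape_id]
        by_group.setdefault(group, []).append(l)
    return {g: representative_landscape(ls) for g, ls in sorted(by_group.items())}


# ---------------------------------------------------------------------------
# I/O


def write_distance_matrix(distances: DistanceMatrix, path) -> None:
    distances.to_frame().to_csv(path, sep="\t", index_label="landscape_id")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(ids=list(frame.columns), values=frame.to_numpy(dtype=np.int64))


def write_ordination(ordination: Ordination, coords_path, eigval_path) -> None:
    k = ordination.coordinates.shape[1]
    frame = pd.DataFrame(
        ordination.coordinates,
        index=ordination.ids,
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    frame.to_csv(coords_path, sep="\t", index_label="landscape_id")
    pd.DataFrame(
        {
            "eigenvalue": ordination.eigenvalues,
        }
    ).to_csv(eigval_path, sep="\t", index_label="rank")
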