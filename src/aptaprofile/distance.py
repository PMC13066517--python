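"""Damerau-Levenshtein distances for collapsing near-identical aptamer reads.

Two variants are provided:

* ``unrestricted`` -- the true Damerau-Levenshtein metric (Lowrance-Wagner):
  substitutions, insertions, deletions and transpositions of adjacent
  characters, where a transposed block may be edited again.  This variant
  satisfies the triangle inequality and is the default throughout the
  package.
* ``osa`` -- optimal string alignment, the common "restricted" variant in
  which no substring is edited more than once.  It can exceed the
  unrestricted distance (classic example: ``CA`` -> ``ABC`` is 2
  unrestricted but 3 under OSA) and is *not* a metric.

The hot path (``nearest_within``) is compiled with numba because family
joining evaluates millions of sequence pairs; distances are computed over
uint8-encoded strings with early abandon once every cell of a DP row
exceeds the cutoff.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dl_distance", "encode", "encode_many", "nearest_within"]

_MAX_ALPHABET = 256


def encode(seq: str) -> np.ndarray:
    """Encode a string as a uint8 code array (raw byte values)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def encode_many(seqs) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a zero-padded matrix plus a length vector."""
    seqs = list(seqs)
    n = len(seqs)
    max_len = max((len(s) for s in seqs), default=0)
    mat = np.zeros((n, max_len), dtype=np.uint8)
    lens = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(seqs):
        b = s.encode("ascii")
        mat[i, : len(b)] = np.frombuffer(b, dtype=np.uint8)
        lens[i] = len(b)
    return mat, lens


@njit(cache=True)
def _osa(a, la, b, lb):  # pragma: no cover - exercised through wrappers
    d = np.empty((la + 1, lb + 1), dtype=np.int64)
    for i in range(la + 1):
        d[i, 0] = i
    for j in range(lb + 1):
        d[0, j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            best = d[i - 1, j - 1] + cost
            if d[i, j - 1] + 1 < best:
                best = d[i, j - 1] + 1
            if d[i - 1, j] + 1 < best:
                best = d[i - 1, j] + 1
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                if d[i - 2, j - 2] + 1 < best:
                    best = d[i - 2, j - 2] + 1
            d[i, j] = best
    return d[la, lb]


@njit(cache=True)
def _dl(a, la, b, lb):  # pragma: no cover - exercised through wrappers
    # Lowrance-Wagner dynamic programme over a (la+2) x (lb+2) table with
    # sentinel row/column holding an unreachable maximum.
    maxdist = la + lb
    d = np.empty((la + 2, lb + 2), dtype=np.int64)
    d[0, 0] = maxdist
    for i in range(la + 1):
        d[i + 1, 0] = maxdist
        d[i + 1, 1] = i
    for j in range(lb + 1):
        d[0, j + 1] = maxdist
        d[1, j + 1] = j
    da = np.zeros(_MAX_ALPHABET, dtype=np.int64)  # last row where char occurred in a
    for i in range(1, la + 1):
        db = 0  # last column in b matching a[i-1] so far in this row
        for j in range(1, lb + 1):
            k = da[b[j - 1]]
            l = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            best = d[i, j] + cost  # substitution / match
            if d[i + 1, j] + 1 < best:  # insertion
                best = d[i + 1, j] + 1
            if d[i, j + 1] + 1 < best:  # deletion
                best = d[i, j + 1] + 1
            trans = d[k, l] + (i - k - 1) + 1 + (j - l - 1)  # transposition
            if trans < best:
                best = trans
            d[i + 1, j + 1] = best
        da[a[i - 1]] = i
    return d[la + 1, lb + 1]


@njit(cache=True)
def _dl_bounded(a, la, b, lb, cutoff):  # pragma: no cover
    """Unrestricted DL distance, or cutoff+1 once it provably exceeds cutoff."""
    if la - lb > cutoff or lb - la > cutoff:
        return cutoff + 1
    maxdist = la + lb
    d = np.empty((la + 2, lb + 2), dtype=np.int64)
    d[0, 0] = maxdist
    for i in range(la + 1):
        d[i + 1, 0] = maxdist
        d[i + 1, 1] = i
    for j in range(lb + 1):
        d[0, j + 1] = maxdist
        d[1, j + 1] = j
    da = np.zeros(_MAX_ALPHABET, dtype=np.int64)
    for i in range(1, la + 1):
        db = 0
        row_min = maxdist
        for j in range(1, lb + 1):
            k = da[b[j - 1]]
            l = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            best = d[i, j] + cost
            if d[i + 1, j] + 1 < best:
                best = d[i + 1, j] + 1
            if d[i, j + 1] + 1 < best:
                best = d[i, j + 1] + 1
            trans = d[k, l] + (i - k - 1) + 1 + (j - l - 1)
            if trans < best:
                best = trans
            d[i + 1, j + 1] = best
            if best < row_min:
                row_min = best
        da[a[i - 1]] = i
        # Row minima of the DL table are non-decreasing in i, so once a full
        # row exceeds the cutoff the final distance must too.
        if row_min > cutoff:
            return cutoff + 1
    dist = d[la + 1, lb + 1]
    return dist if dist <= cutoff else cutoff + 1


@njit(cache=True)
def nearest_within(query, qlen, reps, rep_lens, n_reps, cutoff):  # pragma: no cover
    """Index and distance of the first representative within ``cutoff``.

    Representatives are scanned in storage order; strictly smaller distances
    win, so ties resolve to the earliest (highest-abundance) representative.
    Returns (-1, cutoff+1) when none qualifies.
    """
    best_idx = -1
    best_dist = cutoff + 1
    for r in range(n_reps):
        rl = rep_lens[r]
        diff = qlen - rl if qlen >= rl else rl - qlen
        if diff >= best_dist:
            continue
        dist = _dl_bounded(query, qlen, reps[r], rl, best_dist - 1)
        if dist < best_dist:
            best_dist = dist
            best_idx = r
            if best_dist == 0:
                break
    return best_idx, best_dist


def dl_distance(a: str, b: str, *, restricted: bool = False) -> int:
    """Edit distance between two sequences.

    Parameters
    ----------
    a, b
        Sequences (any strings; empty strings are valid).
    restricted
        If True use the optimal-string-alignment (restricted) variant;
        otherwise the unrestricted Damerau-Levenshtein metric.
    """
    ea, eb = encode(a), encode(b)
    if restricted:
        return int(_osa(ea, len(ea), eb, len(eb)))
    return int(_dl(ea, len(ea), eb, len(eb)))
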