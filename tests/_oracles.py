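"""Independent brute-force oracles used to pin down expected values.

These are deliberately naive: recursive definitions with explicit searches
over all decompositions, plus a Dijkstra over the raw edit graph for tiny
strings.  They share no code with the package implementations.
"""

from functools import lru_cache
import heapq


def dl_oracle(a: str, b: str) -> int:
    """Unrestricted Damerau-Levenshtein by recursion on prefixes with a
    brute-force search over all transposition anchor pairs (k, l): a
    transposition matches a[k] with b[j-1] and a[i-1] with b[l], deleting
    and inserting everything in between."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = d(i - 1, j - 1) + (a[i - 1] != b[j - 1])
        best = min(best, d(i - 1, j) + 1, d(i, j - 1) + 1)
        for k in range(1, i):
            if a[k - 1] != b[j - 1]:
                continue
            for l in range(1, j):
                if b[l - 1] != a[i - 1]:
                    continue
                best = min(best, d(k - 1, l - 1) + (i - k - 1) + 1 + (j - l - 1))
        return best

    return d(len(a), len(b))


def osa_oracle(a: str, b: str) -> int:
    """Restricted (optimal string alignment) variant by plain recursion."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = d(i - 1, j - 1) + (a[i - 1] != b[j - 1])
        best = min(best, d(i - 1, j) + 1, d(i, j - 1) + 1)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def edit_graph_oracle(a: str, b: str, alphabet: str) -> int:
    """Operational definition: Dijkstra over single edits (substitution,
    insertion, deletion, adjacent transposition) from a to b.  Only viable
    for tiny strings; lengths are bounded to keep the state space finite."""
    max_len = max(len(a), len(b)) + 1
    target = b
    dist = {a: 0}
    heap = [(0, a)]
    while heap:
        c, s = heapq.heappop(heap)
        if s == target:
            return c
        if c > dist.get(s, 1 << 30):
            continue
        neighbours = set()
        for i in range(len(s)):
            for ch in alphabet:
                if ch != s[i]:
                    neighbours.add(s[:i] + ch + s[i + 1:])  # substitution
            neighbours.add(s[:i] + s[i + 1:])  # deletion
        if len(s) < max_len:
            for i in range(len(s) + 1):
                for ch in alphabet:
                    neighbours.add(s[:i] + ch + s[i:])  # insertion
        for i in range(len(s) - 1):
            neighbours.add(s[:i] + s[i + 1] + s[i] + s[i + 2:])  # transposition
        for t in neighbours:
            if c + 1 < dist.get(t, 1 << 30):
                dist[t] = c + 1
                heapq.heappush(heap, (c + 1, t))
    raise RuntimeError("unreachable")


def bh_stepup_oracle(pvalues):
    """Literal BH step-up: adjusted p_(i) = min_{j >= i} m * p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order):
        best = min(
            m * pvalues[order[j]] / (j + 1) for j in range(rank_pos, m)
        )
        adjusted[idx] = min(best, 1.0)
    return adjusted
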