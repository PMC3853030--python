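"""Numba-accelerated distance kernels.

These kernels exist purely for speed: generating a length-8 code touches
millions of pairwise distances, and the per-read decoders are run 10^5+
times in the simulations.  Their results are required to be bit-identical
to the plain pure-Python implementations in :mod:`seqlev.metrics`, which
remain the canonical definitions (this identity is asserted in the test
suite).  When numba is unavailable the same code runs un-jitted.

Metric codes: 0 = Hamming, 1 = Levenshtein, 2 = Sequence-Levenshtein.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


METRIC_CODES = {"hamming": 0, "levenshtein": 1, "sequence_levenshtein": 2}


@njit(cache=False)
def pair_distance(a: np.ndarray, b: np.ndarray, metric: int) -> int:
    """Distance between two encoded words under the selected metric.

    Hamming assumes equal lengths (enforced by callers).  Levenshtein is
    the bottom-right cell of the Wagner-Fischer matrix; Sequence-Levenshtein
    is the minimum over the matrix's last row and last column, i.e. the
    cheapest way to edit one word into the other when a trailing
    truncation/elongation step is free.
    """
    la = a.shape[0]
    lb = b.shape[0]
    if metric == 0:
        d = 0
        for i in range(la):
            if a[i] != b[i]:
                d += 1
        return d
    prev = np.empty(lb + 1, dtype=np.int64)
    cur = np.empty(lb + 1, dtype=np.int64)
    for j in range(lb + 1):
        prev[j] = j
    min_last_col = lb  # D[0][lb]
    for i in range(1, la + 1):
        cur[0] = i
        for j in range(1, lb + 1):
            c = prev[j - 1]
            if a[i - 1] != b[j - 1]:
                c += 1
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            cur[j] = c
        if cur[lb] < min_last_col:
            min_last_col = cur[lb]
        tmp = prev
        prev = cur
        cur = tmp
    if metric == 1:
        return prev[lb]
    m = min_last_col
    for j in range(lb + 1):
        if prev[j] < m:
            m = prev[j]
    return m


@njit(cache=False)
def pair_at_least(a: np.ndarray, b: np.ndarray, dmin: int, metric: int) -> bool:
    """Decide whether ``distance(a, b) >= dmin`` (same answer as the full DP).

    Uses the standard banded DP (Ukkonen): any alignment path with cost
    < dmin stays within the diagonal band |i - j| <= dmin - 1, so cells
    outside the band can be treated as "large" without changing the
    decision, and the scan aborts as soon as every reachable boundary
    value is provably >= dmin.
    """
    la = a.shape[0]
    lb = b.shape[0]
    if metric == 0:
        d = 0
        for i in range(la):
            if a[i] != b[i]:
                d += 1
                if d >= dmin:
                    return True
        return False
    if dmin <= 0:
        return True
    h = dmin - 1  # band half-width
    if metric == 1 and (la - lb > h or lb - la > h):
        return True  # distance >= |la - lb| > h
    if la == 0 or lb == 0:
        if metric == 1:
            return la + lb >= dmin
        return False  # the empty word is a prefix of everything: d_SL = 0
    big = dmin + 1  # stands in for any value provably >= dmin
    prev = np.empty(lb + 1, dtype=np.int64)
    cur = np.empty(lb + 1, dtype=np.int64)
    for j in range(lb + 1):
        prev[j] = j if j <= h else big
    min_last_col = prev[lb]
    for i in range(1, la + 1):
        lo = i - h if i - h > 1 else 1
        hi = i + h if i + h < lb else lb
        if lo > hi:
            # Band left the matrix: every remaining cell is >= dmin, but for
            # Sequence-Levenshtein the last-column cells already passed may
            # hold the minimum (b much shorter than a).
            return min_last_col >= dmin
        cur[lo - 1] = i if lo == 1 and i <= h else big
        row_min = big
        for j in range(lo, hi + 1):
            c = prev[j - 1]
            if a[i - 1] != b[j - 1]:
                c += 1
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            if c > big:
                c = big
            cur[j] = c
            if c < row_min:
                row_min = c
        if hi < lb:
            cur[hi + 1] = big  # out-of-band sentinel read by the next row
        if hi == lb and cur[lb] < min_last_col:
            min_last_col = cur[lb]
        if row_min >= dmin and (metric == 1 or min_last_col >= dmin):
            return True
        tmp = prev
        prev = cur
        cur = tmp
    if metric == 1:
        return prev[lb] >= dmin
    m = min_last_col
    for j in range(lo, hi + 1):
        if prev[j] < m:
            m = prev[j]
    return m >= dmin


@njit(cache=False)
def distances_to_pool(query: np.ndarray, pool: np.ndarray, metric: int) -> np.ndarray:
    """Distances from one encoded word to every row of an encoded matrix."""
    out = np.empty(pool.shape[0], dtype=np.int64)
    for r in range(pool.shape[0]):
        out[r] = pair_distance(query, pool[r], metric)
    return out


@njit(cache=False)
def greedy_scan(cands: np.ndarray, seed: np.ndarray, dmin: int, metric: int) -> np.ndarray:
    """Greedy closure over a candidate matrix.

    Scans ``cands`` row by row (callers supply lexicographic order) and
    accepts each candidate whose distance to every already-accepted word
    (seed first) is >= ``dmin``.  Returns a boolean mask over ``cands``.
    A candidate identical to an accepted word has distance 0 and is thus
    rejected automatically.

    Accepted words are checked newest-first: conflicts usually involve a
    lexicographically nearby (hence recently accepted) word, so this
    rejects early.  The acceptance decision is a conjunction, so the
    check order cannot change the result.
    """
    n_cands, n = cands.shape
    n_seed = seed.shape[0]
    accepted = np.empty((n_seed + n_cands, n), dtype=np.uint8)
    for s in range(n_seed):
        accepted[s] = seed[s]
    count = n_seed
    mask = np.zeros(n_cands, dtype=np.bool_)
    for idx in range(n_cands):
        ok = True
        for r in range(count - 1, -1, -1):
            if not pair_at_least(cands[idx], accepted[r], dmin, metric):
                ok = False
                break
        if ok:
            accepted[count] = cands[idx]
            count += 1
            mask[idx] = True
    return mask


def warmup() -> None:
    """Trigger JIT compilation once so timings elsewhere are clean."""
    a = np.array([0, 1, 2, 3], dtype=np.uint8)
    b = np.array([0, 1], dtype=np.uint8)
    for m in (0, 1, 2):
        if m == 0:
            pair_distance(a, a, m)
            pair_at_least(a, a, 2, m)
        else:
            pair_distance(a, b, m)
            pair_at_least(a, b, 2, m)
    distances_to_pool(a, a[None, :], 1)
    greedy_scan(a[None, :], a[None, :], 1, 2)
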