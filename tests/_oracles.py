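"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's alignment engine: the edit-distance
oracle is a plain dynamic program (vectorized with numpy row ops, but
mathematically the full DP over every window of every reference), and the
trimming oracle enumerates every candidate window.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Minimum unit-cost edit distance of ``query`` (end-to-end) against any
    window of ``target`` (free start/end in the target)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    n = len(t)
    j = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    base = np.empty(n + 1, dtype=np.int32)
    for i in range(1, len(q) + 1):
        base[0] = i
        mism = (t != q[i - 1]).astype(np.int32)
        np.minimum(prev[:-1] + mism, prev[1:] + 1, out=base[1:])
        # horizontal propagation D[i][j] = min_{j'<=j} base[j'] + (j - j')
        prev = np.minimum.accumulate(base - j) + j
    return int(prev.min())


def semiglobal_edit_distance_batch(queries: list[str], target: str) -> np.ndarray:
    """Vectorized over many equal-length queries; same DP as above."""
    L = len(queries[0])
    assert all(len(q) == L for q in queries)
    Q = np.frombuffer("".join(queries).encode(), dtype=np.uint8).reshape(-1, L)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m, n = Q.shape[0], len(t)
    j = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros((m, n + 1), dtype=np.int32)
    base = np.empty((m, n + 1), dtype=np.int32)
    for i in range(1, L + 1):
        base[:, 0] = i
        mism = (t[None, :] != Q[:, i - 1, None]).astype(np.int32)
        np.minimum(prev[:, :-1] + mism, prev[:, 1:] + 1, out=base[:, 1:])
        prev = np.minimum.accumulate(base - j, axis=1) + j
    return prev.min(axis=1)


def best_edit_distance_both_strands(query: str, targets: list[str]) -> int:
    """Minimum over all references and both strands."""
    return min(
        min(semiglobal_edit_distance(q, t) for t in targets)
        for q in (query, revcomp(query))
    )


def best_edit_distance_batch(queries: list[str], targets: list[str]) -> np.ndarray:
    """Batched minimum over all references and both strands."""
    out = None
    for strand_queries in (queries, [revcomp(q) for q in queries]):
        for t in targets:
            d = semiglobal_edit_distance_batch(strand_queries, t)
            out = d if out is None else np.minimum(out, d)
    return out


def trim_oracle(quals: list[int], q_threshold: int) -> tuple[int, int]:
    """Enumerate every window whose first and last base exceed the quality
    threshold and return the (start, end) of the longest one ((0, 0) if no
    base survives). Ties cannot occur: the maximal window is unique."""
    q = np.asarray(quals)
    good = q > q_threshold
    n = len(q)
    if not good.any():
        return (0, 0)
    starts = np.arange(n)[:, None]
    ends = np.arange(1, n + 1)[None, :]
    valid = good[:, None] & good[None, :] & (starts < ends)  # good[i], good[j-1]
    lengths = np.where(valid, ends - starts, 0)
    i, jm1 = np.unravel_index(np.argmax(lengths), lengths.shape)
    return int(i), int(jm1) + 1
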