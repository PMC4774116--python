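"""Canonical k-mer helpers shared by the contaminant tagger and the viral mapper.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, which makes indexes strand-insensitive. Windows containing 'N'
are never indexed or matched.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> list[tuple[int, str]]:
    """All (offset, canonical k-mer) pairs of ``seq``; N-containing windows skipped."""
    out = []
    n = len(seq)
    if n < k:
        return out
    rc = reverse_complement(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        out.append((i, fwd if fwd <= rev else rev))
    return out


def canonical_kmers_oriented(seq: str, k: int) -> list[tuple[int, str, bool]]:
    """Like :func:`canonical_kmers` but with a flag: True when the canonical
    form is the forward-strand k-mer at that offset."""
    out = []
    n = len(seq)
    if n < k:
        return out
    rc = reverse_complement(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        if fwd <= rev:
            out.append((i, fwd, True))
        else:
            out.append((i, rev, False))
    return out
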