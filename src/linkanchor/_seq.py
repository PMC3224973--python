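"""Low-level sequence helpers: random sequence, reverse complement, and a
vectorised exact multi-pattern search used for primer alignment on large
genomes (2-bit rolling prefix hash with full-string verification)."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# uint8 ASCII -> 2-bit code; N and anything else -> 255 (never matches)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hash(pattern: str) -> int:
    h = 0
    for c in pattern:
        h = h * 4 + int(_ENC[ord(c)])
    return h


def find_all(haystack: str, patterns: list[str]) -> list[list[int]]:
    """All 0-based start positions of each pattern in ``haystack``.

    Patterns must be ACGT-only and at least 8 nt. A rolling hash over the
    shortest-pattern-length prefix locates candidates in one numpy pass;
    candidates are verified by direct string comparison, so hash
    collisions cannot produce false hits.
    """
    if not patterns:
        return []
    k = min(len(p) for p in patterns)
    if k < 8:
        raise ValueError("patterns must be >= 8 nt")
    n = len(haystack)
    out: list[list[int]] = [[] for _ in patterns]
    if n < k:
        return out
    enc = _encode(haystack)
    valid = np.ones(n - k + 1, dtype=bool)
    h = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        col = enc[j : n - k + 1 + j]
        valid &= col != 255
        h = h * 4 + col
    h[~valid] = -1

    prefix_hashes = np.array([_kmer_hash(p[:k]) for p in patterns], dtype=np.int64)
    order = np.argsort(prefix_hashes, kind="stable")
    sorted_h = prefix_hashes[order]
    cand = np.flatnonzero(np.isin(h, sorted_h))
    for pos in cand.tolist():
        li = np.searchsorted(sorted_h, h[pos], side="left")
        ri = np.searchsorted(sorted_h, h[pos], side="right")
        for oi in order[li:ri].tolist():
            p = patterns[oi]
            if haystack[pos : pos + len(p)] == p:
                out[oi].append(pos)
    return out
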