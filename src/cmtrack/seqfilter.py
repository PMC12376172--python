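"""Infix (semi-global) edit-distance filtering of reads and ASV sequences.

Amplicon structure can be verified by locating a short anchor sequence — a
conserved primer-adjacent region — anywhere inside each read: the minimum
Levenshtein distance between the anchor and any contiguous substring of the
read.  Sequences whose best infix placement exceeds a caller-chosen distance
cutoff are rejected.

The distance is computed by dynamic programming with free gaps at both ends
of the text (first DP row initialized to zero; answer is the minimum over the
final row), using unit costs: match 0, mismatch/insertion/deletion 1.
Characters outside {A, C, G, T} (e.g. N) are treated conservatively as
mismatching every symbol, including themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_ACGT = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AnchorFilterSpec:
    """Anchor sequence, distance cutoff, and strand policy for filtering."""

    anchor: str
    max_distance: int
    search_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if not (0 <= self.max_distance <= len(self.anchor)):
            raise ValueError(
                f"max_distance must be in [0, len(anchor)={len(self.anchor)}], "
                f"got {self.max_distance}"
            )


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else to a never-matching code."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int16)
    for code, base in enumerate(_ACGT):
        out[arr == ord(base)] = code
    return out


def infix_edit_distance(pattern: str, text: str) -> int:
    """Minimum Levenshtein distance between ``pattern`` and any substring of ``text``.

    The empty substring is allowed, so the result never exceeds
    ``len(pattern)``; it is 0 iff the pattern occurs exactly in the text.

    Raises
    ------
    ValueError
        If the pattern is empty (the distance is undefined for filtering).
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    p = _encode(pattern)
    t = _encode(text)
    m = len(p)
    # dp[j] = best edit distance of pattern[:j] against some suffix of the
    # text consumed so far; free start (dp[0] stays 0 at every column).
    dp = np.arange(m + 1, dtype=np.int32)
    idx = np.arange(m + 1, dtype=np.int32)
    best = m  # empty text / empty substring
    p_valid = p >= 0
    for c in t:
        sub = np.where(p_valid & (p == c), 0, 1).astype(np.int32)
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = 0
        # diagonal (match/substitution) and horizontal (gap in pattern) moves
        cand[1:] = np.minimum(dp[:-1] + sub, dp[1:] + 1)
        # vertical moves (gap in text) form a prefix-min chain:
        # dp_new[j] = min_{k<=j} cand[k] + (j - k)
        dp = np.minimum.accumulate(cand - idx) + idx
        if dp[m] < best:
            best = int(dp[m])
    return int(best)


def filter_sequences(
    records: Iterable[tuple[str, str]],
    spec: AnchorFilterSpec,
) -> tuple[list[str], list[str], dict[str, int]]:
    """Keep records whose anchor infix distance is within the cutoff.

    When ``search_reverse_complement`` is set, the reverse complement of the
    anchor is also tried and the smaller distance counts.

    Returns
    -------
    (kept_ids, rejected_ids, distances)
        Distances are reported for every record, kept or not, for audit.
    """
    rc = reverse_complement(spec.anchor) if spec.search_reverse_complement else None
    kept: list[str] = []
    rejected: list[str] = []
    distances: dict[str, int] = {}
    for rec_id, seq in records:
        d = infix_edit_distance(spec.anchor, seq)
        if rc is not None:
            d = min(d, infix_edit_distance(rc, seq))
        distances[rec_id] = d
        (kept if d <= spec.max_distance else rejected).append(rec_id)
    return kept, rejected, distances
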