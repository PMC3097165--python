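"""Ranked trinucleotide (N-gram, N=3) frequency tables.

Overlapping 3-mers are counted on the given strand; any 3-window touching a
masked position is skipped. AAA and TTT are listed separately with distinct
ranks (no reverse-complement collapsing), and ties everywhere rank order is
consumed break lexicographically so the greedy extension automaton is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .isochores import IsochoreSegment
from .seqio import MaskedSequence

__all__ = ["TRIPLETS", "TripletTable", "count_triplets", "table_by_isochore", "family_ranking"]

_BASES = "ACGT"
TRIPLETS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)
_TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}


@dataclass
class TripletTable:
    """Counts of all 64 trinucleotides plus their descending-count ranking."""

    counts: np.ndarray  # shape (64,), int64, lexicographic triplet order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must have exactly 64 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_counts(cls, mapping: Mapping[str, int]) -> "TripletTable":
        counts = np.zeros(64, dtype=np.int64)
        for t, c in mapping.items():
            if t not in _TRIPLET_INDEX:
                raise ValueError(f"not a trinucleotide: {t!r}")
            counts[_TRIPLET_INDEX[t]] = c
        return cls(counts)

    def __getitem__(self, triplet: str) -> int:
        return int(self.counts[_TRIPLET_INDEX[triplet]])

    def __add__(self, other: "TripletTable") -> "TripletTable":
        return TripletTable(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def ranking(self) -> list[str]:
        """All 64 triplets by descending count, ties lexicographic."""
        order = sorted(range(64), key=lambda i: (-self.counts[i], TRIPLETS[i]))
        return [TRIPLETS[i] for i in order]

    def as_dict(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(TRIPLETS, self.counts)}


def _window_codes(seq: MaskedSequence) -> tuple[np.ndarray, np.ndarray]:
    """(3-mer index per window start, validity mask) for one sequence."""
    codes, mask = seq.codes, seq.mask
    n = len(seq)
    if n < 3:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (
        ~mask[:-2] & ~mask[1:-1] & ~mask[2:] & (c0 < 4) & (c1 < 4) & (c2 < 4)
    )
    idx = (c0.astype(np.int64) * 16 + c1 * 4 + c2)
    return idx, valid


def count_triplets(seqs: MaskedSequence | Iterable[MaskedSequence]) -> TripletTable:
    """Overlapping 3-mer counts over unmasked windows; total == valid windows."""
    if isinstance(seqs, MaskedSequence):
        seqs = [seqs]
    counts = np.zeros(64, dtype=np.int64)
    for seq in seqs:
        idx, valid = _window_codes(seq)
        if idx.size:
            counts += np.bincount(idx[valid], minlength=64)
    return TripletTable(counts)


def table_by_isochore(
    genome: Iterable[MaskedSequence], segments: Sequence[IsochoreSegment]
) -> dict[str, TripletTable]:
    """Per-class tables; each 3-window belongs to the segment containing its start."""
    by_name = {s.name: s for s in genome}
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out: dict[str, np.ndarray] = {}
    for seg in segments:
        if seg.name not in by_name:
            raise ValueError(f"segment references unknown sequence {seg.name!r}")
        if seg.name not in cache:
            cache[seg.name] = _window_codes(by_name[seg.name])
        idx, valid = cache[seg.name]
        lo, hi = seg.start, min(seg.end, idx.size)
        if hi <= lo:
            continue
        sl_idx, sl_valid = idx[lo:hi], valid[lo:hi]
        acc = out.setdefault(seg.label, np.zeros(64, dtype=np.int64))
        if sl_idx.size:
            acc += np.bincount(sl_idx[sl_valid], minlength=64)
    return {label: TripletTable(c) for label, c in out.items()}


def family_ranking(table: TripletTable, family: str) -> list[str]:
    """The four triplets of a one-free-position family, by descending count.

    A family fixes two positions and frees one, written with ``x`` at the
    free position, e.g. ``"xTT"`` (upstream continuations of TT) or
    ``"TTx"`` (downstream continuations). Ties break lexicographically.
    """
    if len(family) != 3 or family.count("x") != 1:
        raise ValueError(f"malformed family {family!r}: need 3 symbols with exactly one 'x'")
    if any(ch not in "ACGTx" for ch in family):
        raise ValueError(f"malformed family {family!r}: fixed symbols must be A/C/G/T")
    free = family.index("x")
    members = [family[:free] + b + family[free + 1 :] for b in _BASES]
    return sorted(members, key=lambda t: (-table[t], t))
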