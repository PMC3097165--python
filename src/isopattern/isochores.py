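"""Isochore segmentation: fixed windows, G+C classification, run merging.

Warm-blooded vertebrate genomes are mosaics of long regions of fairly uniform
G+C content (isochores), classically grouped into the G+C-poor families L1,
L2 and the G+C-rich H1, H2, H3 (chicken adds a very G+C-rich H4). The
segmentation here is deliberately plain: consecutive non-overlapping windows
(default 100,000 bases), G+C over unmasked bases only, threshold
classification, and merging of equal-class runs into maximal segments.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import MaskedSequence

__all__ = [
    "IsochoreScheme",
    "FIVE_CLASS",
    "SIX_CLASS",
    "UNCLASSIFIED",
    "WindowRecord",
    "IsochoreSegment",
    "window_gc",
    "classify",
    "merge_segments",
    "segment_genome",
]

UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_WINDOW = 100_000
"""Window size in bases used for isochore selection."""


@dataclass(frozen=True)
class IsochoreScheme:
    """Ordered class labels and the ascending G+C% boundaries between them.

    A boundary value belongs to the *higher* class: intervals are
    ``[0, b1), [b1, b2), ..., [bk, 100]``.
    """

    labels: tuple[str, ...]
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least two classes")
        if len(self.boundaries) != len(self.labels) - 1:
            raise ValueError("need exactly len(labels) - 1 boundaries")
        bs = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("boundaries must be strictly ascending")
        if not all(0 < b < 100 for b in bs):
            raise ValueError("boundaries must lie in (0, 100)")

    def classify(self, gc_percent: float) -> str:
        if not 0 <= gc_percent <= 100:
            raise ValueError(f"G+C percent {gc_percent} outside [0, 100]")
        return self.labels[bisect_right(self.boundaries, gc_percent)]

    def rank(self, label: str) -> int:
        return self.labels.index(label)


#: Five-family human/mouse scheme. Only the outer bounds (<37% for L1,
#: >52% for H3) are fixed points of the analysis; the interior boundaries
#: follow the classical isochore-family literature and are configurable.
FIVE_CLASS = IsochoreScheme(("L1", "L2", "H1", "H2", "H3"), (37.0, 41.0, 46.0, 52.0))

#: Six-family chicken-style scheme (adds the very G+C-rich H4).
SIX_CLASS = IsochoreScheme(("L1", "L2", "H1", "H2", "H3", "H4"), (37.0, 41.0, 46.0, 52.0, 58.0))


def classify(gc_percent: float, scheme: IsochoreScheme = FIVE_CLASS) -> str:
    """Class label for a G+C percentage under ``scheme``."""
    return scheme.classify(gc_percent)


@dataclass
class WindowRecord:
    name: str
    start: int
    end: int
    gc: float  # fraction of G+C among unmasked bases
    unmasked_fraction: float
    label: str

    @property
    def unmasked(self) -> int:
        return int(round(self.unmasked_fraction * (self.end - self.start)))


@dataclass
class IsochoreSegment:
    name: str
    start: int
    end: int
    label: str
    gc: float  # unmasked-base-weighted mean G+C fraction


def window_gc(
    seq: MaskedSequence,
    window: int = DEFAULT_WINDOW,
    scheme: IsochoreScheme = FIVE_CLASS,
    min_unmasked_fraction: float = 0.5,
) -> list[WindowRecord]:
    """Consecutive non-overlapping windows with G+C over unmasked bases.

    Masked bases are excluded from numerator and denominator. The final
    partial window is emitted with its true length. Windows whose unmasked
    fraction falls below ``min_unmasked_fraction`` are labelled UNCLASSIFIED
    (heavily masked windows give unstable G+C).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(seq)
    if n == 0:
        return []
    codes = seq.codes
    unmasked = ~seq.mask
    is_gc = ((codes == 1) | (codes == 2)) & unmasked
    cum_gc = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
    cum_un = np.concatenate([[0], np.cumsum(unmasked, dtype=np.int64)])

    out: list[WindowRecord] = []
    for start in range(0, n, window):
        end = min(start + window, n)
        n_un = int(cum_un[end] - cum_un[start])
        n_gc = int(cum_gc[end] - cum_gc[start])
        gc = n_gc / n_un if n_un else 0.0
        frac = n_un / (end - start)
        label = scheme.classify(100.0 * gc) if frac >= min_unmasked_fraction else UNCLASSIFIED
        out.append(WindowRecord(seq.name, start, end, gc, frac, label))
    return out


def merge_segments(windows: Sequence[WindowRecord]) -> list[IsochoreSegment]:
    """Merge maximal runs of equal-class windows into segments.

    UNCLASSIFIED windows break runs and are emitted as UNCLASSIFIED
    segments. Mean G+C is weighted by unmasked base count. Windows must be
    grouped by sequence and ordered, non-overlapping within each sequence.
    """
    out: list[IsochoreSegment] = []
    seen: set[str] = set()
    prev_name: str | None = None
    prev_end = 0
    run: list[WindowRecord] = []

    def flush() -> None:
        if not run:
            return
        w_tot = sum(w.unmasked for w in run)
        gc = sum(w.gc * w.unmasked for w in run) / w_tot if w_tot else 0.0
        out.append(IsochoreSegment(run[0].name, run[0].start, run[-1].end, run[0].label, gc))
        run.clear()

    for w in windows:
        if w.name != prev_name:
            if w.name in seen:
                raise ValueError(f"windows for {w.name!r} are not contiguous")
            flush()
            seen.add(w.name)
            prev_name, prev_end = w.name, 0
        if w.start < prev_end:
            raise ValueError(f"{w.name}: window at {w.start} overlaps previous end {prev_end}")
        if run and (w.label != run[-1].label or w.start != run[-1].end or w.name != run[-1].name):
            flush()
        run.append(w)
        prev_end = w.end
    flush()
    return out


def segment_genome(
    seqs: Iterable[MaskedSequence],
    window: int = DEFAULT_WINDOW,
    scheme: IsochoreScheme = FIVE_CLASS,
    min_unmasked_fraction: float = 0.5,
) -> tuple[list[WindowRecord], list[IsochoreSegment]]:
    """Window + classify + merge every sequence of a genome."""
    windows: list[WindowRecord] = []
    for seq in seqs:
        windows.extend(window_gc(seq, window, scheme, min_unmasked_fraction))
    return windows, merge_segments(windows)
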