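"""Resolving extension motifs against the RRRRRYYYYY positioning constraint.

A nucleosome positioning motif, projected onto the purine/pyrimidine
alphabet (R = A/G, Y = C/T), approximates the period-10 tiling
``RRRRRYYYYY`` — and no run of purines or pyrimidines may exceed five
residues. :func:`resolve` removes the copy-number uncertainty of repeat
groups by exhaustive search under exactly those two rules, and
:func:`consensus` aligns resolved motifs (gap-free) into a degenerate
A/C/G/T/R/Y/N pattern such as RGAAATTTCY.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .extension import ClosureFlank, ExtensionMotif, FixedBase, RepeatGroup, Token

__all__ = [
    "ry_project",
    "max_class_run",
    "is_complement_symmetric",
    "ResolvedMotif",
    "resolve",
    "ConsensusPattern",
    "consensus",
]

_ACGT_TO_RY = str.maketrans("AGCT", "RRYY")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def ry_project(sequence: str) -> str:
    """A,G -> R; C,T -> Y."""
    bad = set(sequence) - _PURINES - _PYRIMIDINES
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return sequence.translate(str.maketrans("AGCT", "RRYY"))


def max_class_run(sequence: str) -> int:
    """Length of the longest same-class (purine or pyrimidine) run."""
    if not sequence:
        return 0
    proj = ry_project(sequence)
    best = cur = 1
    for a, b in zip(proj, proj[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def is_complement_symmetric(sequence: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    if not sequence:
        return True
    return sequence == str(Seq(sequence).reverse_complement())


@dataclass
class ResolvedMotif:
    """A concrete A/C/G/T realization of an extension motif.

    ``chosen_counts`` maps each repeat-group variable (by position in the
    token walk) to the selected copy number; ``flank_copies`` records how
    many copies of each closure flank's period were laid down.
    """

    sequence: str
    source: ExtensionMotif | None
    chosen_counts: dict[str, int]
    flank_copies: dict[str, int]
    score: int  # matched positions vs the best-phase tiling
    agreement: float  # matched fraction at that alignment

    def __post_init__(self) -> None:
        run = max_class_run(self.sequence)
        if self.sequence and run > 5:
            # resolve() never emits this; guards hand-built instances
            raise ValueError(f"resolved motif violates max class run: {run} > 5")


_TILE_CACHE: dict[int, list[int]] = {}
_RY_TO_BITS = str.maketrans("RY", "10")


def _tiles_for(L: int) -> list[int]:
    """Bit masks of every phase/polarity of the R5Y5 tiling at length L."""
    tiles = _TILE_CACHE.get(L)
    if tiles is None:
        tiles = []
        for phase in range(10):
            bits = "".join("1" if (i + phase) % 10 < 5 else "0" for i in range(L))
            t = int(bits, 2)
            tiles.append(t)
            tiles.append(t ^ ((1 << L) - 1))  # opposite polarity
        _TILE_CACHE[L] = tiles
    return tiles


def _tiling_matches(proj: str) -> int:
    """Matched positions vs the best phase/polarity R5Y5 tiling."""
    L = len(proj)
    if L == 0:
        return 0
    bits = int(proj.translate(_RY_TO_BITS), 2)
    return L - min((bits ^ tile).bit_count() for tile in _tiles_for(L))


def _group_variables(tokens: Sequence[Token]):
    """Enumerate count variables: one per core group; flank period groups
    share one variable per group, and flanks with identical periods share
    the whole assignment. Returns (group_vars, flank_vars, layout)."""
    group_vars: dict[str, None] = {}
    flank_vars: dict[str, None] = {}
    layout: list[tuple] = []  # ("base", ch) | ("group", var, unit) | ("flank", fvar, period)

    def period_key(flank: ClosureFlank) -> str:
        return "".join(
            t.base if isinstance(t, FixedBase) else f"({t.unit})" for t in flank.tokens
        )

    core_i = 0
    for tok in tokens:
        if isinstance(tok, FixedBase):
            layout.append(("base", tok.base))
        elif isinstance(tok, RepeatGroup):
            var = f"core{core_i}({tok.unit})"
            core_i += 1
            group_vars[var] = None
            layout.append(("group", var, tok.unit))
        elif isinstance(tok, ClosureFlank):
            key = period_key(tok)
            fvar = f"flank[{key}]"
            flank_vars[fvar] = None
            period: list[tuple] = []
            for j, t in enumerate(tok.tokens):
                if isinstance(t, FixedBase):
                    period.append(("base", t.base))
                else:
                    var = f"{fvar}.{j}({t.unit})"
                    group_vars[var] = None
                    period.append(("group", var, t.unit))
            layout.append(("flank", fvar, period))
        else:
            raise TypeError(f"not a motif token: {tok!r}")
    return list(group_vars), list(flank_vars), layout


def resolve(
    motif: ExtensionMotif | Sequence[Token],
    max_run: int = 5,
    count_range: Sequence[int] = range(1, 7),
    flank_copy_range: Sequence[int] = range(0, 3),
    max_candidates: int = 2_000_000,
) -> ResolvedMotif:
    """Pick repeat counts maximizing conformity to the R5Y5 tiling.

    Exhaustive search over repeat counts (default 1..6 per group) and
    closure-flank copies (default 0..2), keeping only resolutions whose
    longest purine and pyrimidine runs are <= ``max_run``. Agreement of the
    R/Y projection with a period-10 RRRRRYYYYY tiling (all 10 phases, both
    polarities) is maximized lexicographically: highest matched *fraction*
    first, then most matched positions (so a perfectly conforming motif is
    laid out at full length, e.g. (A)(T) -> AAAAATTTTT rather than AT),
    then the shortest, then the lexicographically smallest sequence.
    """
    source = motif if isinstance(motif, ExtensionMotif) else None
    tokens = motif.tokens if isinstance(motif, ExtensionMotif) else tuple(motif)
    group_vars, flank_vars, layout = _group_variables(tokens)

    n_comb = len(list(count_range)) ** len(group_vars) * len(list(flank_copy_range)) ** len(
        flank_vars
    )
    if n_comb > max_candidates:
        raise ValueError(
            f"search space too large ({n_comb} candidates for {len(group_vars)} groups, "
            f"{len(flank_vars)} flanks); raise max_candidates or simplify the motif"
        )

    best: tuple | None = None  # (-fraction, -matches, length, sequence)
    best_payload: tuple | None = None
    run_re = re.compile(f"R{{{max_run + 1},}}|Y{{{max_run + 1},}}")

    for counts in product(count_range, repeat=len(group_vars)):
        cmap = dict(zip(group_vars, counts))
        for copies in product(flank_copy_range, repeat=len(flank_vars)):
            fmap = dict(zip(flank_vars, copies))
            parts: list[str] = []
            for item in layout:
                if item[0] == "base":
                    parts.append(item[1])
                elif item[0] == "group":
                    parts.append(item[2] * cmap[item[1]])
                else:
                    _, fvar, period = item
                    unit_str = "".join(
                        p[1] if p[0] == "base" else p[2] * cmap[p[1]] for p in period
                    )
                    parts.append(unit_str * fmap[fvar])
            seq = "".join(parts)
            if not seq:
                continue
            proj = seq.translate(_ACGT_TO_RY)
            if run_re.search(proj):
                continue
            matches = _tiling_matches(proj)
            key = (Fraction(-matches, len(seq)), -matches, len(seq), seq)
            if best is None or key < best:
                best = key
                best_payload = (seq, cmap, fmap, matches, matches / len(seq))

    if best_payload is None:
        units = [v for v in group_vars]
        raise ValueError(
            f"no resolution satisfies max_run <= {max_run}; violating groups: {units}"
        )
    seq, cmap, fmap, score, agreement = best_payload
    return ResolvedMotif(seq, source, cmap, fmap, score, agreement)


@dataclass
class ConsensusPattern:
    """Degenerate consensus over {A,C,G,T,R,Y,N} with per-column base sets."""

    iupac: str
    support: list[frozenset]
    offsets: list[int]  # chosen offset of each input motif (global coordinates)

    def ry(self) -> str:
        """R/Y projection of the consensus (N where a column mixes classes)."""
        return "".join(
            "R" if s <= _PURINES else "Y" if s <= _PYRIMIDINES else "N"
            for s in self.support
        )


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
}


def consensus(motifs: Sequence[ResolvedMotif | str], min_coverage: float = 0.5) -> ConsensusPattern:
    """Gap-free progressive alignment of resolved motifs into an IUPAC consensus.

    Motifs are slid (no gaps) to maximize summed positional identity of
    their R/Y projections against the already-placed motifs; ties take the
    smallest offset. Columns covered by fewer than ``min_coverage`` of the
    motifs are trimmed. Per column: one base -> that base; {A,G} -> R;
    {C,T} -> Y; any other mix -> N.
    """
    seqs = [m.sequence if isinstance(m, ResolvedMotif) else str(m) for m in motifs]
    if len(seqs) < 2:
        raise ValueError("consensus needs at least 2 motifs")
    if any(not s for s in seqs):
        raise ValueError("empty motif")
    projs = [ry_project(s) for s in seqs]

    placed: list[tuple[str, int]] = [(projs[0], 0)]  # (projection, offset)
    offsets = [0]
    for proj in projs[1:]:
        lo = min(o for _, o in placed) - len(proj) + 1
        hi = max(o + len(p) for p, o in placed) - 1
        best_score, best_off = -1, None
        for off in range(lo, hi + 1):
            score = 0
            for p, o in placed:
                a = max(off, o)
                b = min(off + len(proj), o + len(p))
                for i in range(a, b):
                    score += proj[i - off] == p[i - o]
            if score > best_score:
                best_score, best_off = score, off
        if best_score <= 0:
            raise ValueError("no positive-identity alignment for motif")
        placed.append((proj, best_off))
        offsets.append(best_off)

    start = min(o for _, o in placed)
    end = max(o + len(p) for p, o in placed)
    n = len(seqs)
    columns: list[frozenset] = []
    kept_offsets = [o - start for o in offsets]
    iupac: list[str] = []
    for col in range(start, end):
        bases = [
            seqs[i][col - offsets[i]]
            for i in range(n)
            if offsets[i] <= col < offsets[i] + len(seqs[i])
        ]
        if len(bases) < min_coverage * n:
            continue
        s = frozenset(bases)
        columns.append(s)
        iupac.append(_IUPAC.get(s, "N"))
    if not iupac:
        raise ValueError("all columns trimmed by the coverage filter")
    return ConsensusPattern("".join(iupac), columns, kept_offsets)
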