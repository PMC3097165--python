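"""Shannon N-gram extension of trinucleotide seeds into positioning motifs.

Starting from a high-frequency triplet ABC, the motif grows downstream by
repeatedly appending the most frequent continuation of its right-edge
dinucleotide (family BCx) and upstream by prepending the most frequent
xAB continuation. Three grammar events structure the result:

* **collapse** — when the freshly emitted tail repeats a short unit twice
  (unit length 1-3, smallest unit wins), the trailing repetitions collapse
  into a repeat group, written ``(unit)``: an uncertain number of copies.
* **escape** — while the edge sits in a repeat cycle, the automaton takes
  the highest-ranked continuation that does *not* prolong the cycle (after
  ``(T)`` the continuation C via TTC even though TTT ranks higher); escapes
  require a positive count, otherwise the cycle closes.
* **closure** — when a direction recreates a repeat unit it already
  produced, the period between the two twins is wrapped into a closure
  flank ``[...]``, meaning the motif continues periodically beyond the
  resolved core; the direction stops.

The automaton is a pure function of (table ranking, seed): greedy top-rank
continuation with lexicographic tie-breaks. A stochastic mode that samples
continuations proportional to their counts is available for exploration but
is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ngram import TRIPLETS, TripletTable, family_ranking

__all__ = [
    "FixedBase",
    "RepeatGroup",
    "ClosureFlank",
    "TraceStep",
    "ExtensionMotif",
    "extend",
    "seed_select",
    "render",
    "parse",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixedBase:
    base: str

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"invalid base {self.base!r}")


@dataclass(frozen=True)
class RepeatGroup:
    """Tandem repetition of a 1-3 base unit with unresolved copy number."""

    unit: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.unit) <= 3 or any(b not in _BASES for b in self.unit):
            raise ValueError(f"invalid repeat unit {self.unit!r}")


@dataclass(frozen=True)
class ClosureFlank:
    """Periodic continuation of the enclosed period beyond the resolved core."""

    tokens: tuple

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("closure flank cannot be empty")


Token = FixedBase | RepeatGroup | ClosureFlank


@dataclass(frozen=True)
class TraceStep:
    direction: str  # "down" | "up"
    event: str  # "extend" | "escape" | "collapse" | "closure" | "self_closure" | "stop"
    family: str | None = None
    ranking: tuple[str, ...] | None = None
    chosen: str | None = None  # appended base, or unit for collapse/closure
    rank_used: int | None = None


@dataclass
class ExtensionMotif:
    tokens: tuple
    seed: str
    trace: tuple[TraceStep, ...]

    @property
    def notation(self) -> str:
        return render(self)


# ---------------------------------------------------------------------------
# token helpers

def _concrete(tokens: Iterable[Token]) -> str:
    """One copy of every repeat unit / flank period, plus fixed bases."""
    out: list[str] = []
    for t in tokens:
        if isinstance(t, FixedBase):
            out.append(t.base)
        elif isinstance(t, RepeatGroup):
            out.append(t.unit)
        else:
            out.append(_concrete(t.tokens))
    return "".join(out)


def _edge(tokens: Sequence[Token], side: str) -> str:
    """The two concrete bases at one end (repeat groups repeat their unit)."""
    chars: list[str] = []
    seq = reversed(tokens) if side == "right" else tokens
    for t in seq:
        if isinstance(t, FixedBase):
            piece = t.base
        elif isinstance(t, RepeatGroup):
            piece = t.unit * 2  # enough context for any unit length
        else:
            piece = _concrete(t.tokens) * 2
        chars.append(piece[::-1] if side == "right" else piece)
        if sum(len(c) for c in chars) >= 2:
            break
    flat = "".join(chars)[:2]
    return flat[::-1] if side == "right" else flat


def _edge_primitive(tokens: Sequence[Token], side: str) -> Token | None:
    """Outermost primitive token at one end, descending into closure flanks."""
    if not tokens:
        return None
    t = tokens[-1] if side == "right" else tokens[0]
    if isinstance(t, ClosureFlank):
        return _edge_primitive(t.tokens, side)
    return t


def _try_collapse(tokens: list[Token], side: str, max_unit: int) -> RepeatGroup | None:
    """Collapse the trailing (or leading) fixed-base run into a repeat group.

    Triggered when the last 2k emitted bases are two copies of a length-k
    unit (k = 1..max_unit, smallest k wins); all complete trailing copies
    are absorbed, including seed bases.
    """
    if side == "right":
        run_start = len(tokens)
        while run_start > 0 and isinstance(tokens[run_start - 1], FixedBase):
            run_start -= 1
        run = [t.base for t in tokens[run_start:]]
    else:
        run_end = 0
        while run_end < len(tokens) and isinstance(tokens[run_end], FixedBase):
            run_end += 1
        run = [t.base for t in tokens[:run_end]]

    s = "".join(run)
    if side == "left":
        s = s[::-1]  # uniform handling: repetition grows at the string's end
    for k in range(1, max_unit + 1):
        if len(s) >= 2 * k and s[-k:] == s[-2 * k : -k]:
            m = 2
            while len(s) >= (m + 1) * k and s[-(m + 1) * k : -m * k] == s[-k:]:
                m += 1
            unit = s[-k:]
            if side == "left":
                unit = unit[::-1]
            group = RepeatGroup(unit)
            if side == "right":
                del tokens[len(tokens) - m * k :]
                tokens.append(group)
            else:
                del tokens[: m * k]
                tokens.insert(0, group)
            return group
    return None


def _continuing_base(unit: str, side: str) -> str:
    """The base that would prolong the repeat cycle at the growing edge."""
    return unit[0] if side == "right" else unit[-1]


# ---------------------------------------------------------------------------
# the automaton

def _run_direction(
    tokens: list[Token],
    table: TripletTable,
    side: str,
    max_steps: int,
    max_unit: int,
    trace: list[TraceStep],
    rng: np.random.Generator | None,
    initial_groups: Sequence[RepeatGroup] = (),
) -> None:
    direction = "down" if side == "right" else "up"
    # Twin matching is direction-local: only groups this pass created (plus,
    # downstream, the group that absorbed the seed) can close the direction.
    my_groups: list[RepeatGroup] = list(initial_groups)

    def choose(candidates: list[tuple[str, int, int]]) -> tuple[str, int] | None:
        """candidates: (base, count, rank index); greedy top or count-weighted."""
        positive = [c for c in candidates if c[1] > 0]
        if not positive:
            return None
        if rng is None:
            base, _, rank = positive[0]
            return base, rank
        weights = np.array([c[1] for c in positive], dtype=float)
        pick = positive[int(rng.choice(len(positive), p=weights / weights.sum()))]
        return pick[0], pick[2]

    for _ in range(max_steps):
        edge = _edge(tokens, side)
        if len(edge) < 2:
            trace.append(TraceStep(direction, "stop"))
            return
        family = edge + "x" if side == "right" else "x" + edge
        ranking = family_ranking(table, family)
        free = 2 if side == "right" else 0
        cands = [(t[free], table[t], r) for r, t in enumerate(ranking)]

        edge_tok = _edge_primitive(tokens, side)
        in_cycle = isinstance(edge_tok, RepeatGroup)
        if in_cycle:
            cont = _continuing_base(edge_tok.unit, side)
            escape = choose([c for c in cands if c[0] != cont])
            if escape is None:
                # no positive-count escape: the cycle continues indefinitely
                trace.append(TraceStep(direction, "self_closure", family,
                                       tuple(ranking), edge_tok.unit))
                _wrap_self_closure(tokens, side)
                return
            base, rank = escape
            event = "escape"
        else:
            top = choose(cands)
            if top is None:
                trace.append(TraceStep(direction, "stop", family, tuple(ranking)))
                return
            base, rank = top
            event = "extend"

        if side == "right":
            tokens.append(FixedBase(base))
        else:
            tokens.insert(0, FixedBase(base))
        trace.append(TraceStep(direction, event, family, tuple(ranking), base, rank))

        group = _try_collapse(tokens, side, max_unit)
        if group is not None:
            trace.append(TraceStep(direction, "collapse", chosen=group.unit))
            twin = next((g for g in my_groups if g.unit == group.unit), None)
            if twin is not None and _wrap_twin_closure(tokens, side, twin, group):
                trace.append(TraceStep(direction, "closure", chosen=group.unit))
                return
            my_groups.append(group)
    trace.append(TraceStep(direction, "stop"))


def _wrap_self_closure(tokens: list[Token], side: str) -> None:
    """Wrap the edge repeat group itself as the periodic continuation."""
    idx = len(tokens) - 1 if side == "right" else 0
    t = tokens[idx]
    if isinstance(t, RepeatGroup):
        tokens[idx] = ClosureFlank((t,))


def _wrap_twin_closure(
    tokens: list[Token], side: str, twin: RepeatGroup, new: RepeatGroup
) -> bool:
    """Wrap the period between the twin groups into a closure flank.

    Downstream the period runs from just after the earlier twin through the
    new group; upstream it is the mirror image. Returns False (no wrap) if
    the period would swallow a flank — a degenerate table; the direction
    still stops.
    """
    ids = [id(t) for t in tokens]
    try:
        i_twin = ids.index(id(twin))
        i_new = ids.index(id(new))
    except ValueError:
        return False
    if side == "right":
        period = tokens[i_twin + 1 : i_new + 1]
    else:
        period = tokens[i_new : i_twin]
    if not period or any(isinstance(t, ClosureFlank) for t in period):
        return False
    flank = ClosureFlank(tuple(period))
    if side == "right":
        tokens[i_twin + 1 : i_new + 1] = [flank]
    else:
        tokens[i_new : i_twin] = [flank]
    return True


def extend(
    table: TripletTable,
    seed: str,
    max_steps: int = 40,
    max_unit: int = 3,
    stochastic: bool = False,
    rng: np.random.Generator | int | None = None,
) -> ExtensionMotif:
    """Grow a motif from a seed triplet: downstream first, then upstream.

    Deterministic greedy automaton (see module docstring); ``max_steps``
    bounds the appended bases per direction. With ``stochastic=True``
    continuations are sampled proportional to their counts using ``rng``.
    """
    if seed not in TRIPLETS:
        raise ValueError(f"seed must be one of the 64 trinucleotides, got {seed!r}")
    if table.total <= 0:
        raise ValueError("cannot extend on a zero-total table")
    if stochastic:
        rng = np.random.default_rng(rng)
    else:
        rng = None

    tokens: list[Token] = [FixedBase(b) for b in seed]
    trace: list[TraceStep] = []
    group = _try_collapse(tokens, "right", max_unit)  # e.g. seed GGG -> (G)
    if group is not None:
        trace.append(TraceStep("down", "collapse", chosen=group.unit))
    _run_direction(tokens, table, "right", max_steps, max_unit, trace, rng,
                   initial_groups=(group,) if group is not None else ())
    _run_direction(tokens, table, "left", max_steps, max_unit, trace, rng)
    return ExtensionMotif(tuple(tokens), seed, tuple(trace))


def seed_select(table: TripletTable, must_contain: str | None = None) -> str:
    """Top-ranked triplet, optionally the top one containing a dinucleotide."""
    if must_contain is not None and (
        len(must_contain) != 2 or any(b not in _BASES for b in must_contain)
    ):
        raise ValueError(f"must_contain must be a dinucleotide, got {must_contain!r}")
    for t in table.ranking:
        if must_contain is None or must_contain in t:
            return t
    raise AssertionError("unreachable: 64 triplets always available")


# ---------------------------------------------------------------------------
# notation

def render(motif: ExtensionMotif | Iterable[Token]) -> str:
    """Tokens -> notation: base, ``(unit)``, ``[period]``."""
    tokens = motif.tokens if isinstance(motif, ExtensionMotif) else motif
    out: list[str] = []
    for t in tokens:
        if isinstance(t, FixedBase):
            out.append(t.base)
        elif isinstance(t, RepeatGroup):
            out.append(f"({t.unit})")
        elif isinstance(t, ClosureFlank):
            out.append("[" + render(t.tokens) + "]")
        else:
            raise TypeError(f"not a motif token: {t!r}")
    return "".join(out)


def parse(notation: str) -> tuple[Token, ...]:
    """Notation -> tokens; inverse of :func:`render`."""
    tokens: list[Token] = []
    i, n = 0, len(notation)
    while i < n:
        ch = notation[i]
        if ch in _BASES:
            tokens.append(FixedBase(ch))
            i += 1
        elif ch == "(":
            j = notation.find(")", i)
            if j < 0:
                raise ValueError(f"unclosed '(' at {i} in {notation!r}")
            tokens.append(RepeatGroup(notation[i + 1 : j]))
            i = j + 1
        elif ch == "[":
            depth, j = 1, i + 1
            while j < n and depth:
                depth += notation[j] == "["
                depth -= notation[j] == "]"
                j += 1
            if depth:
                raise ValueError(f"unclosed '[' at {i} in {notation!r}")
            tokens.append(ClosureFlank(parse(notation[i + 1 : j - 1])))
            i = j
        else:
            raise ValueError(f"unexpected character {ch!r} at {i} in {notation!r}")
    return tuple(tokens)
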