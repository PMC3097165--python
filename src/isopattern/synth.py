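"""Ground-truthed synthetic genomes for the isochore/periodicity analysis.

The generator emulates exactly the statistical structure the pipeline
assumes, with known coordinates for every planted signal:

* an **isochore mosaic** — ordered segments of i.i.d. bases with
  P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2;
* **masked-repeat stretches** — geometric-length runs (mean 300 bp, the
  scale of common interspersed repeats) flagged as masked until a requested
  fraction of positions is covered;
* **planted degenerate motifs** (IUPAC over A/C/G/T/R/Y) at uniform-random
  non-overlapping unmasked positions, which skew the trinucleotide tables;
* **planted periodic dinucleotide trains** at positions
  p0 + round(k * period) + jitter — the synthetic counterpart of the
  ~10.4-base nucleosome periodicity.

Plant order is masks -> motifs -> periodic trains; later plants may
overwrite earlier ones (coordinates are recorded as planted). The whole
construction is a pure function of the spec and its seed.

The i.i.d. background has no Markov structure or CpG depletion; it is the
simplest null under which the module-level expectations have closed forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import MaskedSequence

__all__ = [
    "SegmentSpec",
    "PeriodicPlant",
    "MotifPlant",
    "SyntheticSpec",
    "GroundTruth",
    "generate_genome",
    "plant_periodic_dinucleotide",
    "plant_motif",
]

_BASES = "ACGT"
_IUPAC_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT"}
_MEAN_MASK_STRETCH = 300


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SegmentSpec:
    length: int
    gc_target: float
    class_label: str


@dataclass(frozen=True)
class PeriodicPlant:
    dinucleotide: str
    period: float
    count: int
    jitter_sd: float = 0.0
    origin: int | None = None  # None: uniform-random placement of the train


@dataclass(frozen=True)
class MotifPlant:
    motif: str
    count: int


@dataclass
class SyntheticSpec:
    """Full description of one synthetic genome (validated on construction)."""

    segments: list[SegmentSpec]
    planted_periodicities: list[PeriodicPlant] = field(default_factory=list)
    planted_motifs: list[MotifPlant] = field(default_factory=list)
    mask_fraction: float = 0.0
    seed: int = 0
    name: str = "synth"

    def __post_init__(self) -> None:
        self.segments = [
            s if isinstance(s, SegmentSpec) else SegmentSpec(*s) for s in self.segments
        ]
        self.planted_periodicities = [
            p if isinstance(p, PeriodicPlant) else PeriodicPlant(*p)
            for p in self.planted_periodicities
        ]
        self.planted_motifs = [
            m if isinstance(m, MotifPlant) else MotifPlant(*m) for m in self.planted_motifs
        ]
        if not self.segments:
            raise ValueError("spec needs at least one segment")
        for s in self.segments:
            if s.length < 1:
                raise ValueError(f"segment length must be >= 1, got {s.length}")
            if not 0.0 <= s.gc_target <= 1.0:
                raise ValueError(f"gc_target must be in [0, 1], got {s.gc_target}")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must be in [0, 1)")
        total = self.total_length
        for p in self.planted_periodicities:
            if p.period <= 2:
                raise ValueError(f"period must be > 2 (got {p.period}): occurrences overlap")
            if len(p.dinucleotide) != 2 or any(b not in _BASES for b in p.dinucleotide):
                raise ValueError(f"invalid dinucleotide {p.dinucleotide!r}")
            if p.count and p.count * p.period + 2 > total:
                raise ValueError(f"periodic train {p} does not fit in {total} bases")
        for m in self.planted_motifs:
            if any(ch not in _IUPAC_SETS for ch in m.motif):
                raise ValueError(f"unsupported IUPAC code in motif {m.motif!r}")
            if m.count * len(m.motif) > total:
                raise ValueError(f"motif plant {m} does not fit in {total} bases")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            segments=[SegmentSpec(**s) if isinstance(s, dict) else SegmentSpec(*s)
                      for s in d["segments"]],
            planted_periodicities=[
                PeriodicPlant(**p) if isinstance(p, dict) else PeriodicPlant(*p)
                for p in d.get("planted_periodicities", [])
            ],
            planted_motifs=[
                MotifPlant(**m) if isinstance(m, dict) else MotifPlant(*m)
                for m in d.get("planted_motifs", [])
            ],
            mask_fraction=d.get("mask_fraction", 0.0),
            seed=d.get("seed", 0),
            name=d.get("name", "synth"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Final coordinates of everything the generator planted."""

    segments: list[dict]  # name/start/end/class_label/gc_target/realized_gc
    periodic: list[dict]  # dinucleotide/period/jitter_sd/positions
    motifs: list[dict]  # motif/positions
    mask_fraction: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "segments": self.segments,
                    "periodic": self.periodic,
                    "motifs": self.motifs,
                    "mask_fraction": self.mask_fraction,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _plant_periodic_into(
    bases: np.ndarray,
    mask: np.ndarray,
    plant: PeriodicPlant,
    rng: np.random.Generator,
) -> list[int]:
    L = bases.size
    if plant.count == 0:
        return []
    span = _round_half_up(plant.period * (plant.count - 1)) + 2
    if plant.origin is not None:
        p0 = int(plant.origin)
    else:
        if span > L:
            raise ValueError("periodic train longer than sequence")
        p0 = int(rng.integers(0, L - span + 1))
    d0, d1 = (np.uint8(ord(b)) for b in plant.dinucleotide)
    positions = []
    for k in range(plant.count):
        p = p0 + _round_half_up(k * plant.period)
        if plant.jitter_sd > 0:
            p += _round_half_up(float(rng.normal(0.0, plant.jitter_sd)))
        p = min(max(p, 0), L - 2)
        bases[p] = d0
        bases[p + 1] = d1
        mask[p : p + 2] = False  # a planted signal is, by construction, not a repeat
        positions.append(p)
    return sorted(set(positions))


def plant_periodic_dinucleotide(
    seq: MaskedSequence,
    dinucleotide: str,
    period: float,
    count: int,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    origin: int | None = None,
) -> tuple[MaskedSequence, list[int]]:
    """Overwrite a train of ``count`` occurrences at spacing ``period``.

    Occurrence k lands at ``p0 + round(k * period) + round(N(0, jitter_sd))``,
    clipped to the valid range. Returns the new sequence and the planted
    start positions (sorted, deduplicated).
    """
    plant = PeriodicPlant(dinucleotide, period, count, jitter_sd, origin)
    if plant.period <= 2:
        raise ValueError("period must be > 2: occurrences would overlap")
    if len(dinucleotide) != 2 or any(b not in _BASES for b in dinucleotide):
        raise ValueError(f"invalid dinucleotide {dinucleotide!r}")
    if count and count * period + 2 > len(seq):
        raise ValueError("train does not fit in the sequence")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8).copy()
    mask = seq.mask.copy()
    positions = _plant_periodic_into(bases, mask, plant, rng)
    return MaskedSequence(seq.name, bases.tobytes().decode("ascii"), mask), positions


def _plant_motifs_into(
    bases: np.ndarray,
    mask: np.ndarray,
    plant: MotifPlant,
    occupied: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[int]:
    L = bases.size
    m = len(plant.motif)
    positions = []
    for _ in range(plant.count):
        for _attempt in range(max_attempts):
            p = int(rng.integers(0, L - m + 1))
            window = slice(p, p + m)
            if not mask[window].any() and not occupied[window].any():
                realized = "".join(
                    str(rng.choice(list(_IUPAC_SETS[ch]))) for ch in plant.motif
                )
                bases[window] = np.frombuffer(realized.encode("ascii"), dtype=np.uint8)
                occupied[window] = True
                positions.append(p)
                break
        else:
            raise ValueError(
                f"could not place motif {plant.motif!r} after {max_attempts} attempts "
                f"({len(positions)}/{plant.count} placed)"
            )
    return sorted(positions)


def plant_motif(
    seq: MaskedSequence, iupac_motif: str, count: int, seed: int | None = None
) -> tuple[MaskedSequence, list[int]]:
    """Plant ``count`` non-overlapping instances of a degenerate motif.

    Degenerate positions (R -> A/G, Y -> C/T) are sampled uniformly per
    instance; placements are uniform-random over unmasked, unoccupied
    windows (1000 rejection attempts per instance before erroring).
    """
    if any(ch not in _IUPAC_SETS for ch in iupac_motif):
        bad = sorted(set(iupac_motif) - set(_IUPAC_SETS))
        raise ValueError(f"unsupported IUPAC code(s) {bad} in motif {iupac_motif!r}")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8).copy()
    mask = seq.mask.copy()
    occupied = np.zeros(len(seq), dtype=bool)
    positions = _plant_motifs_into(bases, mask, MotifPlant(iupac_motif, count), occupied, rng)
    return MaskedSequence(seq.name, bases.tobytes().decode("ascii"), mask), positions


def generate_genome(spec: SyntheticSpec) -> tuple[MaskedSequence, GroundTruth]:
    """Build the mosaic, then masks, motifs and periodic trains, in order.

    Deterministic given ``spec.seed``: each stage draws from its own
    spawned random stream, so adding e.g. a motif plant does not perturb
    the background bases.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_bg, rng_mask, rng_motif, rng_per = (np.random.default_rng(c) for c in ss.spawn(4))

    total = spec.total_length
    bases = np.empty(total, dtype=np.uint8)
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seg_records = []
    pos = 0
    for s in spec.segments:
        g = s.gc_target
        p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
        draw = rng_bg.choice(4, size=s.length, p=p)
        bases[pos : pos + s.length] = base_lut[draw]
        realized_gc = float(np.mean((draw == 1) | (draw == 2)))
        seg_records.append(
            {
                "name": spec.name,
                "start": pos,
                "end": pos + s.length,
                "class_label": s.class_label,
                "gc_target": s.gc_target,
                "realized_gc": realized_gc,
            }
        )
        pos += s.length

    mask = np.zeros(total, dtype=bool)
    target = int(round(spec.mask_fraction * total))
    while mask.sum() < target:
        start = int(rng_mask.integers(0, total))
        length = int(rng_mask.geometric(1.0 / _MEAN_MASK_STRETCH))
        end = min(total, start + length)
        window = mask[start:end]
        need = target - int(mask.sum())
        fresh = np.flatnonzero(~window)
        if fresh.size > need:
            window[fresh[:need]] = True
        else:
            window[:] = True

    occupied = np.zeros(total, dtype=bool)
    motif_records = []
    for m in spec.planted_motifs:
        positions = _plant_motifs_into(bases, mask, m, occupied, rng_motif)
        motif_records.append({"motif": m.motif, "positions": positions})

    periodic_records = []
    for p in spec.planted_periodicities:
        positions = _plant_periodic_into(bases, mask, p, rng_per)
        periodic_records.append(
            {
                "dinucleotide": p.dinucleotide,
                "period": p.period,
                "jitter_sd": p.jitter_sd,
                "positions": positions,
            }
        )

    seq = MaskedSequence(spec.name, bases.tobytes().decode("ascii"), mask)
    truth = GroundTruth(seg_records, periodic_records, motif_records, spec.mask_fraction)
    return seq, truth
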