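"""Soft-masked sequence I/O and interval/table output.

The whole pipeline operates on :class:`MaskedSequence`: an uppercase A/C/G/T/N
string plus one boolean mask flag per position. Masked positions (repeats,
assembly gaps) keep their coordinates but are excluded from every counting
procedure downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "MaskedSequence",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "write_tsv",
]

_VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes other than N: converted to N + masked with a warning.
_AMBIGUITY = frozenset("RYSWKMBDHV")

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE_LUT[ord(_b)] = _i


@dataclass(eq=False)
class MaskedSequence:
    """A named sequence over {A,C,G,T,N} with a per-position mask flag.

    Invariants: ``len(bases) == len(mask)``; every N position is masked;
    only A/C/G/T/N occur (canonicalization happens in :func:`read_fasta`).
    """

    name: str
    bases: str
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.ascontiguousarray(self.mask, dtype=bool)
        if len(self.bases) != self.mask.size:
            raise ValueError(
                f"{self.name}: bases length {len(self.bases)} != mask length {self.mask.size}"
            )
        codes = _CODE_LUT[np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)]
        if np.any(codes == 255):
            bad = sorted(set(self.bases) - _VALID_BASES)
            raise ValueError(f"{self.name}: invalid characters {bad}; expected A/C/G/T/N")
        if np.any((codes == 4) & ~self.mask):
            raise ValueError(f"{self.name}: every N position must carry a mask flag")
        self._codes = codes

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskedSequence):
            return NotImplemented
        return (
            self.name == other.name
            and self.bases == other.bases
            and bool(np.array_equal(self.mask, other.mask))
        )

    @property
    def codes(self) -> np.ndarray:
        """Base codes A=0, C=1, G=2, T=3, N=4 (read-only view)."""
        return self._codes

    def subsequence(self, start: int, end: int, name: str | None = None) -> "MaskedSequence":
        """0-based half-open slice, mask preserved."""
        if not (0 <= start <= end <= len(self)):
            raise ValueError(f"slice [{start}, {end}) out of range for length {len(self)}")
        return MaskedSequence(
            name if name is not None else self.name,
            self.bases[start:end],
            self.mask[start:end].copy(),
        )


def _canonicalize(name: str, raw: str, mask_policy: str) -> MaskedSequence:
    if mask_policy not in ("lowercase", "n_only", "both"):
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    upper = np.where(lower, arr - 32, arr).astype(np.uint8)
    bases = upper.tobytes().decode("ascii")

    chars = set(bases)
    bad = chars - _VALID_BASES - _AMBIGUITY
    if bad:
        pos = min(i for i, c in enumerate(bases) if c in bad)
        raise ValueError(
            f"record {name!r}: illegal character {bases[pos]!r} at position {pos}"
        )
    ambig = chars & _AMBIGUITY
    is_n = upper == ord("N")
    if ambig:
        warnings.warn(
            f"record {name!r}: ambiguity codes {sorted(ambig)} converted to N and masked",
            stacklevel=3,
        )
        amb_lut = np.zeros(256, dtype=bool)
        for c in ambig:
            amb_lut[ord(c)] = True
        amb_pos = amb_lut[upper]
        upper = np.where(amb_pos, np.uint8(ord("N")), upper)
        bases = upper.tobytes().decode("ascii")
        is_n = is_n | amb_pos

    if mask_policy == "lowercase":
        mask = lower | is_n  # N is always masked (type invariant)
    elif mask_policy == "n_only":
        mask = is_n.copy()
    else:  # both
        mask = lower | is_n
    return MaskedSequence(name, bases, mask)


def read_fasta(path: str | Path, mask_policy: str = "both") -> list[MaskedSequence]:
    """Read a (multi-record) soft-masked FASTA file.

    ``mask_policy`` selects which RepeatMasker dialect sets the mask flag:
    ``"lowercase"``, ``"n_only"``, or ``"both"`` (default; N is always masked
    because an N carries no countable base).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: line {lineno}: not FASTA (expected '>' header)")
                break
        else:
            raise ValueError(f"{path}: empty file")
    records = [
        _canonicalize(rec.id, str(rec.seq), mask_policy)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(seqs: Iterable[MaskedSequence], path: str | Path, width: int = 60) -> None:
    """Write soft-masked FASTA: masked non-N positions lowercase, N uppercase."""
    with open(path, "w") as fh:
        for seq in seqs:
            arr = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
            soft = np.where(seq.mask & (arr != ord("N")), arr + 32, arr).astype(np.uint8)
            text = soft.tobytes().decode("ascii")
            fh.write(f">{seq.name}\n")
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def write_bed(segments: Sequence, path: str | Path) -> None:
    """Write classified segments as BED5 (0-based half-open).

    Columns: chrom, start, end, class label, G+C percent x 10 as an integer
    score. Segments must be sorted by (name, start) and disjoint per name.
    """
    prev_name, prev_end = None, 0
    seen: set[str] = set()
    with open(path, "w") as fh:
        for seg in segments:
            if seg.name != prev_name:
                if seg.name in seen:
                    raise ValueError(f"segments for {seg.name!r} are not contiguous in input")
                seen.add(seg.name)
                prev_name, prev_end = seg.name, 0
            elif seg.start < prev_end:
                raise ValueError(
                    f"{seg.name}: segment at {seg.start} overlaps or precedes previous end {prev_end}"
                )
            prev_end = seg.end
            score = int(round(seg.gc * 1000))
            fh.write(f"{seg.name}\t{seg.start}\t{seg.end}\t{seg.label}\t{score}\n")


def read_bed(path: str | Path):
    """Read BED5 written by :func:`write_bed` back into IsochoreSegment records."""
    from .isochores import IsochoreSegment

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: expected 5 BED columns, got {len(fields)}")
            name, start, end, label, score = fields[:5]
            out.append(
                IsochoreSegment(name, int(start), int(end), label, int(score) / 1000.0)
            )
    return out


def write_tsv(df, path: str | Path) -> None:
    """Shared TSV dialect: tab-separated, '#'-prefixed header, '.' for missing."""
    import pandas as pd

    df = df.copy()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep=".")
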