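"""Shared fixtures: small sequences and hand-built trinucleotide tables."""

from __future__ import annotations

import numpy as np
import pytest

from isopattern import MaskedSequence, TripletTable


def mseq(bases: str, name: str = "s") -> MaskedSequence:
    """MaskedSequence from a soft-masked string (lowercase or N = masked)."""
    mask = np.array([c.islower() or c.upper() == "N" for c in bases])
    return MaskedSequence(name, bases.upper(), mask)


@pytest.fixture
def at_rich_table() -> TripletTable:
    """AT-rich (human L1-like) table.

    Rankings encode the classical low-G+C landscape: TTT/AAA dominate,
    ATT/AAT next, TTA/TAA the strongest escapes out of the homopolymer
    cycles, and ACG the most frequent CG-containing triplet.
    """
    return TripletTable.from_counts(
        {
            "TTT": 1001,
            "AAA": 1000,
            "ATT": 800,
            "AAT": 800,
            "TTA": 600,
            "TAA": 600,
            "TAT": 250,
            "ATA": 250,
            "ACG": 5,
            "CGT": 4,
        }
    )
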