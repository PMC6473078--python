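"""Core sequence and annotation containers.

Coordinates are 0-based half-open internally; file I/O converts to the
1-based inclusive convention of GFF3. On circular replicons every
coordinate is interpreted modulo the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer encoding used throughout: A=0, C=1, G=2, T=3, N=4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class CircularGenome:
    """A replicon sequence; ``circular=True`` enables modular arithmetic."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Subsequence of given length starting at ``start`` (wraps if circular)."""
        L = self.length
        if self.circular:
            start %= L
            if start + length <= L:
                return self.sequence[start : start + length]
            return self.sequence[start:] + self.sequence[: (start + length) % L]
        if start < 0 or start + length > L:
            raise IndexError("window outside linear genome")
        return self.sequence[start : start + length]


@dataclass
class GeneAnnotation:
    """A CDS feature; start/end are 1-based inclusive as in GFF3."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("GFF3 coordinates are 1-based; got value < 1")

    @property
    def translational_start0(self) -> int:
        """0-based genome position of the first transcribed/translated base."""
        return self.start - 1 if self.strand == "+" else self.end - 1

    def midpoint(self, L: int) -> int:
        """Circular midpoint of the feature span (handles origin-spanning genes)."""
        s, e = self.start - 1, self.end - 1
        span = (e - s) % L
        return (s + span // 2) % L
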