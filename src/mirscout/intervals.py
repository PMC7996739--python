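"""Genomic intervals in a single, fixed coordinate convention.

Everything inside the pipeline is 0-based, half-open, with an explicit
strand.  Conversions to the 1-based inclusive convention of GFF3 and the
engine reports happen only at the I/O boundary (:mod:`mirscout.formats_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Attributes
    ----------
    sequence_id:
        Name of the chromosome/contig the interval lies on.
    start, end:
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand:
        ``"+"`` or ``"-"``; always explicit, never ``"."``.
    """

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """True iff the two intervals share >= 1 nt (same sequence, and same
        strand unless ``stranded=False``)."""
        if self.sequence_id != other.sequence_id:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.sequence_id != other.sequence_id or self.strand != other.strand:
            raise ValueError("cannot union intervals on different sequences/strands")
        return replace(self, start=min(self.start, other.start), end=max(self.end, other.end))

    def expanded(self, left: int, right: int, sequence_length: int | None = None) -> "GenomicInterval":
        """Extend by ``left``/``right`` nt, clipping to ``[0, sequence_length)``."""
        start = max(0, self.start - left)
        end = self.end + right
        if sequence_length is not None:
            end = min(end, sequence_length)
        return replace(self, start=start, end=end)
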