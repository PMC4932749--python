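"""Genomic intervals in 0-based half-open coordinates.

Every module of the package shares one coordinate convention: intervals are
``[start, end)`` on the forward strand of the reference, with an explicit
``+``/``-`` strand attribute.  GTF input (1-based inclusive) is converted on
read; BED is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval", strand_aware: bool = True) -> bool:
        """≥1 nt overlap; strand-aware by default (iCLIP data are stranded)."""
        if self.chrom != other.chrom:
            return False
        if strand_aware and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def expanded(self, flank: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Interval extended by ``flank`` nt on both sides, clipped at bounds."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end, self.strand)
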