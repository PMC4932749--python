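"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement; RNA input yields RNA output."""
    is_rna = "U" in seq.upper()
    rc = str(Seq(to_dna(seq)).reverse_complement())
    return to_rna(rc) if is_rna else rc


def gc_content(seq: str) -> float:
    seq = to_dna(seq)
    if not seq:
        raise ValueError("empty sequence")
    return sum(base in "GC" for base in seq) / len(seq)


def fetch(genome: dict[str, str], chrom: str, start: int, end: int,
          strand: str = "+") -> str:
    """Extract genome[chrom][start:end], reverse-complemented on '-'."""
    seq = genome[chrom][max(0, start):end]
    return reverse_complement(seq) if strand == "-" else seq
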