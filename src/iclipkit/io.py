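"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM through pysam; BED6 and the various
TSV tables are handled directly.  All readers validate and reject malformed
records rather than repairing them silently.

Conventions: the 5-bp random tag travels in the read name as a ``#TAG``
suffix, and the sample identifier as a ``sample/`` prefix, so both survive
any aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pysam
from Bio import SeqIO

from .intervals import GenomicInterval
from .tags import AlignedTag

_IUPAC = set("ACGTUNRYSWKMBDHV")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; duplicate names and
    non-IUPAC characters are errors."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in FASTA record {record.id!r}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class FastqRead:
    name: str
    sequence: str
    qualities: str  # phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"sequence/quality length mismatch in read {self.name}")

    def qscores(self) -> list[int]:
        return [ord(c) - 33 for c in self.qualities]


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in record.letter_annotations["phred_quality"])
        reads.append(FastqRead(record.description, str(record.seq).upper(), quals))
    return reads


def write_fastq(reads: list[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{read.qualities}\n")


# ---------------------------------------------------------------------------
# BED6


@dataclass
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    extra: tuple[str, ...] = ()


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a BED6(+) file; start >= end or a bad strand is a format error."""
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith(("track", "browser", "#")):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
        chrom, start, end, name, score, strand = parts[:6]
        try:
            iv = GenomicInterval(chrom, int(start), int(end), strand)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        records.append(BedRecord(iv, name, float(score), tuple(parts[6:])))
    return records


def write_bed(records: list[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            score = int(rec.score) if float(rec.score).is_integer() else rec.score
            cols = [iv.chrom, str(iv.start), str(iv.end), rec.name, str(score), iv.strand]
            cols.extend(rec.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# SAM-lite

_TAG_RE = re.compile(r"#([ACGTN]+)$")
_ALLOWED_CIGAR_OPS = {0, 1, 2}  # M, I, D


def _parse_read_name(qname: str) -> tuple[str, str]:
    """Extract (sample_id, random_tag) from '<sample>/<id>#<TAG>' names;
    both default to '' when absent."""
    sample = qname.split("/", 1)[0] if "/" in qname else ""
    m = _TAG_RE.search(qname)
    return sample, (m.group(1) if m else "")


def read_alignments(path: str | Path) -> list[AlignedTag]:
    """Read SAM (text) alignments into AlignedTag records.

    Deletion genomic positions are taken from CIGAR D operations; reads whose
    name occurs in more than one record are flagged multi-mapping.  CIGAR
    operations other than M/I/D are rejected.
    """
    tags: list[AlignedTag] = []
    name_counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.cigartuples is None:
                raise ValueError(f"alignment {aln.query_name} lacks a CIGAR")
            bad = [op for op, _ in aln.cigartuples if op not in _ALLOWED_CIGAR_OPS]
            if bad:
                raise ValueError(
                    f"unsupported CIGAR operation(s) {bad} in read {aln.query_name}"
                )
            pos = aln.reference_start
            deletions: list[int] = []
            ref_pos = pos
            for op, length in aln.cigartuples:
                if op == 0:  # M
                    ref_pos += length
                elif op == 2:  # D
                    deletions.extend(range(ref_pos, ref_pos + length))
                    ref_pos += length
            strand = "-" if aln.is_reverse else "+"
            sample, tag = _parse_read_name(aln.query_name)
            iv = GenomicInterval(aln.reference_name, pos, ref_pos, strand)
            tags.append(
                AlignedTag(aln.query_name, iv, tag, deletions, sample_id=sample)
            )
            name_counts[aln.query_name] = name_counts.get(aln.query_name, 0) + 1
    for t in tags:
        if name_counts[t.name] > 1:
            t.multi_mapping = True
    return tags


def write_sam(
    tags: list[AlignedTag],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write AlignedTags as minimal text SAM (M/D CIGAR only, SEQ omitted)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for t in tags:
            iv = t.interval
            if t.deletion_positions:
                dels = sorted(t.deletion_positions)
                left = dels[0] - iv.start
                dlen = dels[-1] - dels[0] + 1
                right = iv.end - (dels[0] + dlen)
                cigar = f"{left}M{dlen}D{right}M"
            else:
                cigar = f"{len(iv)}M"
            flag = 16 if iv.strand == "-" else 0
            fh.write(
                "\t".join(
                    [t.name, str(flag), iv.chrom, str(iv.start + 1), "255",
                     cigar, "*", "0", "0", "*", "*"]
                ) + "\n"
            )
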