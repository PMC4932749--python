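"""Gene annotation: GTF reading/writing and exon classification.

The annotation model is deliberately small: genes contain transcripts,
transcripts contain ordered exons and optionally a CDS span.  Exons are
classified as *first*, *last* or *internal* per transcript (in transcript
orientation), and an internal exon is a *cassette* exon when at least one
other transcript of the same gene skips it.  Cassette status may also be
supplied explicitly (e.g. derived from RNA-seq) via ``set_cassette_exons``.

GTF coordinates (1-based inclusive) are converted to the package's 0-based
half-open convention on read and converted back on write.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .intervals import GenomicInterval


@dataclass
class Transcript:
    id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: GenomicInterval | None = None

    @property
    def exons_5to3(self) -> list[GenomicInterval]:
        """Exons ordered 5'→3' in transcript orientation."""
        ordered = sorted(self.exons, key=lambda e: e.start)
        return ordered if self.interval.strand == "+" else ordered[::-1]


@dataclass
class Gene:
    id: str
    interval: GenomicInterval
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def longest_transcript(self) -> Transcript:
        return max(
            self.transcripts.values(),
            key=lambda t: (sum(len(e) for e in t.exons), t.id),
        )


class GenomeAnnotation:
    """Genes/transcripts/exons with per-exon class labels."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes
        self._explicit_cassettes: set[tuple[str, int, int]] | None = None
        self._validate()

    def _validate(self) -> None:
        for gene in self.genes.values():
            for tx in gene.transcripts.values():
                exons = sorted(tx.exons, key=lambda e: e.start)
                for exon in exons:
                    if exon.start < tx.interval.start or exon.end > tx.interval.end:
                        raise ValueError(
                            f"exon {exon.chrom}:{exon.start}-{exon.end} outside "
                            f"transcript {tx.id}"
                        )
                for a, b in zip(exons, exons[1:]):
                    if b.start < a.end:
                        raise ValueError(f"overlapping exons in transcript {tx.id}")

    # -- exon classes ------------------------------------------------------

    def exon_classes(self, gene_id: str) -> dict[tuple[int, int], set[str]]:
        """Map (start, end) of each distinct exon of a gene to its labels.

        Labels are a subset of {first, last, internal, cassette}.  A
        single-exon transcript's exon is both first and last and never
        internal.
        """
        gene = self.genes[gene_id]
        labels: dict[tuple[int, int], set[str]] = {}
        internal_sets: dict[str, set[tuple[int, int]]] = {}
        for tx in gene.transcripts.values():
            ordered = tx.exons_5to3
            internal_sets[tx.id] = set()
            for i, exon in enumerate(ordered):
                key = (exon.start, exon.end)
                tags = labels.setdefault(key, set())
                if i == 0:
                    tags.add("first")
                if i == len(ordered) - 1:
                    tags.add("last")
                if 0 < i < len(ordered) - 1:
                    tags.add("internal")
                    internal_sets[tx.id].add(key)
        if self._explicit_cassettes is not None:
            for (start, end), tags in labels.items():
                if (gene_id, start, end) in self._explicit_cassettes and "internal" in tags:
                    tags.add("cassette")
        else:
            all_keys = {k for s in internal_sets.values() for k in s}
            for key in all_keys:
                absent_somewhere = any(
                    key not in {(e.start, e.end) for e in tx.exons}
                    for tx in gene.transcripts.values()
                )
                if absent_somewhere:
                    labels[key].add("cassette")
        return labels

    def set_cassette_exons(self, records: list[tuple[str, int, int]]) -> None:
        """Override annotation-derived cassette calls with an explicit list
        of (gene_id, start, end) records, e.g. from RNA-seq."""
        self._explicit_cassettes = set(records)

    def exons_with_label(self, label: str) -> list[tuple[str, GenomicInterval]]:
        out = []
        for gene_id, gene in self.genes.items():
            strand = gene.interval.strand
            chrom = gene.interval.chrom
            for (start, end), tags in self.exon_classes(gene_id).items():
                if label in tags:
                    out.append((gene_id, GenomicInterval(chrom, start, end, strand)))
        return sorted(out, key=lambda t: (t[1].chrom, t[1].start, t[0]))

    def cassette_exons(self) -> list[tuple[str, GenomicInterval]]:
        return self.exons_with_label("cassette")


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read a GTF with gene/transcript/exon (and optional CDS) features."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        genes[gid] = Gene(gid, GenomicInterval(g.seqid, g.start - 1, g.end, g.strand))
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        tid = t.attributes["transcript_id"][0]
        if gid not in genes:
            raise ValueError(f"transcript {tid} references unknown gene {gid}")
        genes[gid].transcripts[tid] = Transcript(
            tid, gid, GenomicInterval(t.seqid, t.start - 1, t.end, t.strand)
        )
    for e in db.features_of_type("exon"):
        tid = e.attributes["transcript_id"][0]
        gid = e.attributes["gene_id"][0]
        tx = genes[gid].transcripts[tid]
        tx.exons.append(GenomicInterval(e.seqid, e.start - 1, e.end, e.strand))
    for c in db.features_of_type("CDS"):
        tid = c.attributes["transcript_id"][0]
        gid = c.attributes["gene_id"][0]
        tx = genes[gid].transcripts[tid]
        cds = GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
        tx.cds = cds if tx.cds is None else GenomicInterval(
            cds.chrom, min(tx.cds.start, cds.start), max(tx.cds.end, cds.end), cds.strand
        )
    return GenomeAnnotation(genes)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = []

    def row(feature: str, iv: GenomicInterval, attrs: str) -> str:
        return "\t".join(
            [iv.chrom, "iclipkit", feature, str(iv.start + 1), str(iv.end),
             ".", iv.strand, ".", attrs]
        )

    for gene in sorted(annotation.genes.values(), key=lambda g: (g.interval.chrom, g.interval.start)):
        gattr = f'gene_id "{gene.id}";'
        lines.append(row("gene", gene.interval, gattr))
        for tx in sorted(gene.transcripts.values(), key=lambda t: t.id):
            tattr = f'gene_id "{gene.id}"; transcript_id "{tx.id}";'
            lines.append(row("transcript", tx.interval, tattr))
            for exon in sorted(tx.exons, key=lambda e: e.start):
                lines.append(row("exon", exon, tattr))
            if tx.cds is not None:
                lines.append(row("CDS", tx.cds, tattr))
    Path(path).write_text("\n".join(lines) + "\n")
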