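"""Synthetic iCLIP data with known ground truth.

The generator builds a toy genome of multi-exon genes on alternating strands
embedded in i.i.d. uniform-ACGT background, plants crosslink sites inside the
genes (optionally implanting the binding motif at the site), and emits:

* iCLIP reads following the crosslink model — a molecule either *truncates*
  at the crosslink (its 5' end is one base 3' of the crosslinked base, in
  transcript orientation) or *reads through* it leaving a 1-2 nt deletion at
  the site;
* PCR duplicates: each molecule is sequenced ``1 + Poisson(mean)`` times,
  with per-base substitution errors on the 5-bp random tag;
* the 9-nt 5' barcode ``RRRIIIIRR`` (random tag split 3+2 around the 4-nt
  sample identifier), with adapter read-through when the fragment is shorter
  than the machine read length;
* true alignments (SAM-lite), so tests need no aligner; and
* cassette-exon junction-count tables with configured PSI per condition.

All randomness flows from one integer-seeded generator, so outputs are
byte-reproducible.  See the methods note for what this emulates and what it
deliberately does not (no empirical quality/error model, no fragment-length
distribution, no repetitive genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, Transcript
from .config import DEFAULT_ADAPTER
from .intervals import GenomicInterval
from .io import FastqRead
from .seq import reverse_complement, to_dna
from .tags import AlignedTag

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length_range: tuple[int, int] = (80, 200)
    intron_length_range: tuple[int, int] = (300, 1500)
    intergenic_length_range: tuple[int, int] = (300, 600)
    fraction_cassette: float = 0.3
    motif: str = "UAGGGA"
    motif_implant_rate: float = 0.6
    crosslink_sites_per_gene: int = 20
    molecules_per_site_mean: float = 4.0
    truncation_fraction: float = 0.85
    pcr_duplication_mean: float = 3.0
    tag_error_rate: float = 0.01
    read_length_range: tuple[int, int] = (20, 41)
    adapter: str = DEFAULT_ADAPTER
    barcode_scheme: str = "RRRIIIIRR"
    samples: dict[str, str] = field(default_factory=lambda: {"TTCA": "s1"})
    psi_control: float | None = None  # None: drawn U(0.2, 0.8) per exon
    psi_knockdown: float | None = None  # None: control + delta on a subset
    delta_psi: float = 0.3
    fraction_shifted: float = 0.5
    junction_depth: int = 100
    n_replicates: int = 3
    degrade_quality: bool = False
    multimap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_cassette", "motif_implant_rate", "truncation_fraction",
                     "tag_error_rate", "fraction_shifted", "multimap_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.exons_per_gene[0] < 3 and self.fraction_cassette > 0:
            raise ValueError("cassette exons require >= 3 exons per gene")
        n_random = self.barcode_scheme.count("R")
        if self.read_length_range[0] < n_random:
            raise ValueError("read lengths must exceed the random-tag length")


@dataclass
class TrueSite:
    gene_id: str
    chrom: str
    position: int
    strand: str
    molecules: int
    motif_implanted: bool


@dataclass
class GroundTruth:
    sites: list[TrueSite]
    motif_instances: list[GenomicInterval]
    cassette_exons: list[tuple[str, GenomicInterval]]
    psi: dict[tuple[str, int, int], tuple[float, float]]  # exon -> (ctrl, kd)
    true_tags: dict[str, str] = field(default_factory=dict)  # molecule id -> tag

    def site_positions(self) -> set[tuple[str, int, str]]:
        return {(s.chrom, s.position, s.strand) for s in self.sites}


# ---------------------------------------------------------------------------
# genome + annotation


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation, GroundTruth]:
    """Toy genome, annotation and ground truth under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    motif = to_dna(config.motif)

    genes: dict[str, Gene] = {}
    chrom = "chr1"
    seq_parts: list[str] = []
    cursor = 0
    truth_sites: list[TrueSite] = []
    motif_instances: list[GenomicInterval] = []
    cassette_exons: list[tuple[str, GenomicInterval]] = []
    psi: dict[tuple[str, int, int], tuple[float, float]] = {}

    def random_seq(n: int) -> str:
        return "".join(rng.choice(BASES, size=n))

    for g in range(config.n_genes):
        spacer = int(rng.integers(*config.intergenic_length_range, endpoint=True))
        seq_parts.append(random_seq(spacer))
        cursor += spacer
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"g{g:03d}"
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        exon_lengths = rng.integers(*config.exon_length_range, size=n_exons, endpoint=True)
        intron_lengths = rng.integers(*config.intron_length_range, size=n_exons - 1, endpoint=True)

        gene_start = cursor
        exons: list[GenomicInterval] = []
        for i, elen in enumerate(exon_lengths):
            exons.append(GenomicInterval(chrom, cursor, cursor + int(elen), strand))
            seq_parts.append(random_seq(int(elen)))
            cursor += int(elen)
            if i < n_exons - 1:
                ilen = int(intron_lengths[i])
                seq_parts.append(random_seq(ilen))
                cursor += ilen
        gene_end = cursor
        gene_iv = GenomicInterval(chrom, gene_start, gene_end, strand)

        # exons in transcript orientation; internal exons eligible as cassette
        ordered = exons if strand == "+" else exons[::-1]
        internal = ordered[1:-1]
        cassette = [
            exon for exon in internal if rng.random() < config.fraction_cassette
        ]
        full_tx = Transcript(f"{gene_id}.t1", gene_id, gene_iv, list(exons))
        first, last = ordered[0], ordered[-1]
        # CDS spans mid-first-exon .. mid-last-exon, leaving UTR stubs
        cds_lo = min(first.start + len(first) // 2, last.start + len(last) // 2)
        cds_hi = max(first.start + len(first) // 2, last.start + len(last) // 2)
        full_tx.cds = GenomicInterval(chrom, cds_lo, cds_hi, strand)
        transcripts = {full_tx.id: full_tx}
        if cassette:
            skipped = [e for e in exons if e not in cassette]
            transcripts[f"{gene_id}.t2"] = Transcript(
                f"{gene_id}.t2", gene_id, gene_iv, skipped
            )
        genes[gene_id] = Gene(gene_id, gene_iv, transcripts)
        for exon in cassette:
            cassette_exons.append((gene_id, exon))
            ctrl = (config.psi_control if config.psi_control is not None
                    else float(rng.uniform(0.2, 0.8)))
            if config.psi_knockdown is not None:
                kd = config.psi_knockdown
            elif rng.random() < config.fraction_shifted:
                kd = float(np.clip(ctrl + config.delta_psi, 0.0, 1.0))
            else:
                kd = ctrl
            psi[(gene_id, exon.start, exon.end)] = (ctrl, kd)

        # crosslink sites near-uniform within the gene, away from gene edges,
        # on jittered slots so implanted motifs can never overlap each other
        margin = 60
        spacing = max(12, 2 * len(motif))
        lo, hi = gene_start + margin, gene_end - margin - len(motif)
        slots = np.arange(lo, hi - spacing, spacing)
        chosen = rng.choice(
            slots, size=min(config.crosslink_sites_per_gene, len(slots)),
            replace=False,
        )
        jitter = rng.integers(0, spacing - len(motif), size=len(chosen))
        positions = chosen + jitter
        for pos in sorted(int(p) for p in positions):
            molecules = 1 + int(rng.poisson(max(config.molecules_per_site_mean - 1, 0)))
            implant = rng.random() < config.motif_implant_rate
            truth_sites.append(TrueSite(gene_id, chrom, pos, strand, molecules, implant))

    tail = int(rng.integers(*config.intergenic_length_range, endpoint=True))
    seq_parts.append(random_seq(tail))
    cursor += tail

    sequence = list("".join(seq_parts))
    for site in truth_sites:
        if not site.motif_implanted:
            continue
        if site.strand == "+":
            start = site.position
            sequence[start:start + len(motif)] = motif
        else:
            start = site.position - len(motif) + 1
            sequence[start:start + len(motif)] = reverse_complement(motif)
        motif_instances.append(
            GenomicInterval(chrom, start, start + len(motif), site.strand)
        )
    genome = {chrom: "".join(sequence)}
    truth = GroundTruth(truth_sites, motif_instances, cassette_exons, psi)
    return genome, GenomeAnnotation(genes), truth


# ---------------------------------------------------------------------------
# iCLIP reads


def _mutate_tag(tag: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return tag
    out = []
    for base in tag:
        if rng.random() < rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
    return "".join(out)


def _make_barcode(tag: str, identifier: str, scheme: str) -> str:
    """Interleave random-tag and identifier bases according to the scheme."""
    tag_iter, ident_iter = iter(tag), iter(identifier)
    return "".join(next(tag_iter) if s == "R" else next(ident_iter) for s in scheme)


def simulate_iclip_reads(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[FastqRead], list[AlignedTag]]:
    """Reads (FASTQ records) and their true alignments (AlignedTags).

    Read names are ``<sample>/m<molecule>c<copy>``; the aligned-tag names
    additionally carry the (possibly error-bearing) random tag as ``#TAG``,
    matching what preprocessing produces.
    """
    rng = np.random.default_rng(config.seed + 1)
    scheme = config.barcode_scheme
    n_random = scheme.count("R")
    n_ident = scheme.count("I")
    identifiers = list(config.samples)
    for ident in identifiers:
        if len(ident) != n_ident:
            raise ValueError(f"identifier {ident!r} does not fit scheme {scheme}")
    machine_length = len(scheme) + config.read_length_range[1]
    chrom_len = {c: len(s) for c, s in genome.items()}

    reads: list[FastqRead] = []
    alignments: list[AlignedTag] = []
    mol_counter = 0
    for site in truth.sites:
        p, chrom, strand = site.position, site.chrom, site.strand
        for _ in range(site.molecules):
            mol_counter += 1
            identifier = identifiers[int(rng.integers(len(identifiers)))]
            sample = config.samples[identifier]
            mol_id = f"{sample}/m{mol_counter}"
            true_tag = "".join(rng.choice(BASES, size=n_random))
            truth.true_tags[mol_id] = true_tag
            frag_len = int(rng.integers(*config.read_length_range, endpoint=True))
            truncated = rng.random() < config.truncation_fraction
            if truncated:
                if strand == "+":
                    span = (p + 1, p + 1 + frag_len)
                else:
                    span = (p - frag_len, p)
                deletions: list[int] = []
            else:
                dlen = int(rng.integers(1, 2, endpoint=True))
                left = int(rng.integers(5, max(6, frag_len - 5)))
                if strand == "+":
                    span = (p - left, p - left + frag_len + dlen)
                    deletions = list(range(p, p + dlen))
                else:
                    end = p + 1 + left
                    span = (end - frag_len - dlen, end)
                    deletions = list(range(p - dlen + 1, p + 1))
            if span[0] < 0 or span[1] > chrom_len[chrom]:
                continue
            fwd = genome[chrom][span[0]:span[1]]
            if deletions:
                d0, d1 = min(deletions), max(deletions) + 1
                fwd = genome[chrom][span[0]:d0] + genome[chrom][d1:span[1]]
            fragment = fwd if strand == "+" else reverse_complement(fwd)

            n_copies = 1 + int(rng.poisson(config.pcr_duplication_mean))
            multimap = rng.random() < config.multimap_fraction
            for copy in range(n_copies):
                tag = _mutate_tag(true_tag, config.tag_error_rate, rng)
                name = f"{mol_id}c{copy}"
                barcode = _make_barcode(tag, identifier, scheme)
                seq = barcode + fragment
                if len(seq) < machine_length:
                    fill = config.adapter + "".join(
                        rng.choice(BASES, size=machine_length)
                    )
                    seq = (seq + fill)[:machine_length]
                quals = "I" * len(seq)
                if config.degrade_quality:
                    quals = quals[:-5] + "#" * 5
                reads.append(FastqRead(name, seq, quals))
                aln_name = f"{name}#{tag}"
                alignments.append(
                    AlignedTag(
                        aln_name,
                        GenomicInterval(chrom, span[0], span[1], strand),
                        tag, list(deletions),
                        multi_mapping=multimap, sample_id=sample,
                    )
                )
                if multimap:
                    decoy_start = (span[0] + 5000) % (chrom_len[chrom] - frag_len - 10)
                    alignments.append(
                        AlignedTag(
                            aln_name,
                            GenomicInterval(chrom, decoy_start, decoy_start + frag_len, strand),
                            tag, [], multi_mapping=True, sample_id=sample,
                        )
                    )
    return reads, alignments


# ---------------------------------------------------------------------------
# junction counts


def simulate_junction_counts(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-replicate inclusion/exclusion junction counts for both conditions:
    inclusion ~ Binomial(junction_depth, psi), exclusion = depth - inclusion."""
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for gene_id, exon in truth.cassette_exons:
        ctrl_psi, kd_psi = truth.psi[(gene_id, exon.start, exon.end)]
        for condition, p in (("control", ctrl_psi), ("knockdown", kd_psi)):
            for rep in range(1, config.n_replicates + 1):
                inclusion = int(rng.binomial(config.junction_depth, p))
                rows.append(
                    {"gene": gene_id, "chrom": exon.chrom, "start": exon.start,
                     "end": exon.end, "strand": exon.strand,
                     "replicate": rep, "condition": condition,
                     "inclusion": inclusion,
                     "exclusion": config.junction_depth - inclusion}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional exact-substring aligner (error-free smoke tests only)


def exact_align(
    reads: list, genome: dict[str, str], tag_from_name: bool = True
) -> list[AlignedTag]:
    """Align reads by exact substring search on both strands.

    Intended for end-to-end smoke tests in the error-free, truncation-only
    setting (it cannot place reads with deletions).  Reads occurring at more
    than one locus are flagged multi-mapping.
    """
    tags: list[AlignedTag] = []
    for read in reads:
        seq = read.sequence
        occurrences: list[tuple[str, int, str]] = []
        for chrom, ref in genome.items():
            for query, strand in ((seq, "+"), (reverse_complement(seq), "-")):
                start = ref.find(query)
                while start != -1:
                    occurrences.append((chrom, start, strand))
                    start = ref.find(query, start + 1)
        multi = len(occurrences) > 1
        tag = read.name.rsplit("#", 1)[1] if tag_from_name and "#" in read.name else ""
        sample = read.name.split("/", 1)[0] if "/" in read.name else ""
        for chrom, start, strand in occurrences:
            tags.append(
                AlignedTag(
                    read.name,
                    GenomicInterval(chrom, start, start + len(seq), strand),
                    tag, [], multi_mapping=multi, sample_id=sample,
                )
            )
    return tags
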