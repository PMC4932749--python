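"""Read preprocessing: barcode extraction, demultiplexing and trimming.

The 5' barcode scheme is a string over {R, I}: R positions hold random
(UMI) bases, I positions hold the sample identifier.  Under the default
``RRRIIIIRR`` scheme the two random segments are stitched together, in read
order, into a 5-bp random tag used later for PCR-duplicate removal; the tag
is appended to the read name as ``#TAG`` so it survives alignment.

Order of operations in :func:`preprocess_reads`: barcode parse -> quality
trim -> adapter trim -> length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .io import FastqRead


@dataclass
class BarcodedRead:
    name: str
    sequence: str
    qualities: str
    sample_id: str
    random_tag: str


@dataclass
class PreprocessSummary:
    """Per-fate read counts; assigned + unassigned + too_short == input."""

    n_input: int = 0
    n_too_short: int = 0
    n_unassigned: int = 0
    n_assigned: int = 0
    n_length_filtered: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)


def parse_barcode(read: FastqRead, scheme: str = "RRRIIIIRR") -> BarcodedRead | None:
    """Split off the barcode; returns None for reads not longer than the
    scheme (the caller counts discards)."""
    if len(read.sequence) <= len(scheme):
        return None
    tag = "".join(b for b, s in zip(read.sequence, scheme) if s == "R")
    sample = "".join(b for b, s in zip(read.sequence, scheme) if s == "I")
    name = f"{read.name}#{tag}"
    return BarcodedRead(
        name, read.sequence[len(scheme):], read.qualities[len(scheme):], sample, tag
    )


def demultiplex(
    reads: list[BarcodedRead], sample_sheet: dict[str, str]
) -> tuple[dict[str, list[BarcodedRead]], list[BarcodedRead]]:
    """Assign reads to samples by exact identifier match.

    ``sample_sheet`` maps the I-segment (e.g. a 4-mer) to a sample name.
    Returns ({sample: reads}, unassigned).  Duplicate identifiers or
    identifiers of the wrong length are configuration errors.
    """
    lengths = {len(k) for k in sample_sheet}
    if len(sample_sheet) != len(set(sample_sheet.values())) or len(lengths) > 1:
        raise ValueError("sample sheet identifiers must be distinct and equal-length")
    by_sample: dict[str, list[BarcodedRead]] = {s: [] for s in sample_sheet.values()}
    unassigned: list[BarcodedRead] = []
    for read in reads:
        sample = sample_sheet.get(read.sample_id)
        if sample is None:
            unassigned.append(read)
        else:
            by_sample[sample].append(read)
    return by_sample, unassigned


def trim_adapter(
    sequence: str,
    adapter: str,
    max_mismatch: int = 1,
    min_overlap: int = 3,
) -> str:
    """Remove a 3' adapter allowing up to ``max_mismatch`` substitutions.

    The longest 3'-terminal match to a prefix of the adapter (at least
    ``min_overlap`` nt) is removed; a full adapter occurrence anywhere in the
    read truncates from the match start.  No indels are considered.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, alen = len(sequence), len(adapter)
    for i in range(n):
        seg_len = min(alen, n - i)
        terminal = i + seg_len == n
        full = seg_len == alen
        if not (full or terminal) or seg_len < min_overlap:
            continue
        mismatches = sum(
            a != b for a, b in zip(sequence[i:i + seg_len], adapter[:seg_len])
        )
        if mismatches <= max_mismatch:
            return sequence[:i]
    return sequence


def quality_trim(read: BarcodedRead, threshold: int = 20) -> BarcodedRead:
    """3' quality trimming by the running-sum rule.

    Scanning from the 3' end, the running sum of (threshold - q) is tracked;
    the read is cut at the position where that sum is maximal (and positive).
    Reads of uniformly high quality are returned unchanged.
    """
    scores = [ord(c) - 33 for c in read.qualities]
    best_sum, running, cut = 0, 0, len(scores)
    for i in range(len(scores) - 1, -1, -1):
        running += threshold - scores[i]
        if running > best_sum:
            best_sum, cut = running, i
    return BarcodedRead(
        read.name, read.sequence[:cut], read.qualities[:cut],
        read.sample_id, read.random_tag,
    )


def length_filter(reads: list[BarcodedRead], min_length: int = 20) -> list[BarcodedRead]:
    """Retain reads of ``min_length`` nt or more (post-barcode, post-trim)."""
    return [r for r in reads if len(r.sequence) >= min_length]


def preprocess_reads(
    reads: list[FastqRead],
    sample_sheet: dict[str, str],
    config: PipelineConfig | None = None,
) -> tuple[dict[str, list[BarcodedRead]], PreprocessSummary]:
    """Full preprocessing stage; returns per-sample trimmed reads + summary."""
    config = config or PipelineConfig()
    summary = PreprocessSummary(n_input=len(reads))
    parsed: list[BarcodedRead] = []
    for read in reads:
        barcoded = parse_barcode(read, config.barcode_scheme)
        if barcoded is None:
            summary.n_too_short += 1
        else:
            parsed.append(barcoded)
    by_sample, unassigned = demultiplex(parsed, sample_sheet)
    summary.n_unassigned = len(unassigned)
    summary.n_assigned = sum(len(v) for v in by_sample.values())
    out: dict[str, list[BarcodedRead]] = {}
    for sample, sample_reads in by_sample.items():
        trimmed = []
        for read in sample_reads:
            read = quality_trim(read, config.quality_threshold)
            seq = trim_adapter(
                read.sequence, config.adapter,
                config.adapter_max_mismatch, config.adapter_min_overlap,
            )
            trimmed.append(
                BarcodedRead(read.name, seq, read.qualities[:len(seq)],
                             read.sample_id, read.random_tag)
            )
        kept = length_filter(trimmed, config.min_read_length)
        summary.n_length_filtered += len(trimmed) - len(kept)
        summary.per_sample[sample] = len(kept)
        out[sample] = kept
    return out, summary
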