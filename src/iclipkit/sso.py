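"""Splice-switching oligonucleotide (SSO) target selection.

Binding peaks located immediately — 10 to 40 nt — downstream of the 5'
splice site (donor) of a repressed cassette exon or pseudoexon are good SSO
targets: an antisense oligo over the silencer displaces the repressor
without occluding the donor itself.  Distances are measured in transcript
orientation from the first intronic base (donor +1) to the peak's nearest
edge, matching how such distances are reported (a peak starting at the 11th
intronic base is "11 nt downstream").

Candidates are ranked by ``(sum of motif-hit scores in the target window) *
log2(1 + peak height)`` — a labelled heuristic combining motif content and
peak strength — and an antisense RNA oligo is proposed over the motif span,
never overlapping the 9-nt donor region (exon -3 ... intron +6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import math

from .intervals import GenomicInterval
from .motif import MotifHit, ScoringMatrix, scan_sequence
from .peaks import Peak
from .seq import fetch, reverse_complement, to_rna

DONOR_EXONIC, DONOR_INTRONIC = 3, 6  # protected donor region: exon -3 .. intron +6


@dataclass
class SsoCandidate:
    exon_id: str
    exon: GenomicInterval
    peak: Peak
    distance_to_5ss: int  # nt from donor +1 to the peak's nearest edge
    motif_hits: list[MotifHit] = field(default_factory=list)
    rank_score: float = 0.0
    proposed_sso: str = ""


def _donor_end(exon: GenomicInterval) -> int:
    """Genomic coordinate of the first intronic base downstream of the donor
    (donor +1): ``exon.end`` on +, ``exon.start - 1`` on -."""
    return exon.end if exon.strand == "+" else exon.start - 1


def _intronic_offset(exon: GenomicInterval, genomic_pos: int) -> int:
    """1-based distance of a genomic position into the downstream intron."""
    if exon.strand == "+":
        return genomic_pos - exon.end + 1
    return exon.start - genomic_pos


def _window_interval(exon: GenomicInterval, window: tuple[int, int]) -> GenomicInterval:
    """Genomic interval of intronic offsets [window.min, window.max]."""
    lo, hi = window
    if exon.strand == "+":
        return GenomicInterval(exon.chrom, exon.end + lo - 1, exon.end + hi, "+")
    return GenomicInterval(exon.chrom, exon.start - hi, exon.start - lo + 1, "-")


def find_sso_candidates(
    peaks: list[Peak],
    exons: list[tuple[str, GenomicInterval]],
    genome: dict[str, str],
    matrix: ScoringMatrix,
    window: tuple[int, int] = (10, 40),
    motif_threshold: float | None = None,
) -> list[SsoCandidate]:
    """Peaks whose nearest edge lies within [min, max] nt downstream of the
    donor of a given exon, ranked by motif content x peak strength.

    ``exons`` are (id, interval) pairs — typically repressed cassette exons
    from the splicing module, optionally extended with user pseudoexons.
    Boundaries are inclusive: offsets of exactly ``window[0]`` or
    ``window[1]`` qualify.
    """
    lo, hi = window
    if motif_threshold is None:
        motif_threshold = matrix.max_score / 2  # half-maximum: permissive but
        # excludes windows scoring like background
    candidates = []
    for exon_id, exon in exons:
        chrom_len = len(genome.get(exon.chrom, ""))
        if _donor_end(exon) < 0 or _donor_end(exon) >= chrom_len:
            warnings.warn(f"exon {exon_id} has no annotated donor within the genome")
            continue
        target = _window_interval(exon, window)
        target_seq = fetch(genome, target.chrom, target.start, target.end, target.strand)
        hits = scan_sequence(target_seq, matrix, motif_threshold)
        for peak in peaks:
            if peak.interval.chrom != exon.chrom or peak.strand != exon.strand:
                continue
            edges = (
                _intronic_offset(exon, peak.interval.start),
                _intronic_offset(exon, peak.interval.end - 1),
            )
            # nearest edge = smallest positive offset of the two peak ends
            distance = min(edges)
            if not lo <= distance <= hi:
                continue
            rank = sum(h.score for h in hits) * math.log2(1 + peak.height)
            candidates.append(
                SsoCandidate(exon_id, exon, peak, distance, hits, rank)
            )
    candidates.sort(
        key=lambda c: (-c.rank_score, c.distance_to_5ss,
                       c.peak.interval.chrom, c.peak.interval.start)
    )
    for cand in candidates:
        cand.proposed_sso = propose_sso(cand, genome, matrix=matrix, window=window)
    return candidates


def propose_sso(
    candidate: SsoCandidate,
    genome: dict[str, str],
    length_range: tuple[int, int] = (18, 25),
    matrix: ScoringMatrix | None = None,
    window: tuple[int, int] = (10, 40),
) -> str:
    """Antisense RNA oligo covering the candidate's motif hits.

    The shortest window within ``length_range`` covering all motif hits is
    chosen (extended symmetrically up to the minimum length), clipped so it
    never overlaps the donor region (exon -3 ... intron +6), then
    reverse-complemented into the RNA alphabet.  If the motif span exceeds
    the maximum length a maximal-coverage oligo is emitted with a warning.
    """
    min_len, max_len = length_range
    exon = candidate.exon
    target = _window_interval(exon, window)
    # motif-hit offsets are relative to the target window's 5' end
    if candidate.motif_hits:
        span_lo = min(h.start for h in candidate.motif_hits)
        span_hi = max(h.end for h in candidate.motif_hits)
    else:  # no motif hit: centre on the peak within the window
        span_lo = max(0, candidate.distance_to_5ss - window[0])
        span_hi = span_lo + 1
    if span_hi - span_lo > max_len:
        warnings.warn(
            f"motif span {span_hi - span_lo} nt exceeds maximum SSO length "
            f"{max_len}; emitting maximal-coverage oligo"
        )
        span_hi = span_lo + max_len
    # pad symmetrically to the minimum length
    while span_hi - span_lo < min_len:
        if span_lo > 0:
            span_lo -= 1
        if span_hi - span_lo < min_len:
            span_hi += 1
    # the target window starts at intronic offset window[0] >= 10, which is
    # already clear of the protected donor region (intron +6); clip anyway.
    span_lo = max(span_lo, 0)
    if exon.strand == "+":
        g_lo = target.start + span_lo
        g_hi = target.start + span_hi
        g_lo = max(g_lo, exon.end + DONOR_INTRONIC)
        sense = genome[exon.chrom][g_lo:g_hi]
    else:
        g_hi = target.end - span_lo
        g_lo = target.end - span_hi
        g_hi = min(g_hi, exon.start - DONOR_INTRONIC)
        sense = reverse_complement(genome[exon.chrom][g_lo:g_hi])
    return to_rna(reverse_complement(sense))
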