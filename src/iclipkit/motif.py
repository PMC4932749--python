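"""Motif discovery and scoring for RNA-binding-protein peaks.

Enrichment is exact k-mer counting of peak (sense-strand) sequences against a
length-matched background — by default a dinucleotide-shuffled copy of the
foreground, alternatively uniform-random sequence.  The top enriched k-mer
plus its one-mismatch neighbours observed in the foreground define the
frequency matrix; the scoring matrix is the per-position
``log2((frequency + pseudocount) / (background + pseudocount))`` transform
against a uniform 0.25 background, so a perfectly conserved base scores
log2(4) = 2 bits at pseudocount 0.  Sequences may be given as DNA or RNA
(U and T are equivalent); only the sense strand is ever scanned, because
iCLIP is strand-specific.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seq import to_dna, to_rna

BASES = "ACGT"


@dataclass
class FrequencyMatrix:
    freq: np.ndarray  # (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("frequency matrix must be (width, 4)")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency matrix rows must sum to 1")

    @property
    def width(self) -> int:
        return self.freq.shape[0]


@dataclass
class ScoringMatrix:
    score: np.ndarray  # (width, 4) log2 scores

    @property
    def width(self) -> int:
        return self.score.shape[0]

    def score_kmer(self, kmer: str) -> float:
        kmer = to_dna(kmer)
        if len(kmer) != self.width:
            raise ValueError(f"k-mer length {len(kmer)} != matrix width {self.width}")
        return float(sum(self.score[i, BASES.index(b)] for i, b in enumerate(kmer)))

    @property
    def max_score(self) -> float:
        return float(self.score.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return to_rna("".join(BASES[i] for i in self.score.argmax(axis=1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.score, columns=list("ACGU"))


@dataclass
class MotifHit:
    start: int  # 0-based offset in the scanned sequence
    kmer: str
    score: float

    @property
    def end(self) -> int:
        return self.start + len(self.kmer)


# ---------------------------------------------------------------------------
# k-mer enrichment


def _count_kmers(sequences: list[str], k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    n_windows = 0
    for seq in sequences:
        seq = to_dna(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if set(kmer) <= set(BASES):
                counts[kmer] += 1
                n_windows += 1
    return counts, n_windows


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Background model preserving (approximate) dinucleotide content:
    the sequence is cut into non-overlapping doublets which are permuted."""
    seq = to_dna(seq)
    doublets = [seq[i:i + 2] for i in range(0, len(seq) - 1, 2)]
    tail = seq[len(doublets) * 2:]
    order = rng.permutation(len(doublets))
    return "".join(doublets[i] for i in order) + tail


def make_background(
    foreground: list[str],
    rng: np.random.Generator,
    method: str = "shuffle",
) -> list[str]:
    """Length-matched background: dinucleotide shuffle of the foreground
    ('shuffle', default) or i.i.d. uniform ACGT ('uniform')."""
    if method == "shuffle":
        return [dinucleotide_shuffle(s, rng) for s in foreground]
    if method == "uniform":
        return ["".join(rng.choice(list(BASES), size=len(s))) for s in foreground]
    raise ValueError(f"unknown background method {method!r}")


def kmer_enrichment(
    foreground: list[str],
    background: list[str],
    k_values: tuple[int, ...] = (6, 7, 8),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Rank k-mers by enrichment of foreground over background counts.

    For each k, every k-mer seen in either set is scored with a one-sided
    binomial test (foreground occurrences out of foreground windows, null
    rate = background frequency with ``pseudocount`` smoothing) and
    BH-adjusted within its k.  Sorted by p then fold, descending fold.
    """
    if not foreground:
        raise ValueError("empty foreground")
    rows = []
    for k in sorted(k_values):
        fg_counts, fg_total = _count_kmers(foreground, k)
        bg_counts, bg_total = _count_kmers(background, k)
        if fg_total == 0 or bg_total == 0:
            continue
        kmers = sorted(set(fg_counts) | set(bg_counts))
        pvals = []
        for kmer in kmers:
            fg, bg = fg_counts[kmer], bg_counts[kmer]
            rate = (bg + pseudocount) / (bg_total + pseudocount)
            fold = ((fg + pseudocount) / (fg_total + pseudocount)) / rate
            p = stats.binomtest(fg, fg_total, min(rate, 1.0), alternative="greater").pvalue
            rows.append(
                {"k": k, "kmer": to_rna(kmer), "fg_count": fg, "bg_count": bg,
                 "fg_total": fg_total, "bg_total": bg_total,
                 "fold": fold, "p_value": p}
            )
            pvals.append(p)
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for row, q in zip(rows[-len(kmers):], adj):
            row["fdr"] = float(q)
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["p_value", "fold"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def top_kmer(table: pd.DataFrame, k: int) -> str:
    sub = table[table["k"] == k]
    if sub.empty:
        raise ValueError(f"no k-mers of length {k} in enrichment table")
    return str(sub.iloc[0]["kmer"])


# ---------------------------------------------------------------------------
# matrices


def motif_instances(
    foreground: list[str], kmer: str, max_mismatch: int = 1
) -> list[str]:
    """Occurrences in the foreground of ``kmer`` or any k-mer within
    ``max_mismatch`` substitutions of it (ungapped, sense strand)."""
    kmer = to_dna(kmer)
    k = len(kmer)
    out = []
    for seq in foreground:
        seq = to_dna(seq)
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if set(window) <= set(BASES) and sum(
                a != b for a, b in zip(window, kmer)
            ) <= max_mismatch:
                out.append(window)
    return out


def build_frequency_matrix(instances: list[str]) -> FrequencyMatrix:
    if not instances:
        raise ValueError("at least one instance required")
    instances = [to_dna(s) for s in instances]
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("instances must have equal length")
    counts = np.zeros((width, 4))
    for inst in instances:
        for i, base in enumerate(inst):
            counts[i, BASES.index(base)] += 1
    return FrequencyMatrix(counts / len(instances))


def build_scoring_matrix(
    freq: FrequencyMatrix,
    background: float = 0.25,
    pseudocount: float = 0.001,
) -> ScoringMatrix:
    if not 0 < background < 1:
        raise ValueError("background must be in (0, 1)")
    with np.errstate(divide="ignore"):  # pseudocount 0 legitimately gives -inf
        score = np.log2((freq.freq + pseudocount) / (background + pseudocount))
    return ScoringMatrix(score)


# ---------------------------------------------------------------------------
# scanning


def scan_sequence(
    seq: str, matrix: ScoringMatrix, threshold: float
) -> list[MotifHit]:
    """All windows of the sequence scoring >= threshold (sense strand only)."""
    seq_dna = to_dna(seq)
    hits = []
    for i in range(len(seq_dna) - matrix.width + 1):
        window = seq_dna[i:i + matrix.width]
        if set(window) <= set(BASES):
            score = matrix.score_kmer(window)
            if score >= threshold:
                hits.append(MotifHit(i, to_rna(window), score))
    return hits


def _best_overlapping_score(
    seq: str, matrix: ScoringMatrix, position: int
) -> float:
    scores = [
        matrix.score_kmer(to_dna(seq)[i:i + matrix.width])
        for i in range(max(0, position - matrix.width + 1),
                       min(position + 1, len(seq) - matrix.width + 1))
        if set(to_dna(seq)[i:i + matrix.width]) <= set(BASES)
    ]
    if not scores:
        raise ValueError("no scannable window overlaps the variant position")
    return max(scores)


def variant_effect(
    seq: str, variant: tuple[int, str, str], matrix: ScoringMatrix
) -> float:
    """Score change of the best motif window overlapping a substitution.

    ``variant`` is (0-based position, ref base, alt base); a negative delta
    predicts disrupted binding, a positive delta a gained/strengthened site.
    """
    position, ref, alt = variant
    seq_dna = to_dna(seq)
    if seq_dna[position] != to_dna(ref):
        raise ValueError(
            f"reference base mismatch at position {position}: "
            f"sequence has {seq_dna[position]}, variant says {to_dna(ref)}"
        )
    alt_seq = seq_dna[:position] + to_dna(alt) + seq_dna[position + 1:]
    return _best_overlapping_score(alt_seq, matrix, position) - _best_overlapping_score(
        seq_dna, matrix, position
    )


def discover_motif(
    foreground: list[str],
    rng: np.random.Generator,
    k_values: tuple[int, ...] = (6, 7, 8),
    background_method: str = "shuffle",
    pick_k: int = 6,
    scoring_background: float = 0.25,
    pseudocount: float = 0.001,
) -> tuple[pd.DataFrame, FrequencyMatrix, ScoringMatrix]:
    """Enrichment table + frequency/scoring matrices for the top ``pick_k``-mer."""
    background = make_background(foreground, rng, background_method)
    table = kmer_enrichment(foreground, background, k_values)
    best = top_kmer(table, pick_k)
    freq = build_frequency_matrix(motif_instances(foreground, best))
    scoring = build_scoring_matrix(freq, scoring_background, pseudocount)
    return table, freq, scoring
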