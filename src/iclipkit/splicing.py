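"""Cassette-exon splicing quantification from junction counts.

For each cassette exon, percent spliced in is
``PSI = inclusion / (inclusion + exclusion)`` per replicate; conditions are
summarised by the mean replicate PSI.  Knockdown and control are compared by

* ``delta_psi = psi_knockdown - psi_control``,
* ``log2fc = log2((psi_kd + 0.01) / (psi_ctrl + 0.01))`` — the 1%
  pseudoinclusion keeps completely skipped exons finite, and
* a two-sided Fisher exact test on the pooled (inclusion, exclusion) counts
  per condition, BH-adjusted across events.

Because the profiled factor is a splicing repressor, a significant event
whose inclusion *rises* on knockdown is classified ``repressed`` (the factor
was holding it down) and one whose inclusion falls is ``activated``.

The Fisher test on pooled counts ignores replicate overdispersion; see the
methods note for the consequences and the extension point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .intervals import GenomicInterval
from .seq import fetch, gc_content

PSEUDOINCLUSION = 0.01


@dataclass
class CassetteExonEvent:
    gene_id: str
    exon: GenomicInterval
    control_counts: list[tuple[int, int]]  # (inclusion, exclusion) per replicate
    knockdown_counts: list[tuple[int, int]]
    psi_control: float = float("nan")
    psi_knockdown: float = float("nan")
    delta_psi: float = float("nan")
    log2fc: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    regulation_class: str = "neutral"


def compute_psi(inclusion: int, exclusion: int) -> float | None:
    """PSI = inclusion / (inclusion + exclusion); None when unquantifiable."""
    if inclusion < 0 or exclusion < 0:
        raise ValueError("junction counts must be non-negative")
    total = inclusion + exclusion
    if total == 0:
        return None
    return inclusion / total


def _condition_psi(counts: list[tuple[int, int]]) -> float | None:
    psis = [psi for inc, exc in counts if (psi := compute_psi(inc, exc)) is not None]
    return float(np.mean(psis)) if psis else None


def compare_conditions(
    control_counts: list[tuple[int, int]],
    knockdown_counts: list[tuple[int, int]],
) -> tuple[float, float, float, float, float] | None:
    """(psi_control, psi_knockdown, delta_psi, log2fc, p_value) or None when
    a condition has no quantifiable replicate."""
    psi_ctrl = _condition_psi(control_counts)
    psi_kd = _condition_psi(knockdown_counts)
    if psi_ctrl is None or psi_kd is None:
        return None
    log2fc = math.log2((psi_kd + PSEUDOINCLUSION) / (psi_ctrl + PSEUDOINCLUSION))
    pooled_ctrl = tuple(map(sum, zip(*control_counts)))
    pooled_kd = tuple(map(sum, zip(*knockdown_counts)))
    _, p = stats.fisher_exact([list(pooled_ctrl), list(pooled_kd)], alternative="two-sided")
    return psi_ctrl, psi_kd, psi_kd - psi_ctrl, log2fc, float(p)


def classify_events(
    events: list[CassetteExonEvent], fdr_threshold: float = 0.10
) -> list[CassetteExonEvent]:
    """Attach BH FDR across all quantifiable events and classify each as
    repressed (inclusion up on knockdown), activated (down) or neutral."""
    quantifiable = []
    for event in events:
        result = compare_conditions(event.control_counts, event.knockdown_counts)
        if result is None:
            event.regulation_class = "unquantifiable"
            continue
        (event.psi_control, event.psi_knockdown, event.delta_psi,
         event.log2fc, event.p_value) = result
        quantifiable.append(event)
    if quantifiable:
        _, adjusted, _, _ = multipletests(
            [e.p_value for e in quantifiable], method="fdr_bh"
        )
        for event, fdr in zip(quantifiable, adjusted):
            event.fdr = float(fdr)
            if event.fdr < fdr_threshold and event.delta_psi > 0:
                event.regulation_class = "repressed"
            elif event.fdr < fdr_threshold and event.delta_psi < 0:
                event.regulation_class = "activated"
            else:
                event.regulation_class = "neutral"
    return events


# ---------------------------------------------------------------------------
# junction-count table I/O


def read_junction_counts(path: str) -> list[CassetteExonEvent]:
    """Read a junction-count TSV with columns gene, chrom, start, end, strand,
    replicate, condition (control/knockdown), inclusion, exclusion."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end", "strand",
                "replicate", "condition", "inclusion", "exclusion"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"junction table missing columns {sorted(missing)}")
    events = []
    for (gene, chrom, start, end, strand), group in table.groupby(
        ["gene", "chrom", "start", "end", "strand"], sort=True
    ):
        counts: dict[str, list[tuple[int, int]]] = {"control": [], "knockdown": []}
        for _, row in group.sort_values("replicate").iterrows():
            condition = str(row["condition"])
            if condition not in counts:
                raise ValueError(f"unknown condition {condition!r} for gene {gene}")
            counts[condition].append((int(row["inclusion"]), int(row["exclusion"])))
        events.append(
            CassetteExonEvent(
                str(gene), GenomicInterval(str(chrom), int(start), int(end), str(strand)),
                counts["control"], counts["knockdown"],
            )
        )
    return events


def events_to_frame(events: list[CassetteExonEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": e.gene_id, "chrom": e.exon.chrom, "start": e.exon.start,
            "end": e.exon.end, "strand": e.exon.strand,
            "psi_control": e.psi_control, "psi_knockdown": e.psi_knockdown,
            "delta_psi": e.delta_psi, "log2fc": e.log2fc,
            "p_value": e.p_value, "fdr": e.fdr, "class": e.regulation_class,
        }
        for e in events
    )


# ---------------------------------------------------------------------------
# splice-site strength


class PwmSpliceScorer:
    """First-order PWM splice-site scorer trained on annotated junctions.

    Donor windows cover the last 3 exonic + first 6 intronic bases; acceptor
    windows the last 20 intronic + first 3 exonic bases.  Scores are summed
    per-position log2 frequency ratios against a uniform 0.25 background.
    This built-in scorer exists to drive the group comparisons; any callable
    mapping a window sequence to a score (e.g. a MaxEnt implementation) can
    be plugged in instead.
    """

    DONOR_EXON, DONOR_INTRON = 3, 6
    ACCEPTOR_INTRON, ACCEPTOR_EXON = 20, 3

    def __init__(self, donor_pwm: np.ndarray, acceptor_pwm: np.ndarray):
        self.donor_pwm = donor_pwm
        self.acceptor_pwm = acceptor_pwm

    @classmethod
    def train(cls, annotation: GenomeAnnotation, genome: dict[str, str],
              pseudocount: float = 0.5) -> "PwmSpliceScorer":
        donors, acceptors = [], []
        for gene in annotation.genes.values():
            for tx in gene.transcripts.values():
                for d, a in _junction_windows(tx, genome):
                    if d is not None:
                        donors.append(d)
                    if a is not None:
                        acceptors.append(a)
        return cls(_train_pwm(donors, pseudocount), _train_pwm(acceptors, pseudocount))

    def _score(self, window: str, pwm: np.ndarray) -> float:
        if len(window) != pwm.shape[0]:
            raise ValueError(f"window length {len(window)} != PWM width {pwm.shape[0]}")
        return float(sum(pwm[i, "ACGT".index(b)] for i, b in enumerate(window.upper())
                         if b in "ACGT"))

    def donor_score(self, window: str) -> float:
        return self._score(window, self.donor_pwm)

    def acceptor_score(self, window: str) -> float:
        return self._score(window, self.acceptor_pwm)


def _train_pwm(windows: list[str], pseudocount: float) -> np.ndarray:
    if not windows:
        raise ValueError("no training windows")
    width = len(windows[0])
    counts = np.full((width, 4), pseudocount)
    for w in windows:
        for i, b in enumerate(w.upper()):
            if b in "ACGT":
                counts[i, "ACGT".index(b)] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return np.log2(freq / 0.25)


def _junction_windows(tx, genome):
    """Yield (donor_window, acceptor_window) per internal junction of a
    transcript, in transcript orientation (either may be None at contig
    edges)."""
    exons = tx.exons_5to3
    strand = tx.interval.strand
    for upstream, downstream in zip(exons, exons[1:]):
        if strand == "+":
            donor = fetch(genome, upstream.chrom,
                          upstream.end - PwmSpliceScorer.DONOR_EXON,
                          upstream.end + PwmSpliceScorer.DONOR_INTRON, "+")
            acceptor = fetch(genome, downstream.chrom,
                             downstream.start - PwmSpliceScorer.ACCEPTOR_INTRON,
                             downstream.start + PwmSpliceScorer.ACCEPTOR_EXON, "+")
        else:
            donor = fetch(genome, upstream.chrom,
                          upstream.start - PwmSpliceScorer.DONOR_INTRON,
                          upstream.start + PwmSpliceScorer.DONOR_EXON, "-")
            acceptor = fetch(genome, downstream.chrom,
                             downstream.end - PwmSpliceScorer.ACCEPTOR_EXON,
                             downstream.end + PwmSpliceScorer.ACCEPTOR_INTRON, "-")
        expected_d = PwmSpliceScorer.DONOR_EXON + PwmSpliceScorer.DONOR_INTRON
        expected_a = PwmSpliceScorer.ACCEPTOR_EXON + PwmSpliceScorer.ACCEPTOR_INTRON
        yield (donor if len(donor) == expected_d else None,
               acceptor if len(acceptor) == expected_a else None)


def exon_site_windows(exon: GenomicInterval, genome: dict[str, str]) -> tuple[str, str]:
    """(donor_window, acceptor_window) for one exon in transcript orientation."""
    if exon.strand == "+":
        donor = fetch(genome, exon.chrom, exon.end - PwmSpliceScorer.DONOR_EXON,
                      exon.end + PwmSpliceScorer.DONOR_INTRON, "+")
        acceptor = fetch(genome, exon.chrom,
                         exon.start - PwmSpliceScorer.ACCEPTOR_INTRON,
                         exon.start + PwmSpliceScorer.ACCEPTOR_EXON, "+")
    else:
        donor = fetch(genome, exon.chrom, exon.start - PwmSpliceScorer.DONOR_INTRON,
                      exon.start + PwmSpliceScorer.DONOR_EXON, "-")
        acceptor = fetch(genome, exon.chrom, exon.end - PwmSpliceScorer.ACCEPTOR_EXON,
                         exon.end + PwmSpliceScorer.ACCEPTOR_INTRON, "-")
    return donor, acceptor


def splice_site_strength_compare(
    groups: dict[str, list[GenomicInterval]],
    genome: dict[str, str],
    scorer: PwmSpliceScorer,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of donor/acceptor strength for each
    regulated group vs the neutral group.  Groups smaller than
    ``min_group_size`` are skipped."""
    scores: dict[str, dict[str, list[float]]] = {}
    for name, exons in groups.items():
        scores[name] = {"donor": [], "acceptor": []}
        for exon in exons:
            donor, acceptor = exon_site_windows(exon, genome)
            scores[name]["donor"].append(scorer.donor_score(donor))
            scores[name]["acceptor"].append(scorer.acceptor_score(acceptor))
    rows = []
    for name in groups:
        if name == "neutral":
            continue
        for site in ("donor", "acceptor"):
            a, b = scores[name][site], scores["neutral"][site]
            if len(a) < min_group_size or len(b) < min_group_size:
                rows.append({"group": name, "site": site, "n": len(a),
                             "p_value": float("nan"), "skipped": True})
                continue
            result = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"group": name, "site": site, "n": len(a),
                         "p_value": float(result.pvalue), "skipped": False})
    return pd.DataFrame(rows)


def gc_content_compare(
    groups: dict[str, list[GenomicInterval]],
    genome: dict[str, str],
    flank: int = 100,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """GC fraction of each exon and its flanks, with rank-sum p vs neutral."""
    values: dict[str, dict[str, list[float]]] = {}
    for name, exons in groups.items():
        values[name] = {"exon": [], "upstream": [], "downstream": []}
        for exon in exons:
            body = fetch(genome, exon.chrom, exon.start, exon.end, exon.strand)
            left = fetch(genome, exon.chrom, exon.start - flank, exon.start, exon.strand)
            right = fetch(genome, exon.chrom, exon.end, exon.end + flank, exon.strand)
            upstream, downstream = (left, right) if exon.strand == "+" else (right, left)
            values[name]["exon"].append(gc_content(body))
            values[name]["upstream"].append(gc_content(upstream) if upstream else float("nan"))
            values[name]["downstream"].append(gc_content(downstream) if downstream else float("nan"))
    rows = []
    for name, regions in values.items():
        for region, vals in regions.items():
            clean = [v for v in vals if not math.isnan(v)]
            row = {"group": name, "region": region, "n": len(clean),
                   "mean_gc": float(np.mean(clean)) if clean else float("nan"),
                   "p_value": float("nan")}
            if name != "neutral":
                ref = [v for v in values["neutral"][region] if not math.isnan(v)]
                if len(clean) >= min_group_size and len(ref) >= min_group_size:
                    row["p_value"] = float(
                        stats.mannwhitneyu(clean, ref, alternative="two-sided").pvalue
                    )
            rows.append(row)
    return pd.DataFrame(rows)
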