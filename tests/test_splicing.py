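"""PSI quantification, condition comparison, classification and the
splice-site-strength / GC-content group comparisons."""

import math
from math import comb

import numpy as np
import pytest

import iclipkit as ik
from iclipkit.intervals import GenomicInterval
from iclipkit.splicing import (
    CassetteExonEvent,
    PwmSpliceScorer,
    events_to_frame,
    exon_site_windows,
)


# ---------------------------------------------------------------------------
# PSI


@pytest.mark.parametrize("inc,exc,expected", [(90, 10, 0.90), (0, 50, 0.0), (7, 13, 0.35)])
def test_compute_psi(inc, exc, expected):
    assert ik.compute_psi(inc, exc) == pytest.approx(expected)


def test_compute_psi_unquantifiable_and_invalid():
    assert ik.compute_psi(0, 0) is None
    with pytest.raises(ValueError):
        ik.compute_psi(-1, 5)


# ---------------------------------------------------------------------------
# condition comparison


def test_log2fc_pseudoinclusion_formula_hand_computation():
    # psi_kd 0.5, psi_ctrl 0.25 -> log2(0.51/0.26)
    result = ik.compare_conditions([(25, 75)], [(50, 50)])
    psi_ctrl, psi_kd, delta, log2fc, _ = result
    assert psi_ctrl == 0.25 and psi_kd == 0.5
    assert delta == pytest.approx(0.25)
    assert log2fc == pytest.approx(math.log2(0.51 / 0.26), abs=1e-12)


def test_equal_conditions_have_zero_delta_and_log2fc():
    result = ik.compare_conditions([(40, 60)], [(40, 60)])
    _, _, delta, log2fc, p = result
    assert delta == 0 and log2fc == 0 and p == pytest.approx(1.0)


def test_log2fc_agrees_with_independent_recomputation(rng):
    for _ in range(50):
        ctrl = [(int(rng.integers(0, 100)), int(rng.integers(1, 100))) for _ in range(3)]
        kd = [(int(rng.integers(0, 100)), int(rng.integers(1, 100))) for _ in range(3)]
        psi_ctrl, psi_kd, _, log2fc, _ = ik.compare_conditions(ctrl, kd)
        expected = math.log2((psi_kd + 0.01) / (psi_ctrl + 0.01))
        assert log2fc == pytest.approx(expected, abs=1e-12)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating all 2x2 tables with the same
    margins (hypergeometric tail)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "ctrl,kd",
    [((10, 90), (50, 50)), ((5, 5), (2, 8)), ((0, 10), (3, 7)), ((12, 3), (7, 9))],
)
def test_fisher_p_matches_hypergeometric_enumeration(ctrl, kd):
    *_, p = ik.compare_conditions([ctrl], [kd])
    assert p == pytest.approx(fisher_oracle(ctrl[0], ctrl[1], kd[0], kd[1]), rel=1e-9)


def test_unquantifiable_condition_returns_none():
    assert ik.compare_conditions([(0, 0)], [(10, 10)]) is None


# ---------------------------------------------------------------------------
# classification


def make_event(gene, ctrl, kd, start=1000):
    return CassetteExonEvent(
        gene, GenomicInterval("chr1", start, start + 100, "+"), ctrl, kd
    )


def test_classification_directions_and_neutrality():
    events = [
        # inclusion up on knockdown: the factor was repressing the exon
        make_event("up", [(10, 90)] * 3, [(60, 40)] * 3),
        # inclusion down on knockdown: the factor was activating it
        make_event("down", [(60, 40)] * 3, [(10, 90)] * 3, start=2000),
        # no change
        make_event("flat", [(50, 50)] * 3, [(50, 50)] * 3, start=3000),
    ]
    ik.classify_events(events)
    classes = {e.gene_id: e.regulation_class for e in events}
    assert classes == {"up": "repressed", "down": "activated", "flat": "neutral"}


def test_insignificant_event_is_neutral_regardless_of_delta():
    event = make_event("g", [(3, 2)], [(2, 3)])  # tiny counts: Fisher p large
    ik.classify_events([event])
    assert event.fdr >= 0.1 and event.regulation_class == "neutral"


def test_events_frame_has_all_fields():
    events = ik.classify_events([make_event("g", [(10, 90)], [(60, 40)])])
    frame = events_to_frame(events)
    assert {"gene", "psi_control", "psi_knockdown", "delta_psi", "log2fc",
            "p_value", "fdr", "class"} <= set(frame.columns)


def test_junction_table_round_trip(tmp_path, small_simulation):
    config, _, _, truth = small_simulation
    table = ik.simulate_junction_counts(truth, config)
    path = tmp_path / "junctions.tsv"
    table.to_csv(path, sep="\t", index=False)
    events = ik.read_junction_counts(path)
    assert len(events) == len(truth.cassette_exons)
    for event in events:
        assert len(event.control_counts) == config.n_replicates
        assert len(event.knockdown_counts) == config.n_replicates


# ---------------------------------------------------------------------------
# splice-site strength comparison


class StubScorer:
    """Deterministic scorer mapping each distinct window to a queued value."""

    def __init__(self, values):
        self._values = dict(values)

    def donor_score(self, window):
        return self._values[window]

    acceptor_score = donor_score


def _exon_grid(genome_length=20000):
    """Six disjoint exons on a synthetic chromosome with distinct windows."""
    rng = np.random.default_rng(7)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=genome_length))}
    exons = [GenomicInterval("chr1", 1000 + i * 2000, 1100 + i * 2000, "+")
             for i in range(6)]
    return genome, exons


def test_rank_sum_exact_enumeration_small_groups():
    """Scores {1,2,3} vs {4,5,6}: 2 of the 20 arrangements are as extreme,
    exact two-sided p = 0.1."""
    genome, exons = _exon_grid()
    values = {}
    for exon, score in zip(exons, [1, 2, 3, 4, 5, 6]):
        donor, acceptor = exon_site_windows(exon, genome)
        values[donor] = score
        values[acceptor] = score
    groups = {"repressed": exons[:3], "neutral": exons[3:]}
    table = ik.splice_site_strength_compare(groups, genome, StubScorer(values))
    for _, row in table.iterrows():
        assert row["p_value"] == pytest.approx(0.1)


def test_identical_distributions_give_p_near_one():
    genome, exons = _exon_grid()
    values = {}
    for i, exon in enumerate(exons):
        donor, acceptor = exon_site_windows(exon, genome)
        values[donor] = [1, 2, 3][i % 3]
        values[acceptor] = [1, 2, 3][i % 3]
    groups = {"repressed": exons[:3], "neutral": exons[3:]}
    table = ik.splice_site_strength_compare(groups, genome, StubScorer(values))
    assert (table["p_value"] > 0.9).all()


def test_small_group_is_skipped_with_flag():
    genome, exons = _exon_grid()
    values = {}
    for exon in exons:
        donor, acceptor = exon_site_windows(exon, genome)
        values[donor] = values[acceptor] = 1.0
    groups = {"repressed": exons[:2], "neutral": exons[2:]}
    table = ik.splice_site_strength_compare(groups, genome, StubScorer(values))
    assert table["skipped"].all()


def test_pwm_scorer_prefers_true_donor_sites(small_simulation):
    """The built-in PWM scorer, trained on annotated junctions, scores real
    donor windows above random windows on average."""
    _, genome, annotation, _ = small_simulation
    scorer = PwmSpliceScorer.train(annotation, genome)
    true_scores, random_scores = [], []
    rng = np.random.default_rng(0)
    for gene_id, exon in annotation.exons_with_label("internal"):
        donor, _ = exon_site_windows(exon, genome)
        true_scores.append(scorer.donor_score(donor))
        random_window = "".join(rng.choice(list("ACGT"), size=9))
        random_scores.append(scorer.donor_score(random_window))
    assert np.mean(true_scores) > np.mean(random_scores)


# ---------------------------------------------------------------------------
# GC content


@pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
def test_gc_content_values(seq, expected):
    from iclipkit.seq import gc_content
    assert gc_content(seq) == expected


def test_gc_content_compare_reports_groups_and_pvalues():
    genome, exons = _exon_grid()
    groups = {"repressed": exons[:3], "neutral": exons[3:]}
    table = ik.gc_content_compare(groups, genome, flank=100)
    assert set(table["region"]) == {"exon", "upstream", "downstream"}
    repressed = table[(table["group"] == "repressed")]
    assert repressed["mean_gc"].between(0, 1).all()
    assert repressed["p_value"].notna().all()
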