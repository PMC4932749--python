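"""Uniqueness filtering, PCR-duplicate collapsing, crosslink assignment and
the read-start concordance diagnostic."""

import itertools

import numpy as np
import pytest

import iclipkit as ik
from iclipkit.intervals import GenomicInterval
from iclipkit.tags import AlignedTag, _tag_components


def make_tag(start=100, end=130, strand="+", tag="AACGT", name="r", dels=(),
             multi=False, sample="s1"):
    return AlignedTag(name, GenomicInterval("chr1", start, end, strand), tag,
                      list(dels), multi_mapping=multi, sample_id=sample)


# ---------------------------------------------------------------------------
# uniqueness


def test_filter_unique_drops_only_multi_mappers():
    tags = [make_tag(name=f"r{i}", multi=(i < 3)) for i in range(10)]
    kept = ik.filter_unique(tags)
    assert len(kept) == 7 and not any(t.multi_mapping for t in kept)
    assert ik.filter_unique([make_tag()]) == [make_tag()]
    assert ik.filter_unique([make_tag(multi=True)] * 3) == []


# ---------------------------------------------------------------------------
# PCR-duplicate collapsing


def brute_force_components(tags):
    """Independent oracle: all-pairs Hamming graph + transitive closure."""
    n = len(tags)
    adjacency = [
        [sum(a != b for a, b in zip(tags[i], tags[j])) <= 1 for j in range(n)]
        for i in range(n)
    ]
    # transitive closure by repeated squaring of the boolean relation
    changed = True
    while changed:
        changed = False
        for i, j, k in itertools.product(range(n), repeat=3):
            if adjacency[i][k] and adjacency[k][j] and not adjacency[i][j]:
                adjacency[i][j] = True
                changed = True
    # label each tag by the smallest index reachable from it
    return [min(j for j in range(n) if adjacency[i][j] or i == j) for i in range(n)]


def n_clusters(comp):
    return len(set(comp))


@pytest.mark.parametrize(
    "tags,expected",
    [
        (["AACGT", "AACGA"], 1),  # one mismatch: considered identical
        (["AACGT", "AAGGA"], 2),  # distance 2: distinct molecules
        (["AACGT", "AACGA", "AACCA"], 1),  # distance-1 chain merges transitively
    ],
)
def test_tag_clustering_examples(tags, expected):
    assert n_clusters(_tag_components(tags)) == expected
    assert n_clusters(brute_force_components(tags)) == expected


def test_tag_clustering_matches_brute_force_oracle_exhaustively(rng):
    """Connected components equal all-pairs transitive closure on random
    groups of up to 12 tags."""
    bases = np.array(list("ACGT"))
    for trial in range(300):
        size = int(rng.integers(1, 13))
        # low-cardinality alphabet makes chance distance-1 pairs common
        tags = ["".join(rng.choice(bases[:2] if trial % 2 else bases, size=5))
                for _ in range(size)]
        ours = _tag_components(tags)
        oracle = brute_force_components(tags)
        assert n_clusters(ours) == n_clusters(oracle)
        # same partition, not just the same number of parts
        for i in range(size):
            for j in range(size):
                assert (ours[i] == ours[j]) == (oracle[i] == oracle[j])


def test_greedy_mode_differs_on_chains_only():
    chain = ["AACGT", "AACGA", "AACCA"]
    assert n_clusters(_tag_components(chain, transitive=False)) == 2
    assert n_clusters(_tag_components(chain, transitive=True)) == 1


def test_collapse_keeps_lexicographically_smallest_representative():
    tags = [make_tag(tag="AACGT", name="r1"), make_tag(tag="AACGA", name="r2")]
    kept, report = ik.collapse_pcr_duplicates(tags)
    assert [t.random_tag for t in kept] == ["AACGA"]
    assert report.n_input == 2 and report.n_output == 1


def test_collapse_groups_by_position_strand_and_sample():
    tags = [
        make_tag(start=100, tag="AACGT", name="a"),
        make_tag(start=100, tag="AACGT", name="b", sample="s2"),  # other sample
        make_tag(start=200, end=230, tag="AACGT", name="c"),  # other position
        make_tag(start=100, tag="AACGT", name="d", strand="-", end=130),  # other strand
    ]
    kept, _ = ik.collapse_pcr_duplicates(tags)
    assert len(kept) == 4


def test_collapse_groups_by_5prime_start_despite_variable_3prime_ends():
    # same molecule trimmed to different lengths still collapses
    tags = [make_tag(start=100, end=130, name="a"), make_tag(start=100, end=125, name="b")]
    kept, _ = ik.collapse_pcr_duplicates(tags)
    assert len(kept) == 1


def test_collapse_rejects_wrong_tag_length():
    with pytest.raises(ValueError, match="length"):
        ik.collapse_pcr_duplicates([make_tag(tag="ACGT")])


def test_dedup_without_duplication_merges_only_chance_close_tags(small_simulation):
    """With no PCR duplication, counts shrink only where two true molecules at
    one position drew random tags within Hamming distance 1 of each other."""
    from collections import defaultdict
    from iclipkit.tags import hamming

    config, genome, _, truth = small_simulation
    clean = ik.SimulationConfig(
        **{**vars(config), "pcr_duplication_mean": 0.0, "tag_error_rate": 0.0}
    )
    _, alignments = ik.simulate_iclip_reads(genome, truth, clean)
    kept, report = ik.collapse_pcr_duplicates(alignments)
    assert report.n_output <= report.n_input == len(alignments)

    groups = defaultdict(list)
    for t in alignments:
        groups[(t.interval.chrom, t.interval.strand, t.start_5p, t.sample_id)].append(t)
    for key, members in groups.items():
        tags = [t.random_tag for t in members]
        separated = all(
            hamming(a, b) >= 2
            for i, a in enumerate(tags) for b in tags[:i]
        )
        if separated:
            assert report.clusters_per_position[key] == len(members)
        else:
            assert report.clusters_per_position[key] < len(members)


# ---------------------------------------------------------------------------
# crosslink assignment


@pytest.mark.parametrize(
    "tag,expected",
    [
        (make_tag(100, 130, "+"), ("chr1", 99, "+")),  # base 5' of the read start
        (make_tag(100, 130, "+", dels=[110]), ("chr1", 110, "+")),  # deletion site
        (make_tag(200, 250, "-"), ("chr1", 250, "-")),  # minus-strand convention
        (make_tag(100, 130, "+", dels=[110, 111]), ("chr1", 110, "+")),  # 5'-most
        (make_tag(100, 130, "-", dels=[110, 111]), ("chr1", 111, "-")),  # 5'-most on -
    ],
)
def test_assign_crosslink_rules(tag, expected):
    site = ik.assign_crosslink(tag)
    assert (site.chrom, site.position, site.strand) == expected


def test_assign_crosslink_skips_negative_positions():
    assert ik.assign_crosslink(make_tag(0, 30, "+")) is None
    sites, skipped = ik.assign_crosslinks([make_tag(0, 30, "+"), make_tag(100, 130, "+")])
    assert skipped == 1 and len(sites) == 1


def test_assign_crosslinks_aggregates_molecule_counts():
    tags = [make_tag(100, 130, "+", name=f"r{i}") for i in range(3)]
    sites, _ = ik.assign_crosslinks(tags)
    assert len(sites) == 1 and sites[0].count == 3


def test_minus_strand_convention_matches_simulator_truth(small_simulation):
    """Crosslinks recovered exactly on both strands in the error-free
    truncation-only setting."""
    config, genome, annotation, truth = small_simulation
    clean = ik.SimulationConfig(
        **{**vars(config), "truncation_fraction": 1.0, "tag_error_rate": 0.0,
           "pcr_duplication_mean": 0.0}
    )
    _, alignments = ik.simulate_iclip_reads(genome, truth, clean)
    sites, skipped = ik.assign_crosslinks(alignments)
    true_positions = truth.site_positions()
    assert skipped == 0
    for strand in "+-":
        strand_sites = [s for s in sites if s.strand == strand]
        assert strand_sites, f"no sites on {strand} strand"
        assert all((s.chrom, s.position, s.strand) in true_positions
                   for s in strand_sites)


# ---------------------------------------------------------------------------
# start-profile diagnostic


def fragments_at(starts, length, strand="+", name_prefix="f"):
    return [
        make_tag(s, s + length, strand, name=f"{name_prefix}{i}")
        if strand == "+" else make_tag(s - length, s, strand, name=f"{name_prefix}{i}")
        for i, s in enumerate(starts)
    ]


def test_start_profile_concordant_when_classes_share_starts():
    starts = list(range(1000, 1025))
    tags = fragments_at(starts, 25) + fragments_at(starts, 41, name_prefix="g")
    result = ik.start_profile_diagnostic(tags)
    assert result.verdict == "start-concordant"
    assert result.modal_offset == 0


def test_start_profile_detects_shifted_long_class():
    starts = list(range(1000, 1025))
    tags = fragments_at(starts, 25) + fragments_at(
        [s + 5 for s in starts], 41, name_prefix="g"
    )
    result = ik.start_profile_diagnostic(tags)
    assert result.modal_offset == 5
    assert result.verdict == "start-shifted"


def test_start_profile_requires_minimum_fragments_per_window():
    starts = list(range(1000, 1010))  # 10 short + 9 long = 19 < 20
    tags = fragments_at(starts, 25) + fragments_at(starts[:9], 41, name_prefix="g")
    result = ik.start_profile_diagnostic(tags)
    assert result.verdict == "insufficient data"
    assert result.modal_offset is None
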