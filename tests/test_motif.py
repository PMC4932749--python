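"""k-mer enrichment, frequency/scoring matrices, scanning and variant effects."""

import numpy as np
import pytest

import iclipkit as ik
from iclipkit.motif import (
    MotifHit,
    ScoringMatrix,
    make_background,
    motif_instances,
    top_kmer,
)


def implant_motif_sequences(rng, n=200, length=21, motif="TAGGGA", rate=0.6):
    out = []
    for _ in range(n):
        seq = list(rng.choice(list("ACGT"), size=length))
        if rng.random() < rate:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos:pos + len(motif)] = motif
        out.append("".join(seq))
    return out


# ---------------------------------------------------------------------------
# enrichment


def test_implanted_motif_is_top_enriched_6mer(rng):
    foreground = implant_motif_sequences(rng)
    table = ik.kmer_enrichment(foreground, make_background(foreground, rng), (6,))
    assert top_kmer(table, 6) == "UAGGGA"
    assert table.iloc[0]["fdr"] < 0.1


def test_null_foreground_yields_no_enriched_kmer(rng):
    sequences = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(100)]
    table = ik.kmer_enrichment(sequences, list(sequences), (6,))
    assert (table["fdr"] >= 0.1).all()  # identical fg/bg: fold 1, p 1


def test_kmer_enrichment_rejects_empty_foreground():
    with pytest.raises(ValueError):
        ik.kmer_enrichment([], ["ACGTACGT"], (6,))


def test_fold_uses_pseudocount_for_absent_background_kmer():
    table = ik.kmer_enrichment(["TAGGGATAGGGA"], ["CCCCCCCCCCCC"], (6,))
    row = table[table["kmer"] == "UAGGGA"].iloc[0]
    assert row["bg_count"] == 0 and np.isfinite(row["fold"]) and row["fold"] > 1


# ---------------------------------------------------------------------------
# matrices


def test_frequency_matrix_examples():
    m1 = ik.build_frequency_matrix(["TAGG", "TAGG"])
    assert m1.freq[0, "ACGT".index("T")] == 1.0
    m2 = ik.build_frequency_matrix(["TAGG", "CAGG"])
    assert m2.freq[0, "ACGT".index("T")] == 0.5
    assert m2.freq[0, "ACGT".index("C")] == 0.5
    with pytest.raises(ValueError):
        ik.build_frequency_matrix(["TAGG", "TAG"])
    with pytest.raises(ValueError):
        ik.build_frequency_matrix([])


def test_frequency_matrix_accepts_rna_alphabet():
    assert np.allclose(
        ik.build_frequency_matrix(["UAGG"]).freq,
        ik.build_frequency_matrix(["TAGG"]).freq,
    )


def test_frequency_matrix_columns_sum_to_one(rng):
    instances = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(50)]
    matrix = ik.build_frequency_matrix(instances)
    assert np.allclose(matrix.freq.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("freq,expected", [(0.25, 0.0), (1.0, 2.0), (0.5, 1.0)])
def test_scoring_matrix_log2_identities_at_zero_pseudocount(freq, expected):
    other = (1 - freq) / 3
    fm = ik.build_frequency_matrix  # build via raw array instead
    import iclipkit.motif as motif_mod
    matrix = motif_mod.FrequencyMatrix(np.array([[freq, other, other, other]]))
    scoring = ik.build_scoring_matrix(matrix, background=0.25, pseudocount=0.0)
    assert scoring.score[0, 0] == pytest.approx(expected)


def test_scoring_matrix_is_exact_log2_transform_of_frequencies(rng):
    counts = rng.integers(1, 50, size=(6, 4)).astype(float)
    freq = counts / counts.sum(axis=1, keepdims=True)
    import iclipkit.motif as motif_mod
    scoring = ik.build_scoring_matrix(motif_mod.FrequencyMatrix(freq), 0.25, 0.001)
    independent = np.log2((freq + 0.001) / (0.25 + 0.001))
    assert np.max(np.abs(scoring.score - independent)) < 1e-12


def test_max_per_position_score_bounded_by_two_bits(rng):
    instances = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(20)]
    scoring = ik.build_scoring_matrix(ik.build_frequency_matrix(instances),
                                      pseudocount=0.0)
    assert scoring.score.max() <= 2.0 + 1e-12


# ---------------------------------------------------------------------------
# scanning


def brute_force_scan(seq, matrix, threshold):
    seq = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq) - matrix.width + 1):
        window = seq[i:i + matrix.width]
        if set(window) <= set("ACGT"):
            score = sum(matrix.score[j, "ACGT".index(b)] for j, b in enumerate(window))
            if score >= threshold:
                hits.append((i, score))
    return hits


def test_scan_matches_brute_force_enumeration(rng):
    instances = ["TAGGGA", "TAGGGT", "CAGGGA", "TAAGGA"]
    matrix = ik.build_scoring_matrix(ik.build_frequency_matrix(instances))
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 200))))
        ours = [(h.start, h.score) for h in ik.scan_sequence(seq, matrix, 1.0)]
        oracle = brute_force_scan(seq, matrix, 1.0)
        assert len(ours) == len(oracle)
        for (i, s), (j, t) in zip(ours, oracle):
            assert i == j and s == pytest.approx(t)


def test_scanning_consensus_attains_maximum_score():
    matrix = ik.build_scoring_matrix(ik.build_frequency_matrix(["TAGGGA"] * 5))
    [hit] = ik.scan_sequence("TAGGGA", matrix, 0.0)
    assert hit.score == pytest.approx(matrix.max_score)
    assert ik.scan_sequence("TAGGGA", matrix, matrix.max_score + 1) == []


def test_toy_two_position_matrix_hand_summation():
    import iclipkit.motif as motif_mod
    freq = motif_mod.FrequencyMatrix(
        np.array([[0, 0, 0, 1.0], [1.0, 0, 0, 0]])  # consensus UA
    )
    matrix = ik.build_scoring_matrix(freq, pseudocount=0.0)
    hits = ik.scan_sequence("UAUA", matrix, 3.9)
    assert [(h.start, h.score) for h in hits] == [(0, pytest.approx(4.0)),
                                                  (2, pytest.approx(4.0))]


def test_sense_strand_only_no_reverse_complement_hits(rng):
    matrix = ik.build_scoring_matrix(ik.build_frequency_matrix(["TAGGGA"] * 5))
    seq = "CCCTAGGGACCC"
    rc = "GGGTCCCTAGGG"[::-1]  # reverse complement of seq
    assert len(ik.scan_sequence(seq, matrix, matrix.max_score - 0.01)) == 1
    from iclipkit.seq import reverse_complement
    assert ik.scan_sequence(reverse_complement(seq), matrix, matrix.max_score - 0.01) == []


# ---------------------------------------------------------------------------
# variant effects


@pytest.fixture(scope="module")
def uag_matrix():
    # consensus UAGGGA with modest degeneracy, as discovered from peaks
    instances = ["TAGGGA"] * 12 + ["TAGGGT", "CAGGGA", "TAGAGA", "TAGGAA"]
    return ik.build_scoring_matrix(ik.build_frequency_matrix(instances))


def test_uag_to_ucg_mutation_predicts_disruption(uag_matrix):
    # the 2A>C mutation of the UAG core weakens predicted binding
    delta = ik.variant_effect("GGUAGGGAGG", (3, "A", "C"), uag_matrix)
    assert delta < 0


def test_multi_base_gain_of_motif_predicts_increase(uag_matrix):
    """Mutating UUAGAUUU to UUAGGGAU (successive substitutions) creates a
    strong UAGGGA site and raises the predicted binding score."""
    seq = "CCUUAGAUUUCC"
    current = seq
    deltas = []
    for pos, ref, alt in [(6, "A", "G"), (7, "U", "G"), (8, "U", "A")]:
        deltas.append(ik.variant_effect(current, (pos, ref, alt), uag_matrix))
        current = current[:pos] + alt + current[pos + 1:]
    assert "UAGGGA" in current
    assert sum(deltas) > 0
    best = lambda s: max(h.score for h in ik.scan_sequence(s, uag_matrix, -100))
    assert best(current) > best(seq)


def test_identity_variant_has_zero_delta(uag_matrix):
    assert ik.variant_effect("GGUAGGGAGG", (3, "A", "A"), uag_matrix) == 0


def test_variant_with_wrong_reference_base_errors(uag_matrix):
    with pytest.raises(ValueError, match="position 3"):
        ik.variant_effect("GGUAGGGAGG", (3, "G", "C"), uag_matrix)


# ---------------------------------------------------------------------------
# end-to-end discovery


def test_discover_motif_recovers_implant_and_consensus(rng):
    foreground = implant_motif_sequences(rng, n=200, rate=0.6)
    table, freq, scoring = ik.discover_motif(foreground, rng, (6,), pick_k=6)
    assert top_kmer(table, 6) == "UAGGGA"
    assert scoring.consensus == "UAGGGA"
    # consensus score equals the independent elementwise recomputation
    independent = np.log2((freq.freq + 0.001) / 0.251).max(axis=1).sum()
    assert scoring.max_score == pytest.approx(independent, abs=1e-12)
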