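"""Alignment identity, probe-window search, variants, polyA and termini."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitrace import (
    ParameterError,
    cluster_3prime_termini,
    find_discriminating_variants,
    find_pan_probe_region,
    find_polya_signals,
    find_specific_probe_region,
    global_percent_identity,
)
from splitrace.probe_design import best_ungapped_identity, make_aligner

BASES = np.array(list("ACGT"))


def _random_seq(rng, n):
    return "".join(rng.choice(BASES, n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def gotoh_overlap_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-2.0, extend=-0.5):
    """Independent affine-gap overlap-alignment DP (Gotoh): end gaps are
    free, internal gaps pay open/extend.  Leading (trailing) free gaps can
    only precede (follow) one sequence's residues, matching a global
    alignment whose end-gap scores are zero."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = np.full((n + 1, m + 1), neg)  # ends in a match/mismatch column
    E = np.full((n + 1, m + 1), neg)  # ends in a paid gap in b (consumes a)
    F = np.full((n + 1, m + 1), neg)  # ends in a paid gap in a (consumes b)
    lead = np.full((n + 1, m + 1), neg)  # free leading gaps only
    for i in range(n + 1):
        lead[i][0] = 0.0
    for j in range(m + 1):
        lead[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = s + max(
                H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1], lead[i - 1][j - 1]
            )
            E[i][j] = max(H[i - 1][j] + open_, E[i - 1][j] + extend, F[i - 1][j] + open_)
            F[i][j] = max(H[i][j - 1] + open_, F[i][j - 1] + extend, E[i][j - 1] + open_)
    stacked = np.maximum(np.maximum(H, E), F)
    best = max(float(stacked[:, m].max()), float(stacked[n, :].max()))
    return max(best, 0.0)


class TestGlobalPercentIdentity:
    def test_identical_sequences_are_100(self):
        assert global_percent_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_single_substitution_is_seven_of_eight(self):
        assert global_percent_identity("ACGTACGT", "ACGAACGT") == pytest.approx(87.5)

    def test_probe_inside_longer_gene_scores_over_aligned_span(self):
        # terminal gaps excluded: a perfect sub-sequence scores 100
        assert global_percent_identity("ACGTAC", "TTTTACGTACTTTT") == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = _random_seq(rng, 80)
            b = _mutate(rng, a, 0.1)
            assert global_percent_identity(a, b) == pytest.approx(
                global_percent_identity(b, a)
            )

    def test_substitution_only_identity_matches_construction(self):
        # with substitutions only, the optimal alignment is gap-free and the
        # identity is exactly the fraction of unchanged positions
        rng = np.random.default_rng(9)
        a = _random_seq(rng, 200)
        positions = rng.choice(200, size=12, replace=False)
        b = list(a)
        for p in positions:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        assert global_percent_identity(a, "".join(b)) == pytest.approx(
            100 * (200 - 12) / 200
        )

    def test_alignment_score_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(13)
        aligner = make_aligner()
        for _ in range(8):
            a = _random_seq(rng, 50)
            # share a mutated copy with an indel so the optimum is positive
            b = _mutate(rng, a[:20], 0.1) + _random_seq(rng, 5) + _mutate(rng, a[26:], 0.1)
            assert aligner.score(a, b) == pytest.approx(gotoh_overlap_score(a, b))

    def test_invalid_input_rejected(self):
        with pytest.raises(ParameterError):
            global_percent_identity("", "ACGT")
        with pytest.raises(ParameterError):
            global_percent_identity("ACGT", "ACXT")


class TestProbeWindows:
    def test_identical_family_qualifies_everywhere(self):
        seq = "ACGTACGTACGTACGTACGT"
        family = {"s1": seq, "s2": seq, "s3": seq}
        hits = find_pan_probe_region(family, 8, 100.0)
        assert len(hits) == len(seq) - 8 + 1
        assert all(h.min_identity_within_family == 100.0 for h in hits)

    def test_planted_conserved_block_is_the_only_pan_region(self):
        rng = np.random.default_rng(0)
        block = _random_seq(rng, 30)
        family = {f"s{i}": _random_seq(rng, 40) + block + _random_seq(rng, 40) for i in range(4)}
        hits = find_pan_probe_region(family, 30, 90.0)
        assert hits, "the planted block must be found"
        # every qualifying window overlaps the planted block (positions 41-70)
        for h in hits:
            assert h.start <= 70 and h.end >= 41
        assert hits[0].min_identity_within_family == 100.0

    def test_specific_search_needs_offtargets(self):
        with pytest.raises(ParameterError):
            find_specific_probe_region(("t", "ACGTACGT"), {}, 4, 65.0)

    def test_target_equal_to_offtarget_has_no_specific_window(self):
        seq = "ACGTACGTACGTACGT"
        assert find_specific_probe_region(("t", seq), {"o": seq}, 8, 65.0) == []

    def test_planted_divergent_block_is_the_only_specific_region(self):
        rng = np.random.default_rng(1)
        backbone = _random_seq(rng, 120)
        divergent = _random_seq(rng, 30)
        target = ("t", backbone[:40] + divergent + backbone[70:])
        offtargets = {f"o{i}": backbone for i in range(3)}
        hits = find_specific_probe_region(target, offtargets, 30, 65.0)
        assert hits
        for h in hits:
            assert h.start <= 70 and h.end >= 41  # overlaps the divergent block

    def test_pan_and_specific_windows_are_disjoint(self):
        # a window cannot be >=84% conserved and <=65% divergent against the
        # same comparison set (min identity <= max identity)
        rng = np.random.default_rng(2)
        conserved = _random_seq(rng, 60)
        ref = conserved + _random_seq(rng, 60)
        others = {
            f"s{i}": _mutate(rng, conserved, 0.03) + _random_seq(rng, 60)
            for i in range(1, 4)
        }
        family = {"ref": ref, **others}
        pan = find_pan_probe_region(family, 30, 84.0, reference="ref")
        specific = find_specific_probe_region(("ref", ref), others, 30, 65.0)
        pan_starts = {h.start for h in pan}
        specific_starts = {h.start for h in specific}
        assert pan_starts
        assert specific_starts
        assert pan_starts.isdisjoint(specific_starts)


class TestDiscriminatingVariants:
    def test_identical_sequences_have_no_variants(self):
        assert find_discriminating_variants("ACGTACGT", "ACGTACGT") == []

    def test_single_engineered_substitution(self):
        rng = np.random.default_rng(3)
        a = _random_seq(rng, 60)
        b = a[:30] + ("C" if a[30] != "C" else "G") + a[31:]
        variants = find_discriminating_variants(a, b)
        assert len(variants) == 1
        v = variants[0]
        assert (v.position, v.kind) == (31, "substitution")
        assert v.bases_a == a[30]

    def test_indel_plus_substitutions_are_flagged_by_type(self):
        rng = np.random.default_rng(4)
        a = _random_seq(rng, 80)
        b = list(a)
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for p in (10, 30, 50):
            b[p] = swap[b[p]]
        # 2-nt deletion relative to strain A at positions 65-66
        b = "".join(b[:64] + b[66:])
        variants = find_discriminating_variants(a, b)
        assert len(variants) == 4
        kinds = {(v.position, v.kind) for v in variants}
        assert (11, "substitution") in kinds
        assert (31, "substitution") in kinds
        assert (51, "substitution") in kinds
        (indel,) = [v for v in variants if v.kind == "insertion"]
        assert indel.bases_a == a[64:66]
        assert indel.bases_b == "-"

    def test_region_offsets_reported_coordinates(self):
        a = "AAAA" + "ACGTACGTAC" + "AAAA"
        b = "ACGTACTTAC"  # substitution at region position 7
        variants = find_discriminating_variants(a, b, region=(5, 14))
        subs = [v for v in variants if v.kind == "substitution"]
        assert any(v.position == 11 for v in subs)  # 1-based on full strain A


class TestPolyASignals:
    def test_planted_hexamer_upstream(self):
        seq = "T" * 50 + "AATAAA" + "T" * 14 + "CA"
        hits = find_polya_signals(seq, 72)
        assert len(hits) == 1
        assert hits[0].hexamer == "AATAAA"
        assert hits[0].start == 51
        assert hits[0].distance == 21

    def test_no_hexamer_in_window_is_empty(self):
        assert find_polya_signals("T" * 100, 80) == []

    def test_two_hexamers_ordered_by_distance(self):
        seq = "G" * 30 + "AATAAA" + "G" * 6 + "ATTAAA" + "G" * 10 + "CC"
        cleavage = 54
        hits = find_polya_signals(seq, cleavage)
        assert [h.hexamer for h in hits] == ["ATTAAA", "AATAAA"]
        assert hits[0].distance < hits[1].distance

    def test_cleavage_outside_sequence_rejected(self):
        with pytest.raises(ParameterError):
            find_polya_signals("ACGT", 10)


class TestCleavageClustering:
    def test_single_position_is_one_terminus(self):
        clusters = cluster_3prime_termini([2301], 0)
        assert len(clusters) == 1
        assert clusters[0].representative == 2301

    def test_adjacent_nucleotide_heterogeneity(self):
        # same signal, cleavage one base apart: distinct at tolerance 0,
        # merged at tolerance 1
        assert len(cluster_3prime_termini([2301, 2302, 2450], 0)) == 3
        clusters = cluster_3prime_termini([2301, 2302, 2450], 1)
        assert len(clusters) == 2
        assert clusters[0].members == (2301, 2302)

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=30),
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
    )
    @settings(deadline=None, max_examples=60)
    def test_cluster_count_non_increasing_in_tolerance(self, positions, t1, t2):
        lo, hi = sorted((t1, t2))
        assert len(cluster_3prime_termini(positions, hi)) <= len(
            cluster_3prime_termini(positions, lo)
        )

    def test_clusters_are_disjoint_and_cover_all_positions(self):
        positions = [5, 6, 7, 30, 31, 90]
        clusters = cluster_3prime_termini(positions, 2)
        members = [p for c in clusters for p in c.members]
        assert sorted(members) == sorted(positions)

    def test_simulated_polya_sites_are_recovered(self, beta_variants):
        # deep sampling of a gene with 3 polyA sites recovers 3 termini
        from splitrace import SimParams, simulate_cell_truth
        from splitrace.cluster import PolyASite, StrainVariantMap, VariantSite
        from splitrace.synthetic_data import _add_molecules

        variants = StrainVariantMap(
            {"g": (VariantSite(1, "A", "G"),)},
            {
                "g": (
                    PolyASite(2300, 0.5),
                    PolyASite(2400, 0.3),
                    PolyASite(2500, 0.2),
                )
            },
            ("B6", "JF1"),
        )
        from splitrace import CellTruth

        truth = CellTruth(cell_id="c", alleles=("B6", "JF1"))
        rng = np.random.default_rng(8)
        _add_molecules(truth, "B6", "g", 200, variants, rng)
        observed = [
            pos
            for pos, count in truth.polya_counts[("B6", "g")].items()
            for _ in range(count)
        ]
        clusters = cluster_3prime_termini(observed, 5)
        assert len(clusters) == 3
        assert {c.representative for c in clusters} == {2300, 2400, 2500}
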