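"""Motif parsing, correlation, alignment and merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motiflogit import (
    MotifParseError,
    PositionProbabilityMatrix,
    align_ppms,
    cluster_and_merge,
    generate_library,
    merge_report,
    merged_library,
    parse_motif_file,
    ppm_correlation,
    write_motif_file,
)
from motiflogit.simulate import SyntheticSpec

from conftest import random_ppm


def _write(tmp_path, text, name="motifs.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParsing:
    @pytest.mark.parametrize(
        "rows, pseudocount, expected",
        [
            # pure counts normalize to a 0/1 matrix
            ("A [ 4 0 ]\nC [ 0 4 ]\nG [ 0 0 ]\nT [ 0 0 ]", 0.0,
             [[1, 0, 0, 0], [0, 1, 0, 0]]),
            ("A [ 3 1 ]\nC [ 1 3 ]\nG [ 0 0 ]\nT [ 0 0 ]", 0.0,
             [[0.75, 0.25, 0, 0], [0.25, 0.75, 0, 0]]),
            # pseudocount 1: (c + 1) / (sum + 4)
            ("A [ 3 1 ]\nC [ 1 3 ]\nG [ 0 0 ]\nT [ 0 0 ]", 1.0,
             [[0.5, 0.25, 0.125, 0.125], [0.25, 0.5, 0.125, 0.125]]),
        ],
    )
    def test_counts_to_probabilities(self, tmp_path, rows, pseudocount, expected):
        path = _write(tmp_path, f">m1\n{rows}\n")
        ppms = parse_motif_file(path, pseudocount=pseudocount)
        assert len(ppms) == 1
        np.testing.assert_allclose(ppms[0].probs, expected, atol=1e-12)

    def test_multi_motif_file(self, tmp_path):
        text = ">first\nA [ 1 0 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 0 0 ]\n" \
               ">second\nA [ 0 1 ]\nC [ 1 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        ppms = parse_motif_file(_write(tmp_path, text), pseudocount=0.0)
        assert [p.name for p in ppms] == ["first", "second"]

    def test_negative_entry_names_motif(self, tmp_path):
        text = ">bad_motif\nA [ 1 -2 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        with pytest.raises(MotifParseError, match="bad_motif"):
            parse_motif_file(_write(tmp_path, text))

    def test_unequal_rows_rejected(self, tmp_path):
        text = ">ragged\nA [ 1 0 1 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        with pytest.raises(MotifParseError, match="ragged"):
            parse_motif_file(_write(tmp_path, text))

    def test_round_trip(self, tmp_path, small_library):
        path = tmp_path / "lib.jaspar"
        write_motif_file(small_library, path)
        back = parse_motif_file(path, pseudocount=0.0)
        assert [p.name for p in back] == [p.name for p in small_library]
        for a, b in zip(small_library, back):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)


class TestPpmInvariants:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PositionProbabilityMatrix("bad", [[0.5, 0.1, 0.1, 0.1]])

    def test_reverse_complement_is_involution(self, sharp_ppm):
        rc2 = sharp_ppm.reverse_complement().reverse_complement()
        np.testing.assert_allclose(rc2.probs, sharp_ppm.probs)


class TestCorrelation:
    def test_self_correlation_is_one(self, sharp_ppm):
        assert ppm_correlation(sharp_ppm, sharp_ppm) == pytest.approx(1.0, abs=1e-12)

    def test_single_position_cross(self):
        # [1,0,0,0] vs [0,1,0,0], centered on the 0.25 row mean -> -1/3
        a = PositionProbabilityMatrix("a", [[1, 0, 0, 0]])
        b = PositionProbabilityMatrix("b", [[0, 1, 0, 0]])
        assert ppm_correlation(a, b) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_two_position_hand_computed(self):
        a = PositionProbabilityMatrix("a", [[1, 0, 0, 0], [0, 0, 1, 0]])
        b = PositionProbabilityMatrix("b", [[1, 0, 0, 0], [0, 1, 0, 0]])
        # direct evaluation of the centered cross-product formula
        ca = a.probs - 0.25
        cb = b.probs - 0.25
        expected = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        assert ppm_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_uniform_matrix_is_undefined(self, sharp_ppm):
        uniform = PositionProbabilityMatrix("u", np.full((1, 4), 0.25))
        one_pos = PositionProbabilityMatrix("p", [[1, 0, 0, 0]])
        assert np.isnan(ppm_correlation(uniform, one_pos))

    def test_shape_mismatch_rejected(self, sharp_ppm):
        b = PositionProbabilityMatrix("b", [[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            ppm_correlation(sharp_ppm, b)


def _brute_force_best(a, b, both_orientations=True):
    """Independent enumeration oracle over every offset and orientation."""
    def padded_corr(pa, pb, offset):
        lo = min(0, offset)
        hi = max(pa.shape[0], offset + pb.shape[0])
        span = hi - lo
        a_pad = np.tile([0.25, 0.25, 0.25, 0.25], (span, 1))
        b_pad = a_pad.copy()
        a_pad[-lo:-lo + pa.shape[0]] = pa
        b_pad[offset - lo:offset - lo + pb.shape[0]] = pb
        ca, cb = a_pad - a_pad.mean(1, keepdims=True), b_pad - b_pad.mean(1, keepdims=True)
        den = np.sqrt((ca * ca).sum() * (cb * cb).sum())
        return (ca * cb).sum() / den if den else 0.0

    best = -np.inf
    variants = [b.probs] + ([b.probs[::-1, ::-1]] if both_orientations else [])
    for pb in variants:
        for off in range(-(pb.shape[0] - 1), a.probs.shape[0]):
            best = max(best, padded_corr(a.probs, pb, off))
    return best


class TestAlignment:
    def test_self_alignment(self, sharp_ppm):
        aln = align_ppms(sharp_ppm, sharp_ppm)
        assert aln.offset == 0
        assert aln.orientation == "forward"
        assert aln.correlation == pytest.approx(1.0, abs=1e-12)

    def test_recovers_embedded_offset(self, sharp_ppm):
        sub = PositionProbabilityMatrix("sub", sharp_ppm.probs[2:6])
        aln = align_ppms(sharp_ppm, sub)
        assert aln.offset == 2
        assert aln.correlation == pytest.approx(
            _brute_force_best(sharp_ppm, sub), abs=1e-12
        )

    def test_reverse_complement_detected(self, sharp_ppm):
        aln = align_ppms(sharp_ppm, sharp_ppm.reverse_complement())
        assert aln.orientation == "reverse"
        assert aln.correlation == pytest.approx(1.0, abs=1e-12)

    def test_forward_only_flag(self, sharp_ppm):
        aln = align_ppms(sharp_ppm, sharp_ppm.reverse_complement(),
                         both_orientations=False)
        assert aln.orientation == "forward"
        assert aln.correlation < 1.0 - 1e-6

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), la=st.integers(2, 9), lb=st.integers(2, 9))
    def test_symmetry_and_matches_brute_force(self, seed, la, lb):
        rng = np.random.default_rng(seed)
        a, b = random_ppm(rng, la), random_ppm(rng, lb)
        ab = align_ppms(a, b)
        ba = align_ppms(b, a)
        oracle = _brute_force_best(a, b)
        assert ab.correlation == pytest.approx(oracle, abs=1e-10)
        assert ab.correlation == pytest.approx(ba.correlation, abs=1e-10)


class TestClusterAndMerge:
    def test_identical_pair_merges_to_input(self, sharp_ppm):
        twin = PositionProbabilityMatrix("twin", sharp_ppm.probs)
        clusters = cluster_and_merge([sharp_ppm, twin], threshold=0.9)
        assert len(clusters) == 1
        np.testing.assert_allclose(clusters[0].merged.probs, sharp_ppm.probs, atol=1e-12)
        assert set(clusters[0].member_names) == {"sharp8", "twin"}

    def test_dissimilar_pair_stays_separate(self, rng):
        a, b = random_ppm(rng, 8), random_ppm(rng, 8)
        corr = align_ppms(a, b).correlation
        assert corr < 0.9  # sanity on the fixture draw
        clusters = cluster_and_merge([a, b], threshold=0.9)
        assert len(clusters) == 2

    def test_chain_forms_single_component(self, sharp_ppm, rng):
        # b bridges a and c: correlations a-b and b-c exceed a-c
        other = random_ppm(rng, 8)
        bridge_probs = 0.5 * sharp_ppm.probs + 0.5 * other.probs
        bridge = PositionProbabilityMatrix("bridge", bridge_probs)
        c_ab = align_ppms(sharp_ppm, bridge).correlation
        c_bc = align_ppms(bridge, other).correlation
        c_ac = align_ppms(sharp_ppm, other).correlation
        threshold = min(c_ab, c_bc) - 1e-9
        assert c_ac < threshold  # the chain premise
        clusters = cluster_and_merge([sharp_ppm, bridge, other], threshold=threshold)
        assert len(clusters) == 1
        assert len(clusters[0].member_names) == 3

    def test_recovers_planted_duplicate_groups(self):
        spec = SyntheticSpec(n_motifs=5, seed=11, n_duplicate_groups=2,
                             duplicates_per_group=2)
        library = generate_library(spec)
        clusters = cluster_and_merge(library, threshold=0.9)
        groups = {frozenset(c.member_names) for c in clusters}
        expected = {
            frozenset({"M000", "M000_dup0", "M000_dup1"}),
            frozenset({"M001", "M001_dup0", "M001_dup1"}),
            frozenset({"M002"}),
            frozenset({"M003"}),
            frozenset({"M004"}),
        }
        assert groups == expected

    def test_merging_is_idempotent(self):
        spec = SyntheticSpec(n_motifs=5, seed=11, n_duplicate_groups=2,
                             duplicates_per_group=2)
        clusters = cluster_and_merge(generate_library(spec), threshold=0.9)
        again = cluster_and_merge(merged_library(clusters), threshold=0.9)
        assert all(len(c.member_names) == 1 for c in again)

    def test_merged_rows_are_stochastic(self, small_library):
        spec = SyntheticSpec(n_motifs=6, seed=3, n_duplicate_groups=3,
                             duplicates_per_group=2)
        clusters = cluster_and_merge(generate_library(spec), threshold=0.9)
        for cluster in clusters:
            sums = cluster.merged.probs.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_lower_threshold_means_fewer_clusters(self, small_library):
        spec = SyntheticSpec(n_motifs=8, seed=5, n_duplicate_groups=2,
                             duplicates_per_group=1)
        library = generate_library(spec)
        counts = [
            len(cluster_and_merge(library, threshold=t))
            for t in (0.95, 0.8, 0.6, 0.4, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_uniform_motif_never_merges(self, sharp_ppm):
        uniform = PositionProbabilityMatrix("uniform", np.full((8, 4), 0.25))
        clusters = cluster_and_merge([sharp_ppm, uniform], threshold=0.1)
        names = {frozenset(c.member_names) for c in clusters}
        assert frozenset({"uniform"}) in names

    def test_average_linkage_option(self):
        spec = SyntheticSpec(n_motifs=5, seed=11, n_duplicate_groups=2,
                             duplicates_per_group=2)
        library = generate_library(spec)
        clusters = cluster_and_merge(library, threshold=0.9, linkage="average")
        assert sum(len(c.member_names) for c in clusters) == len(library)

    def test_merge_report_rows(self):
        spec = SyntheticSpec(n_motifs=4, n_causal=2, true_weights=(1.0, -1.0),
                             seed=2, n_duplicate_groups=1, duplicates_per_group=1)
        library = generate_library(spec)
        clusters = cluster_and_merge(library, threshold=0.9)
        report = merge_report(clusters, library)
        assert report.n_members.sum() == len(library)
        merged_row = report[report.n_members > 1].iloc[0]
        assert merged_row.min_pairwise_correlation >= 0.9
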