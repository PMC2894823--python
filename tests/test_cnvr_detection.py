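"""Sweep-line detector, merging, state assignment and their invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cnvgwas import (
    CnvCall,
    DetectionConfig,
    SubCnvr,
    assign_states,
    build_state_matrix,
    coverage_profile,
    detect_sub_cnvrs,
    filter_min_snps,
    merge_sub_cnvrs,
)
from cnvgwas.errors import ConfigError, ContractError, ResolutionError
from cnvgwas.io_formats import SnpMarker

from conftest import brute_force_sub_cnvrs, random_instance


class TestFilterMinSnps:
    def test_strict_less_than_discarded(self):
        calls = [CnvCall("A", "1", 1, 10, -1, n) for n in (1, 3, 5)]
        assert [c.n_snps for c in filter_min_snps(calls, 3)] == [3, 5]

    def test_threshold_one_is_identity(self):
        calls = [CnvCall("A", "1", 1, 10, -1, 1)]
        assert filter_min_snps(calls, 1) == calls
        assert filter_min_snps([], 3) == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigError):
            filter_min_snps([], 0)


class TestDetectSubCnvrs:
    def test_no_calls_gives_empty_list(self):
        assert detect_sub_cnvrs([], 5, DetectionConfig(freq_threshold=0.1)) == []

    def test_single_interval_identity(self):
        calls = [CnvCall("A", "1", 100, 500, +1, 4)]
        (r,) = detect_sub_cnvrs(calls, 1, DetectionConfig(freq_threshold=0.5))
        assert (r.start_pos, r.end_pos, r.frequency) == (100, 500, 1.0)
        assert r.carrier_ids == {"A"}

    def test_three_subject_overlap_core_only(self, three_subject_calls):
        regions = detect_sub_cnvrs(three_subject_calls, 4, DetectionConfig(freq_threshold=0.5))
        assert [(r.start_pos, r.end_pos) for r in regions] == [(200, 300)]
        assert regions[0].frequency == 0.75
        assert regions[0].carrier_ids == {"A", "B", "C"}

    def test_threshold_boundary_is_strict(self, three_subject_calls):
        assert detect_sub_cnvrs(
            three_subject_calls, 4, DetectionConfig(freq_threshold=0.75)
        ) == []

    def test_duplicate_calls_of_one_subject_counted_once(self):
        # the same subject reported twice must not inflate the carrier count,
        # but its call borders stay segment boundaries
        calls = [
            CnvCall("A", "1", 100, 300, -1),
            CnvCall("A", "1", 150, 350, -2),
            CnvCall("B", "1", 100, 300, -1),
        ]
        regions = detect_sub_cnvrs(calls, 4, DetectionConfig(freq_threshold=0.4))
        assert all(r.n_carriers == 2 for r in regions)
        assert [(r.start_pos, r.end_pos) for r in regions] == [(100, 150), (150, 300)]

    def test_chromosomes_never_combined(self):
        calls = [CnvCall("A", "1", 100, 200, -1), CnvCall("B", "2", 100, 200, -1)]
        regions = detect_sub_cnvrs(calls, 2, DetectionConfig(freq_threshold=0.3))
        assert [(r.chromosome, r.start_pos) for r in regions] == [("1", 100), ("2", 100)]

    def test_unmapped_chromosome_raises_with_snp_map(self):
        snp_map = [SnpMarker("m1", "1", 100)]
        calls = [CnvCall("A", "7", 100, 200, -1)]
        with pytest.raises(ResolutionError, match="'7'"):
            detect_sub_cnvrs(calls, 2, DetectionConfig(freq_threshold=0.3), snp_map=snp_map)

    def test_zero_subjects_rejected(self):
        with pytest.raises(ConfigError):
            detect_sub_cnvrs([], 0, DetectionConfig(freq_threshold=0.3))

    def test_bracketing_markers_attached(self):
        snp_map = [SnpMarker("m1", "1", 100), SnpMarker("m2", "1", 500)]
        calls = [CnvCall("A", "1", 100, 500, -1)]
        (r,) = detect_sub_cnvrs(calls, 1, DetectionConfig(freq_threshold=0.5), snp_map=snp_map)
        assert (r.start_marker, r.end_marker) == ("m1", "m2")

    def test_unpooled_detection_separates_gains_and_losses(self):
        calls = [
            CnvCall("A", "1", 100, 300, -1),
            CnvCall("B", "1", 100, 300, +1),
        ]
        pooled = detect_sub_cnvrs(calls, 4, DetectionConfig(freq_threshold=0.3))
        assert [(r.n_carriers, r.sign) for r in pooled] == [(2, None)]
        split = detect_sub_cnvrs(
            calls, 4, DetectionConfig(freq_threshold=0.2, pool_states=False)
        )
        assert sorted((r.sign, r.n_carriers) for r in split) == [("gain", 1), ("loss", 1)]

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls, n_subjects = random_instance(rng)
        threshold = float(rng.choice([0.05, 0.1, 0.2, 0.3, 0.5]))
        got = detect_sub_cnvrs(calls, n_subjects, DetectionConfig(freq_threshold=threshold))
        expected = brute_force_sub_cnvrs(calls, n_subjects, threshold)
        assert [
            (r.chromosome, r.start_pos, r.end_pos, r.carrier_ids) for r in got
        ] == expected

    @given(st.integers(0, 10_000))
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        calls, n_subjects = random_instance(rng)
        cfg = DetectionConfig(freq_threshold=0.2)
        base = detect_sub_cnvrs(calls, n_subjects, cfg)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert detect_sub_cnvrs(shuffled, n_subjects, cfg) == base

    @given(st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        calls, n_subjects = random_instance(rng)
        counts, lengths = [], []
        for thr in (0.05, 0.10, 0.15, 0.20, 0.25):
            regions = detect_sub_cnvrs(calls, n_subjects, DetectionConfig(freq_threshold=thr))
            counts.append(len(regions))
            lengths.append(sum(r.end_pos - r.start_pos for r in regions))
        assert counts == sorted(counts, reverse=True)
        assert lengths == sorted(lengths, reverse=True)

    @given(st.integers(0, 10_000))
    def test_frequency_is_exact_rational(self, seed):
        rng = np.random.default_rng(seed)
        calls, n_subjects = random_instance(rng)
        for r in detect_sub_cnvrs(calls, n_subjects, DetectionConfig(freq_threshold=0.1)):
            assert r.frequency == len(r.carrier_ids) / n_subjects
            assert r.frequency > 0.1


class TestCoverageProfile:
    def test_empty_and_single_call(self):
        assert coverage_profile([], "1") == []
        calls = [CnvCall("A", "1", 100, 500, -1)]
        assert coverage_profile(calls, "1") == [(100, 500, 1)]

    def test_three_subject_profile(self, three_subject_calls):
        assert coverage_profile(three_subject_calls, "1") == [
            (100, 200, 1),
            (200, 300, 3),
            (300, 400, 1),
        ]

    @given(st.integers(0, 10_000))
    def test_total_area_equals_deduplicated_covered_length(self, seed):
        rng = np.random.default_rng(seed)
        calls, _ = random_instance(rng)
        for chrom in {c.chromosome for c in calls}:
            on = [c for c in calls if c.chromosome == chrom]
            area = sum(n * (e - s) for s, e, n in coverage_profile(on, chrom))
            # independent accounting: union length per subject, summed
            expected = 0
            for subject in {c.subject_id for c in on}:
                covered = set()
                for c in on:
                    if c.subject_id == subject:
                        covered.update(range(c.start_pos, c.end_pos))
                expected += len(covered)
            assert area == expected


class TestMergeSubCnvrs:
    def _sub(self, chrom, start, end, carriers=("A",), n=4):
        return SubCnvr(chromosome=chrom, start_pos=start, end_pos=end,
                       n_subjects=n, carrier_ids=frozenset(carriers))

    def test_single_region_identity(self):
        (m,) = merge_sub_cnvrs([self._sub("1", 200, 300)])
        assert (m.start_pos, m.end_pos, len(m.members)) == (200, 300, 1)

    def test_shared_boundary_merges(self):
        (m,) = merge_sub_cnvrs([self._sub("1", 200, 300, "AB"), self._sub("1", 300, 450, "BC")])
        assert (m.start_pos, m.end_pos, len(m.members)) == (200, 450, 2)
        assert m.carrier_ids == frozenset("ABC")  # recomputed over the merged span

    def test_chromosome_separation(self):
        merged = merge_sub_cnvrs([self._sub("1", 200, 300), self._sub("2", 200, 300)])
        assert len(merged) == 2

    def test_gap_prevents_merge(self):
        merged = merge_sub_cnvrs([self._sub("1", 200, 300), self._sub("1", 350, 450)])
        assert len(merged) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ContractError, match="sorted"):
            merge_sub_cnvrs([self._sub("1", 300, 450), self._sub("1", 200, 300)])

    @given(st.integers(0, 10_000))
    def test_merge_monotone_and_split_recovers_input(self, seed):
        rng = np.random.default_rng(seed)
        calls, n_subjects = random_instance(rng)
        subs = detect_sub_cnvrs(calls, n_subjects, DetectionConfig(freq_threshold=0.1))
        merged = merge_sub_cnvrs(subs)
        assert len(merged) <= len(subs)
        assert [m for region in merged for m in region.members] == subs
        for region in merged:
            assert region.start_pos == region.members[0].start_pos
            assert region.end_pos == region.members[-1].end_pos


class TestAssignStates:
    cfg = DetectionConfig(freq_threshold=0.1, state_len_threshold=0.5)

    def _region(self, start=200, end=400):
        return SubCnvr(chromosome="1", start_pos=start, end_pos=end,
                       n_subjects=4, carrier_ids=frozenset("A"))

    def test_majority_overlap_sets_signed_state(self):
        # region length 201 bp; overlap 150 bp -> 150/201 > 0.5
        calls = [CnvCall("A", "1", 251, 400, -1)]
        states = assign_states(self._region(), calls, self.cfg, ["A", "B"])
        assert states["A"] == -1 and states["B"] == 0

    def test_overlap_exactly_at_threshold_gives_zero(self):
        # region [1,200], length 200; overlap exactly 100 -> 0.5 is not > 0.5
        region = self._region(start=1, end=200)
        calls = [CnvCall("A", "1", 101, 200, +1)]
        states = assign_states(region, calls, self.cfg, ["A"])
        assert states["A"] == 0

    def test_no_overlapping_call_gives_zero(self):
        calls = [CnvCall("A", "1", 500, 600, -1)]
        assert assign_states(self._region(), calls, self.cfg, ["A"])["A"] == 0

    def test_longest_overlap_wins(self):
        calls = [
            CnvCall("A", "1", 200, 280, +2),   # overlap 81
            CnvCall("A", "1", 230, 400, -1),   # overlap 171 -> wins
        ]
        assert assign_states(self._region(), calls, self.cfg, ["A"])["A"] == -1

    def test_tie_prefers_larger_magnitude_then_leftmost(self):
        region = self._region(start=100, end=299)  # length 200
        calls = [
            CnvCall("A", "1", 100, 250, -1),  # overlap 151
            CnvCall("A", "1", 149, 299, +2),  # overlap 151, |state| larger -> wins
        ]
        assert assign_states(region, calls, self.cfg, ["A"])["A"] == +2

    def test_absolute_length_alternative(self):
        cfg = DetectionConfig(freq_threshold=0.1, absolute_len_threshold=100)
        calls = [CnvCall("A", "1", 251, 400, -1)]  # overlap 150 > 100 bp
        assert assign_states(self._region(), calls, cfg, ["A"])["A"] == -1
        cfg2 = DetectionConfig(freq_threshold=0.1, absolute_len_threshold=150)
        assert assign_states(self._region(), calls, cfg2, ["A"])["A"] == 0

    def test_state_matrix_shape_and_alignment(self, three_subject_calls):
        cfg = DetectionConfig(freq_threshold=0.5)
        regions = detect_sub_cnvrs(three_subject_calls, 4, cfg)
        matrix = build_state_matrix(regions, three_subject_calls, cfg, list("ABCD"))
        assert matrix.frame.shape == (1, 4)
        assert matrix.frame.loc["1:200-300"].tolist() == [-1, -1, -1, 0]
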