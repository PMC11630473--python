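"""Coverage-based detection: filters, background statistics, window calling,
merging and border refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prophagekit import (
    AlignmentRecord,
    BackgroundStats,
    CandidateElement,
    DetectionParams,
    background_stats,
    call_high_coverage_regions,
    call_plasmid_contig,
    detect_elements,
    filter_alignments,
    merge_elements,
    refine_borders,
    sample_qc,
    segment_contigs,
    simulate_clipped_alignments,
    sliding_window_means,
)


def _rec(**kw):
    defaults = dict(read_id="r", contig="c", start=0, end=120, identity=0.995,
                    aligned_read_fraction=0.9, is_primary=True)
    defaults.update(kw)
    return AlignmentRecord(**defaults)


class TestAlignmentFilter:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(), True),
            (dict(identity=0.985), False),
            (dict(is_primary=False), False),
            (dict(end=49), False),                      # alignment < 50 bp
            (dict(aligned_read_fraction=0.79), False),
            (dict(identity=0.99, end=50, aligned_read_fraction=0.80), True),  # boundaries inclusive
        ],
    )
    def test_filter_contract(self, kwargs, kept):
        out = list(filter_alignments([_rec(**kwargs)]))
        assert bool(out) is kept

    def test_sample_qc_strict_threshold(self):
        assert not sample_qc(250_000)
        assert sample_qc(250_001)
        assert not sample_qc(0)


class TestSegmentation:
    def test_long_contig_sliced_into_equal_pieces(self):
        segs = segment_contigs({"c": 900_000})
        assert len(segs) == 3
        assert all(s.length == 300_000 for s in segs)
        assert segs[-1].end == 900_000

    def test_role_assignment_by_length(self):
        roles = {
            300_000: "background_eligible",
            80_000: "background_eligible",
            60_000: "plasmid_candidate",
            4_000: "too_short",
        }
        for length, role in roles.items():
            (seg,) = segment_contigs({"c": length})
            assert seg.role == role, length

    def test_remainder_absorbed_by_last_piece(self):
        segs = segment_contigs({"c": 700_001})
        assert len(segs) == 3
        assert sum(s.length for s in segs) == 700_001
        assert segs[-1].length - segs[0].length <= 2


class TestBackgroundStats:
    def test_constant_depth(self):
        st_ = background_stats(np.full(100, 10))
        assert (st_.median, st_.corrected_std) == (10.0, 0.0)

    def test_extreme_values_excluded(self):
        st_ = background_stats(np.array([10, 10, 10, 100]))
        assert st_.median == 10.0
        assert st_.corrected_std == 0.0
        assert st_.n_bases_used == 3

    def test_no_extremes_equals_plain_population_sd(self):
        data = np.array([4, 6, 8, 10, 12])
        st_ = background_stats(data)
        assert st_.median == 8.0
        assert st_.corrected_std == pytest.approx(np.sqrt(8.0))

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_filter_then_sd_oracle(self, values):
        """Independent oracle: filter values above 3x median, then population SD."""
        arr = np.array(values)
        med = float(np.median(arr))
        kept = [v for v in values if v <= 3 * med]
        expected = float(np.std(kept)) if kept else 0.0
        got = background_stats(arr)
        assert got.median == med
        assert got.corrected_std == pytest.approx(expected)
        assert got.n_bases_used == len(kept)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            background_stats(np.array([]))


class TestPlasmidRule:
    def test_threshold_is_strict(self, rng):
        # contig with median 80 vs genome median 50 + std: boundary behavior
        flat = np.full(10_000, 80)
        assert call_plasmid_contig(flat, genome_median=50.0)      # 80 > 50 + 0
        assert not call_plasmid_contig(flat, genome_median=80.0)  # equality fails

    def test_size_range_enforced(self):
        with pytest.raises(ValueError):
            call_plasmid_contig(np.full(1_000, 80), 50.0)


class TestSlidingWindows:
    def test_constant_depth_gives_constant_means(self):
        starts, means = sliding_window_means(np.full(1_000, 20))
        assert np.all(means == 20.0)
        assert starts[0] == 0 and np.all(np.diff(starts) == 50)

    @pytest.mark.parametrize("length,n", [(250, 1), (300, 2), (299, 1), (249, 0)])
    def test_window_count(self, length, n):
        starts, means = sliding_window_means(np.full(length, 5))
        assert len(starts) == len(means) == n

    def test_each_mean_covers_exactly_one_window(self):
        depth = np.zeros(400)
        depth[:250] = 10  # first window all 10s, second window 200x10
        starts, means = sliding_window_means(depth)
        assert means[0] == 10.0
        assert means[1] == pytest.approx(200 * 10 / 250)


class TestRegionCalling:
    def _call(self, means, med=50.0, sd=10.0):
        starts = np.arange(len(means)) * 50
        return call_high_coverage_regions(
            starts, np.array(means, dtype=float), BackgroundStats(med, sd, 1)
        )

    def test_long_run_above_one_sigma_called(self):
        # 40 windows at median+2sd: span 250+39*50 = 2200 > 1500
        els = self._call([70.0] * 40)
        assert len(els) == 1
        assert els[0].end - els[0].start == 2200

    def test_short_run_at_two_sigma_not_called(self):
        # 12 windows span 800: needs >3 sigma
        els = self._call([70.0] * 12)
        assert els == []

    def test_short_run_above_three_sigma_called(self):
        els = self._call([95.0] * 12)
        assert len(els) == 1
        assert els[0].end - els[0].start == 800

    def test_never_emits_span_below_500(self):
        for n in range(1, 6):  # spans 250..450
            assert self._call([500.0] * n) == []

    def test_zero_sd_any_excess_qualifies(self):
        els = self._call([50.5] * 40, sd=0.0)
        assert len(els) == 1


class TestMerging:
    def test_gap_below_1000_merges(self):
        a = CandidateElement("c", 1_000, 2_000)
        b = CandidateElement("c", 2_500, 4_000)
        (merged,) = merge_elements([a, b])
        assert (merged.start, merged.end) == (1_000, 4_000)

    def test_gap_of_exactly_1000_not_merged(self):
        a = CandidateElement("c", 1_000, 2_000)
        b = CandidateElement("c", 3_000, 4_000)
        assert len(merge_elements([a, b])) == 2

    def test_idempotent_and_separated(self):
        els = [CandidateElement("c", s, s + 700) for s in range(0, 20_000, 900)]
        once = merge_elements([CandidateElement(e.contig, e.start, e.end) for e in els])
        twice = merge_elements([CandidateElement(e.contig, e.start, e.end) for e in once])
        assert [(e.start, e.end) for e in once] == [(e.start, e.end) for e in twice]
        for e1, e2 in zip(once, once[1:]):
            assert e2.start - e1.end >= 1_000

    def test_cross_contig_link_not_concatenated(self):
        a = CandidateElement("cA", 9_500, 10_000, element_id="a")
        b = CandidateElement("cB", 0, 600, element_id="b")
        out = merge_elements([a, b], contig_order=["cA", "cB"],
                             contig_lengths={"cA": 10_000, "cB": 50_000})
        assert len(out) == 2
        assert out[0].cross_contig_link == "b"
        assert out[1].cross_contig_link == "a"


class TestBorderRefinement:
    def test_clip_evidence_recovers_planted_borders_exactly(self, small_profile):
        _, profile, truth = small_profile
        clips = simulate_clipped_alignments(truth, 3, 150, seed=2)
        el = CandidateElement("contig_1", 49_800, 60_300)
        s, e, method = refine_borders(el, clips, profile["contig_1"])
        assert (s, e, method) == (50_000, 60_000, "clip")

    def test_coverage_tier_locates_sharp_step(self):
        depth = np.full(30_000, 50.0)
        depth[12_000:20_000] = 250.0
        el = CandidateElement("c", 11_900, 20_100, source="induction")
        s, e, method = refine_borders(el, None, depth)
        assert method == "coverage"
        assert abs(s - 12_000) <= 50
        assert abs(e - 20_000) <= 50

    def test_gene_span_tier_for_inactive_islands(self):
        el = CandidateElement("c", 6_500, 15_500, source="island")
        genes = [(7_000, 7_900), (9_000, 10_500), (14_100, 14_950)]
        s, e, method = refine_borders(el, None, None, island_span=(6_500, 15_500),
                                      gene_calls=genes)
        assert (s, e, method) == (7_000, 14_950, "gene_span")

    def test_no_evidence_keeps_raw_borders(self):
        el = CandidateElement("c", 100, 900, source="island")
        s, e, method = refine_borders(el)
        assert (s, e) == (100, 900)
        assert method == "raw"


class TestEndToEnd:
    def test_planted_element_and_plasmid_recovered(self, small_profile):
        _, profile, truth = small_profile
        res = detect_elements(profile)
        by_contig = {e.contig: e for e in res.elements}
        el = by_contig["contig_1"]
        assert abs(el.start - 50_000) <= 100 and abs(el.end - 60_000) <= 100
        pl = by_contig["plasmid_1"]
        assert (pl.start, pl.end, pl.border_method) == (0, 30_000, "contig_whole")

    def test_null_genome_yields_no_calls(self):
        from prophagekit import SimulationConfig, simulate_depth_profile
        profile, _ = simulate_depth_profile(
            SimulationConfig(seed=77, contig_lengths=[300_000])
        )
        res = detect_elements(profile)
        assert res.elements == []
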