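"""Backfitting, temporal smoothing, segment repair, temporal parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ernstates as es
from ernstates.backfit import Segmentation, refresh_correlations
from ernstates.core import EXCLUDED, UNASSIGNED


@pytest.fixture(scope="module")
def maps2(montage12):
    return es.make_ground_truth_maps(2, montage12, seed=0, corr_ceiling=0.0)


def seg_from_labels(labels, rate=250.0, n_states=4):
    labels = np.asarray(labels, dtype=int)
    corr = np.where(labels >= 0, 0.9, np.nan)
    return Segmentation(labels, corr, rate, n_states)


class TestBackfit:
    def test_dominant_template_wins(self, maps2, montage12):
        data = np.column_stack([maps2.templates[0] * 5, maps2.templates[1] * 2])
        seg = es.backfit(data, maps2, min_corr=0.5, rate=250.0)
        np.testing.assert_array_equal(seg.labels, [0, 1])
        np.testing.assert_allclose(seg.corr, [1.0, 1.0], atol=1e-9)

    def test_threshold_unassigns(self, maps2, montage12):
        # a map correlating ~0.45 with both templates stays unassigned at .50
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = es.average_reference(rng.standard_normal(12))
            c = max(
                abs(es.spatial_correlation(v, maps2.templates[0])),
                abs(es.spatial_correlation(v, maps2.templates[1])),
            )
            if c < 0.5:
                break
        else:
            pytest.skip("no sub-threshold map found")
        seg = es.backfit(v[:, None], maps2, min_corr=0.5, rate=250.0)
        assert seg.labels[0] == UNASSIGNED
        seg2 = es.backfit(v[:, None], maps2, min_corr=0.0, rate=250.0)
        assert seg2.labels[0] >= 0

    def test_polarity_invariant_matches_flipped_template(self, maps2):
        data = (-maps2.templates[1])[:, None]
        seg = es.backfit(data, maps2, min_corr=0.5, polarity_mode="invariant", rate=250.0)
        assert seg.labels[0] == 1
        assert seg.corr[0] == pytest.approx(1.0)

    def test_min_corr_zero_labels_every_nonzero_sample(self, maps4, montage30):
        rng = np.random.default_rng(1)
        data = es.average_reference(rng.standard_normal((30, 300)))
        seg = es.backfit(data, maps4, min_corr=0.0, rate=250.0)
        assert np.all(seg.labels >= 0)

    def test_window_restriction_excludes(self, maps2):
        data = np.repeat(maps2.templates[0][:, None], 10, axis=1)
        mask = np.zeros(10, dtype=bool)
        mask[3:7] = True
        seg = es.backfit(data, maps2, min_corr=0.0, rate=250.0, window_mask=mask)
        assert np.all(seg.labels[~mask] == EXCLUDED)
        assert np.all(seg.labels[mask] == 0)


class TestSmoothing:
    def _noisy_seg(self, maps, montage, seed):
        rec, _ = es.simulate_resting_recording(
            maps, montage, duration_s=12, rate=250, snr=1.5, seed=seed
        )
        return rec, es.backfit(rec, maps, min_corr=0.0)

    def test_besag_zero_is_noop(self, maps4, montage30):
        rec, seg = self._noisy_seg(maps4, montage30, 0)
        out = es.smooth_labels(seg, rec, maps4, besag_factor=0.0)
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_island_absorbed(self, maps2, montage12):
        labels = np.array([0] * 20 + [1] + [0] * 20)
        data = maps2.templates[labels].T.copy()
        # make the island's topography genuinely ambiguous so context decides
        data[:, 20] = 0.6 * maps2.templates[1] + 0.55 * maps2.templates[0]
        seg = es.backfit(data, maps2, min_corr=0.0, rate=250.0)
        assert seg.labels[20] == 1
        out = es.smooth_labels(seg, data, maps2, besag_factor=50.0)
        assert out.labels[20] == 0

    def test_segment_count_never_increases(self, maps4, montage30):
        for seed in range(20):
            rec, seg = self._noisy_seg(maps4, montage30, seed)
            out = es.smooth_labels(seg, rec, maps4)
            assert len(out.segments) <= len(seg.segments)

    def test_unassigned_never_relabelled(self, maps4, montage30):
        rec, _ = self._noisy_seg(maps4, montage30, 3)
        seg = es.backfit(rec, maps4, min_corr=0.9)
        out = es.smooth_labels(seg, rec, maps4)
        np.testing.assert_array_equal(
            out.labels == UNASSIGNED, seg.labels == UNASSIGNED
        )


class TestRejectSmallSegments:
    def test_split_rule_example(self):
        # 250 Hz -> threshold ceil(32*250/1000) = 8 samples
        labels = [0] * 10 + [1] * 5 + [2] * 10
        out = es.reject_small_segments(seg_from_labels(labels), min_dur_ms=32.0)
        # B(5) splits 3/2: A gets ceil(5/2)=3, C gets 2
        expected = [0] * 13 + [2] * 12
        np.testing.assert_array_equal(out.labels, expected)

    def test_no_short_segments_identity(self):
        labels = [0] * 10 + [1] * 9 + [0] * 20
        out = es.reject_small_segments(seg_from_labels(labels))
        np.testing.assert_array_equal(out.labels, labels)

    def test_boundary_segment_merges_into_neighbor(self):
        labels = [3] * 4 + [1] * 30
        out = es.reject_small_segments(seg_from_labels(labels))
        np.testing.assert_array_equal(out.labels, [1] * 34)

    def test_short_recording_warns(self):
        with pytest.warns(UserWarning):
            out = es.reject_small_segments(seg_from_labels([2] * 5))
        np.testing.assert_array_equal(out.labels, [2] * 5)

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=40),
        st.lists(st.integers(1, 30), min_size=1, max_size=40),
    )
    @settings(deadline=None, max_examples=250)
    def test_postcondition_no_short_segment(self, seq_labels, seq_lengths):
        labels = np.concatenate(
            [np.full(n, lab) for lab, n in zip(seq_labels, seq_lengths)]
        )
        out = es.reject_small_segments(seg_from_labels(labels), min_dur_ms=32.0)
        runs = out.segments
        if len(labels) >= 8:
            for _, i0, i1 in runs:
                assert i1 - i0 >= 8 or len(runs) == 1
        assert len(out.labels) == len(labels)  # sample count preserved

    def test_excluded_regions_untouched(self):
        labels = np.array([EXCLUDED] * 10 + [0] * 10 + [1] * 3 + [0] * 10 + [EXCLUDED] * 5)
        out = es.reject_small_segments(seg_from_labels(labels))
        assert np.all(out.labels[:10] == EXCLUDED)
        assert np.all(out.labels[-5:] == EXCLUDED)
        assert np.all(out.labels[10:33] == 0)


class TestTemporalParameters:
    def test_perfect_single_map(self, maps2, montage12):
        one = es.MicrostateSet(maps2.templates[:1], "invariant")
        data = np.column_stack([maps2.templates[0] * s for s in [1, 5, 2, 8]])
        seg = es.backfit(data, one, min_corr=0.0, rate=250.0)
        stats = es.temporal_parameters(seg, data, one)
        assert stats.gev[0] == pytest.approx(1.0, abs=1e-12)
        assert stats.coverage_pct[0] == pytest.approx(100.0)

    def test_counting_example(self, maps2):
        # 1000 samples at 250 Hz; state 0 in 4 segments totalling 400 samples
        labels = np.full(1000, 1)
        for start in (0, 250, 500, 750):
            labels[start : start + 100] = 0
        seg = seg_from_labels(labels, rate=250.0, n_states=2)
        rng = np.random.default_rng(0)
        data = es.average_reference(rng.standard_normal((12, 1000)))
        stats = es.temporal_parameters(seg, data, maps2)
        assert stats.coverage_pct[0] == pytest.approx(40.0)
        assert stats.occurrence_per_s[0] == pytest.approx(1.0)
        assert stats.mean_duration_ms[0] == pytest.approx(400.0)

    def test_never_assigned_flagged(self, maps2):
        labels = np.zeros(100, dtype=int)
        seg = seg_from_labels(labels, n_states=2)
        data = es.average_reference(np.random.default_rng(1).standard_normal((12, 100)))
        stats = es.temporal_parameters(seg, data, maps2)
        assert stats.never_assigned[1]
        assert stats.gev[1] == 0 and stats.coverage_pct[1] == 0
        assert stats.mean_duration_ms[1] == 0

    def test_coverage_occurrence_duration_identity(self, maps4, montage30):
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=30, rate=250, snr=5, seed=5
        )
        seg = es.backfit(rec, maps4, min_corr=0.5)
        seg = es.reject_small_segments(seg)
        stats = es.temporal_parameters(seg, rec, maps4)
        for k in range(4):
            if stats.never_assigned[k]:
                continue
            lhs = stats.coverage_pct[k] / 100.0
            rhs = stats.occurrence_per_s[k] * stats.mean_duration_ms[k] / 1000.0
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_gev_streaming_equals_two_pass_oracle(self, maps4, montage30):
        rng = np.random.default_rng(9)
        for trial in range(50):
            n = int(rng.integers(50, 200))
            data = es.average_reference(rng.standard_normal((30, n)))
            seg = es.backfit(data, maps4, min_corr=rng.uniform(0, 0.6), rate=250.0)
            stats = es.temporal_parameters(seg, data, maps4)
            # naive oracle
            gfp = es.compute_gfp(data)
            denom = np.sum(gfp**2)
            for k in range(4):
                num = 0.0
                for t in range(n):
                    if seg.labels[t] == k:
                        c = es.spatial_correlation(
                            data[:, t], maps4.templates[k], "variant"
                        )
                        num += (gfp[t] * c) ** 2
                assert stats.gev[k] == pytest.approx(num / denom, abs=1e-10)
            assert stats.gev.sum() <= 1 + 1e-12

    def test_gev_sums_to_one_in_exact_mixture(self, maps4, montage30):
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=12, rate=250, snr=np.inf, seed=6
        )
        seg = es.backfit(rec, maps4, min_corr=0.0)
        stats = es.temporal_parameters(seg, rec, maps4)
        assert stats.gev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fit_gev_matches_backfit_gev(self, maps4, montage30):
        """Clustering GEV equals temporal-parameter GEV at threshold 0, no smoothing."""
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=12, rate=250, snr=4, seed=8
        )
        peaks = es.extract_gfp_peak_topographies(rec)
        fitted = es.modified_kmeans(peaks, 4, "invariant", restarts=10, seed=0)
        seg = es.backfit(peaks.T, fitted, min_corr=0.0, rate=250.0)
        stats = es.temporal_parameters(seg, peaks.T, fitted)
        assert stats.gev.sum() == pytest.approx(fitted.fit_gev, abs=1e-8)

    def test_determinism(self, maps4, montage30):
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=12, rate=250, snr=3, seed=10
        )
        segs = []
        for _ in range(2):
            seg = es.backfit(rec, maps4, min_corr=0.5)
            seg = es.smooth_labels(seg, rec, maps4)
            seg = es.reject_small_segments(seg)
            segs.append(seg)
        np.testing.assert_array_equal(segs[0].labels, segs[1].labels)
        np.testing.assert_array_equal(segs[0].corr, segs[1].corr)
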