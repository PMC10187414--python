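"""Clustering: GFP peaks, modified k-means, validity criteria, ERP segmentation."""

import numpy as np
import pytest

import ernstates as es
from ernstates.clustering import ErpSegmentation, _pool_templates, assign_topographies
from ernstates.core import EXCLUDED
from ernstates.criteria import CriterionReport


def recording_with_gfp(montage, gfp_series, rate=250.0):
    """Two alternating orthogonal maps scaled to a prescribed GFP series."""
    rng = np.random.default_rng(0)
    base = es.average_reference(rng.standard_normal(montage.n_channels))
    base /= es.compute_gfp(base)
    data = np.column_stack([base * g for g in gfp_series])
    return es.EEGRecording(data, rate, montage)


class TestGfpPeaks:
    def test_simple_peaks(self, montage12):
        rec = recording_with_gfp(montage12, [1, 3, 1, 3, 1])
        peaks = es.extract_gfp_peak_topographies(rec)
        assert peaks.shape == (2, 12)
        np.testing.assert_allclose(es.compute_gfp(peaks.T), [3.0, 3.0])

    def test_monotone_series_no_peaks(self, montage12):
        rec = recording_with_gfp(montage12, np.arange(1.0, 11.0))
        assert es.extract_gfp_peak_topographies(rec).shape[0] == 0

    def test_rectified_sinusoid_peak_count(self, maps4, montage30):
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=10, rate=250, snr=np.inf, seed=0, env_period_ms=100
        )
        gfp = es.compute_gfp(rec.data)
        # oracle: count sign changes (+ to -) of the first difference
        d = np.sign(np.diff(gfp))
        oracle = int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
        peaks = es.extract_gfp_peak_topographies(rec)
        assert peaks.shape[0] == oracle
        assert 90 <= peaks.shape[0] <= 110  # ~one per 100 ms envelope period


class TestModifiedKmeans:
    def test_exact_two_map_mixture(self, montage12):
        maps = es.make_ground_truth_maps(2, montage12, seed=0, corr_ceiling=0.0)
        topos = np.vstack([maps.templates[i % 2] * s for i, s in enumerate([3, -2] * 10)])
        out = es.modified_kmeans(topos, 2, "invariant", restarts=10, seed=1)
        assert out.fit_gev == pytest.approx(1.0, abs=1e-12)
        M = np.abs(out.templates @ maps.templates.T)
        assert M.max(axis=0).min() > 1 - 1e-9  # templates equal up to sign

    def test_k1_variant_is_normalized_mean(self):
        rng = np.random.default_rng(4)
        topos = es.average_reference(rng.standard_normal((8, 10)).T).T
        out = es.modified_kmeans(topos, 1, "variant", restarts=3, seed=0)
        m = topos.mean(axis=0)  # mean of zero-mean maps
        m = m - m.mean()
        m /= np.linalg.norm(m)
        assert abs(np.dot(out.templates[0], m)) > 1 - 1e-9

    def test_monotone_gev_ascent(self, maps4, montage30):
        rec, _ = es.simulate_resting_recording(
            maps4, montage30, duration_s=12, rate=250, snr=3, seed=2
        )
        peaks = es.extract_gfp_peak_topographies(rec)
        out = es.modified_kmeans(peaks, 4, "invariant", restarts=1, seed=3)
        hist = np.array(out.gev_history)
        assert np.all(np.diff(hist) >= -1e-12)

    def test_sign_flip_invariance(self, montage12):
        rng = np.random.default_rng(5)
        topos = rng.standard_normal((30, 12))
        out_a = es.modified_kmeans(topos, 3, "invariant", restarts=20, seed=6)
        flip = np.ones(30)
        flip[::2] = -1
        out_b = es.modified_kmeans(topos * flip[:, None], 3, "invariant", restarts=20, seed=6)
        assert out_a.fit_gev == pytest.approx(out_b.fit_gev, abs=1e-9)
        lab_a, _ = assign_topographies(topos, out_a)
        lab_b, _ = assign_topographies(topos * flip[:, None], out_b)
        # same partition up to cluster renaming
        for j in range(3):
            assert len(set(lab_b[lab_a == j])) == 1

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            es.modified_kmeans(np.random.default_rng(0).standard_normal((3, 5)), 4)

    def test_small_brute_force_optimum(self):
        # 10 maps on 4 channels, k=2: exhaustive assignment search
        rng = np.random.default_rng(42)
        topos = rng.standard_normal((10, 4))
        from ernstates.clustering import _prepare

        X, V, w = _prepare(topos)
        n = 10
        O = np.einsum("ni,nj->nij", X, X).reshape(n, 16)
        masks = ((np.arange(2 ** (n - 1))[:, None] >> np.arange(n - 1)) & 1).astype(float)
        S1 = masks @ O[1:]
        S0 = O.sum(axis=0) - S1
        lam0 = np.linalg.eigvalsh(S0.reshape(-1, 4, 4))[:, -1]
        lam1 = np.linalg.eigvalsh(S1.reshape(-1, 4, 4))[:, -1]
        best = float(((lam0 + lam1) / w.sum()).max())
        out = es.modified_kmeans(topos, 2, "invariant", restarts=100, seed=0)
        assert out.fit_gev == pytest.approx(best, abs=1e-8)


class TestCriteria:
    def _fit_grid(self, topos, k_grid, mode="invariant", seed=0):
        return {
            k: es.modified_kmeans(topos, k, mode, restarts=10, seed=seed + k) for k in k_grid
        }

    def test_separated_clusters_silhouette_peak(self, montage12):
        maps = es.make_ground_truth_maps(4, montage12, seed=3, corr_ceiling=0.0)
        rng = np.random.default_rng(1)
        topos = np.vstack(
            [m + 0.05 * rng.standard_normal((25, 12)) for m in maps.templates]
        )
        sets = self._fit_grid(topos, range(1, 9))
        rep = es.criterion_scores(topos, sets)
        sil = rep.curves["silhouette"]
        assert max(sil, key=sil.get) == 4
        assert es.meta_criterion(rep) == 4

    def test_identical_topographies_degenerate(self, montage12):
        base = es.average_reference(np.random.default_rng(2).standard_normal(12))
        topos = np.tile(base, (20, 1))
        sets = {k: es.MicrostateSet(np.tile(base, (1, 1)), "invariant") for k in range(1, 4)}
        rep = es.criterion_scores(topos, sets)
        assert rep.degenerate
        assert es.meta_criterion(rep) == 1

    def test_small_grid_rejected(self, montage12):
        topos = np.random.default_rng(3).standard_normal((10, 12))
        sets = self._fit_grid(topos, [2, 3])
        with pytest.raises(ValueError):
            es.criterion_scores(topos, sets)

    def test_index_formulas_against_reference(self, montage12):
        """Each index curve matches an independent re-implementation."""
        maps = es.make_ground_truth_maps(3, montage12, seed=9, corr_ceiling=0.2)
        rng = np.random.default_rng(7)
        topos = np.vstack([m + 0.1 * rng.standard_normal((15, 12)) for m in maps.templates])
        k_grid = range(1, 7)
        sets = self._fit_grid(topos, k_grid)
        rep = es.criterion_scores(topos, sets)

        # independent distance matrix
        X = topos - topos.mean(axis=1, keepdims=True)
        V = X / np.linalg.norm(X, axis=1, keepdims=True)
        D = 1 - np.abs(np.clip(V @ V.T, -1, 1))
        np.fill_diagonal(D, 0)

        for k in [3]:
            lab, cw = assign_topographies(topos, sets[k])
            # silhouette by hand
            n = len(lab)
            s_vals = []
            for i in range(n):
                same = (lab == lab[i]) & (np.arange(n) != i)
                a = D[i, same].mean()
                b = min(D[i, lab == j].mean() for j in range(k) if j != lab[i])
                s_vals.append((b - a) / max(a, b))
            assert rep.curves["silhouette"][k] == pytest.approx(np.mean(s_vals), abs=1e-10)

            # Dunn by hand
            diam = max(D[lab == j][:, lab == j].max() for j in range(k))
            inter = min(
                D[lab == a][:, lab == b].min()
                for a in range(k)
                for b in range(k)
                if a < b
            )
            assert rep.curves["dunn"][k] == pytest.approx(inter / diam, abs=1e-10)

            # point-biserial by hand
            iu = np.triu_indices(n, 1)
            diff = (lab[iu[0]] != lab[iu[1]]).astype(float)
            assert rep.curves["point_biserial"][k] == pytest.approx(
                np.corrcoef(D[iu], diff)[0, 1], abs=1e-10
            )


class TestMetaCriterion:
    def _report(self, votes):
        names = [f"c{i}" for i in range(len(votes))]
        return CriterionReport(list(range(1, 13)), {}, dict(zip(names, votes)))

    @pytest.mark.parametrize(
        "votes, expected",
        [
            ([4] * 7, 4),
            ([3, 4, 4, 4, 5, 6, 7], 4),
            ([2, 3, 4, 5, 6, 7, 8], 5),
        ],
    )
    def test_median_vote(self, votes, expected):
        assert es.meta_criterion(self._report(votes)) == expected

    def test_even_count_ties_toward_smaller(self):
        assert es.meta_criterion(self._report([3, 3, 5, 5])) == 3


class TestResampling:
    def test_single_epoch_output_length(self, resting_rec):
        rec, _ = resting_rec
        peaks = es.extract_gfp_peak_topographies(rec)
        sets = es.subject_level_resampling(
            peaks, n_epochs=1, n_subsamples=150, k_grid=range(1, 7), kmeans_restarts=3, seed=0
        )
        assert len(sets) == 1

    def test_identical_topographies_vote_one(self, montage12):
        base = es.average_reference(np.random.default_rng(0).standard_normal(12))
        topos = np.tile(base, (300, 1))
        sets = es.subject_level_resampling(
            topos, n_epochs=2, n_subsamples=100, k_grid=range(1, 5), kmeans_restarts=2, seed=1
        )
        assert all(s.k == 1 for s in sets)

    def test_subsample_clipping_warns(self, montage12):
        topos = np.random.default_rng(1).standard_normal((50, 12))
        with pytest.warns(UserWarning):
            es.subject_level_resampling(
                topos, n_epochs=1, n_subsamples=100, k_grid=range(1, 5),
                kmeans_restarts=2, seed=2,
            )

    def test_planted_k_selected_in_most_epochs(self, resting_rec):
        rec, _ = resting_rec
        filtered = es.spatial_filter(rec)
        peaks = es.extract_gfp_peak_topographies(filtered)
        sets = es.subject_level_resampling(
            peaks, n_epochs=5, n_subsamples=200, k_grid=range(1, 13), kmeans_restarts=4, seed=3
        )
        ks = [s.k for s in sets]
        assert sum(k == 4 for k in ks) >= 4


class TestGroupClustering:
    def _subject_sets(self, maps, montage, n_subjects, seed0):
        out = []
        for i in range(n_subjects):
            rec, _ = es.simulate_resting_recording(
                maps, montage, duration_s=30, rate=250, snr=8, seed=seed0 + i
            )
            peaks = es.extract_gfp_peak_topographies(rec)
            out.append(
                es.subject_level_resampling(
                    peaks, n_epochs=3, n_subsamples=150, k_grid=range(1, 7),
                    kmeans_restarts=4, seed=seed0 + 100 + i,
                )
            )
        return out

    def test_recovers_planted_maps(self, maps4, montage30):
        subject_sets = self._subject_sets(maps4, montage30, 4, 50)
        group = es.group_level_clustering(
            subject_sets, stage1_epochs=4, stage1_sets=12, k_grid=range(1, 7),
            restarts=8, seed=9,
        )
        M = np.abs(group.templates @ maps4.templates.T)
        assert M.max(axis=0).min() >= 0.95

    def test_subject_order_invariance(self, maps4, montage30):
        subject_sets = self._subject_sets(maps4, montage30, 3, 80)
        kw = dict(stage1_epochs=3, stage1_sets=9, k_grid=range(1, 7), restarts=6, seed=11)
        a = es.group_level_clustering(subject_sets, **kw)
        b = es.group_level_clustering(subject_sets[::-1], **kw)
        np.testing.assert_array_equal(a.templates, b.templates)

    def test_requires_two_subjects(self, maps4, montage30):
        subject_sets = self._subject_sets(maps4, montage30, 1, 120)
        with pytest.raises(ValueError):
            es.group_level_clustering(subject_sets)


class TestErpSegmentation:
    def test_single_map_erp_is_one_state(self, montage12):
        maps = es.make_ground_truth_maps(2, montage12, seed=1)
        times = np.linspace(-500, 800, 326)
        env = np.abs(np.sin(np.pi * (times + 500) / 200)) + 0.1
        data = np.outer(maps.templates[0], env)
        seg = es.segment_grand_average(
            data, times, k_grid=range(1, 6), restarts=10, seed=0
        )
        keep = ~((times >= -500) & (times <= -300))
        assert seg.mset.k == 1
        assert np.all(seg.labels[keep] == 0)
        assert np.all(seg.labels[~keep] == EXCLUDED)

    def test_identify_error_microstate_window(self):
        times = np.arange(-500, 801, 4.0)
        labels = np.full(len(times), EXCLUDED)
        post = times > -300
        labels[post] = 0
        span = (times >= -64) & (times <= 108)
        labels[span] = 1
        labels[post & (times > 108)] = 2
        mset = es.MicrostateSet(np.random.default_rng(0).standard_normal((3, 12)), "variant")
        seg = ErpSegmentation(mset, labels, times)
        (w0, w1), template, lab = es.identify_error_microstate(seg)
        assert lab == 1
        assert w0 == pytest.approx(-64, abs=4)
        assert w1 == pytest.approx(108, abs=4)

    def test_unlabelled_response_time_raises(self):
        times = np.arange(-500, 801, 4.0)
        labels = np.full(len(times), EXCLUDED)
        mset = es.MicrostateSet(np.random.default_rng(0).standard_normal((1, 12)), "variant")
        with pytest.raises(ValueError):
            es.identify_error_microstate(ErpSegmentation(mset, labels, times))


class TestPooling:
    def test_pool_is_order_and_sign_canonical(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 8))
        s1 = es.MicrostateSet(t, "invariant")
        s2 = es.MicrostateSet(-t[::-1], "invariant")
        np.testing.assert_allclose(
            _pool_templates([s1]), _pool_templates([s2]), atol=1e-12
        )
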