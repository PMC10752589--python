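import numpy as np
import pytest

from starburst.imaging import (Movie, cluster_rois, elbow_cluster_count,
                               fit_gaussian_rf, preprocess_trace,
                               reconstruct_rf_map, rf_map_peak,
                               segment_rois, select_active_pixels)
from starburst.metrics import fwhm_from_sigma
from starburst.rf import RFParams
from starburst.synthetic import (NoiseModel, gen_cluster_library, gen_movie,
                                 gen_oriented_bar_responses, gen_roi_dataset,
                                 gen_roi_layout)


class TestActivePixels:
    def test_zero_movie_empty_mask(self):
        mov = Movie(np.zeros((10, 8, 8)))
        assert not select_active_pixels(mov).any()

    def test_zero_threshold_selects_responding_pixels(self):
        data = np.zeros((5, 4, 4))
        data[2, 1, 1] = 0.5
        mov = Movie(data)
        assert select_active_pixels(mov, threshold=0.0).sum() == 1

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Movie(np.full((2, 2, 2), np.nan))


class TestSegmentation:
    def _two_source_movie(self, noise_sd=0.02, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(100)
        tr1 = np.clip(np.sin(t / 6.0), 0, None)
        tr2 = np.clip(np.sin((t - 30) / 10.0), 0, None)
        centers = np.array([[30.0, 30.0], [120.0, 120.0]])
        return gen_movie(centers, [tr1, tr2], psf_sigma=0.5,
                         noise_sd=noise_sd, seed=seed, roi_radius=5.0)

    def test_two_separated_sources_recovered(self):
        mov = self._two_source_movie()
        rois = segment_rois(mov, select_active_pixels(mov, 0.2))
        assert len(rois) >= 2
        # each ROI's pixels should map to a single ground-truth source
        correct = total = 0
        for roi in rois:
            ids = [mov.truth[i, j] for i, j in roi["pixels"]]
            ids = [i for i in ids if i >= 0]
            if not ids:
                continue
            vals, counts = np.unique(ids, return_counts=True)
            correct += counts.max()
            total += len(ids)
        assert total > 0 and correct / total >= 0.95

    def test_extent_constraint_respected(self):
        from scipy.spatial.distance import pdist
        mov = self._two_source_movie()
        rois = segment_rois(mov, select_active_pixels(mov, 0.2),
                            max_extent=10.0)
        for roi in rois:
            pts = np.array(roi["pixels"]) * mov.pixel_size
            if len(pts) > 1:
                assert pdist(pts).max() <= 10.0 + 1e-9

    def test_high_cv_rois_dropped(self):
        """An ROI whose pixel amplitudes vary with CV > 1 is removed,
        while a same-shaped uniform-amplitude ROI is kept."""
        wave = np.clip(np.sin(np.arange(80) / 5.0), 0, None)
        for amps, expect_kept in ((np.array([10.0, 0.1, 0.1, 0.1]), False),
                                  (np.array([1.0, 1.1, 0.9, 1.0]), True)):
            data = np.zeros((80, 4, 4))
            data[:, 1, 0:4] = wave[:, None] * amps
            mov = Movie(data, pixel_size=1.0)
            mask = np.zeros((4, 4), dtype=bool)
            mask[1, 0:4] = True
            rois = segment_rois(mov, mask, max_extent=5.0, cv_max=1.0,
                                k_start=1)
            kept = {p for r in rois for p in r["pixels"]}
            assert ((1, 0) in kept) == expect_kept

    def test_empty_mask_gives_no_rois(self):
        mov = Movie(np.zeros((5, 6, 6)))
        assert segment_rois(mov, np.zeros((6, 6), dtype=bool)) == []


class TestPreprocess:
    def test_smooth_trace_nearly_unchanged(self):
        t = np.arange(300)
        x = np.clip(np.sin((t - 50) / 40.0), 0, None)
        y = preprocess_trace(x)
        n = np.corrcoef(x, y)[0, 1]
        assert n > 0.999
        assert y.max() == pytest.approx(1.0)

    def test_high_frequency_power_attenuated(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096) + 5.0
        x[0:10] = 5.0   # stable baseline window
        y = preprocess_trace(x)
        fx = np.abs(np.fft.rfft(x - x.mean())) ** 2
        fy = np.abs(np.fft.rfft(y - y.mean())) ** 2
        hi = slice(len(fx) // 2, None)          # well above 0.05 x fs cutoff
        atten = fy[hi].sum() / fx[hi].sum() * (fx[:50].sum() / fy[:50].sum())
        assert atten < 0.05

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            preprocess_trace(np.zeros(50))


class TestElbow:
    def test_constructed_knee_found(self):
        # piecewise-linear: steep to k = 7, nearly flat afterwards
        y = np.r_[np.linspace(4000, 60, 7), np.linspace(55, 40, 5)]
        assert elbow_cluster_count(y) == 7

    def test_flat_curve_one_cluster(self):
        assert elbow_cluster_count(np.full(10, 3.0)) == 1

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            elbow_cluster_count(np.array([5.0, 3.0, 4.0, 2.0]))


class TestClustering:
    def test_partition_recovery_small_library(self):
        from sklearn.metrics import adjusted_rand_score
        lib = gen_cluster_library("OFF6")
        rois, labels = gen_roi_dataset(lib, n_rois=72,
                                       noise=NoiseModel(sd=0.1), seed=2)
        cs = cluster_rois(rois, k=6, metric="maximum")
        assert adjusted_rand_score(labels, cs.labels) >= 0.9

    def test_duplicated_rois_identical_partition(self):
        lib = gen_cluster_library("ON7")
        rois, _ = gen_roi_dataset(lib, n_rois=40, seed=3)
        a = cluster_rois(list(rois), k=7)
        b = cluster_rois(list(rois), k=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_clusters_sorted_most_transient_first(self):
        from starburst.metrics import transiency_index
        lib = gen_cluster_library("ON7")
        rois, _ = gen_roi_dataset(lib, n_rois=100,
                                  noise=NoiseModel(sd=0.05), seed=4)
        cs = cluster_rois(rois, k=7)
        tis = []
        for w in cs.mean_waveforms:
            shifted = w - w.min()
            tis.append(transiency_index(shifted))
        assert all(np.diff(tis) <= 1e-9)

    def test_needs_at_least_two_rois(self):
        with pytest.raises(ValueError):
            cluster_rois([])


class TestRFMapping:
    def test_phantom_peak_recovered_within_ten_microns(self):
        resp, th, pos = gen_oriented_bar_responses(
            RFParams(center_width=90.0), center=(25.0, -15.0))
        m = reconstruct_rf_map(resp, th, pos)
        x, y = rf_map_peak(m)
        assert np.hypot(x - 25.0, y - (-15.0)) <= 10.0

    def test_uniform_responses_no_spurious_peak(self):
        """Uniform projections reconstruct without a dominant localized
        peak (5-angle FBP leaves ~30-40% streak ripple in the core, so
        exact flatness is not attainable; the guard is against a spurious
        source-like maximum)."""
        th = np.arange(5) * 36.0
        pos = (np.arange(32) - 16) * (300.0 / 32)
        m = reconstruct_rf_map(np.ones((5, 32)), th, pos)
        n = m.grid.shape[0]
        c = slice(n // 4, 3 * n // 4)
        core = m.grid[c, c]
        assert core.max() < 1.6 * core.mean()
        assert core.min() > 0.0

    def test_two_sources_resolved_at_100um(self):
        r1, th, pos = gen_oriented_bar_responses(
            RFParams(center_width=50.0), center=(-50.0, 0.0))
        r2, _, _ = gen_oriented_bar_responses(
            RFParams(center_width=50.0), center=(50.0, 0.0))
        m = reconstruct_rf_map(r1 + r2, th, pos)
        n = m.grid.shape[0]
        mid = m.grid[n // 2]
        # two local maxima separated by a dip at the center
        peak = mid.max()
        center_val = mid[n // 2]
        assert center_val < 0.8 * peak

    def test_missing_projections_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_rf_map(np.full((5, 32), np.nan),
                               np.arange(5) * 36.0, np.linspace(-150, 150, 32))

    def test_gaussian_fit_self_consistency(self):
        n = 32
        c = (np.arange(n) - (n - 1) / 2) * 10.0
        X, Y = np.meshgrid(c, c)
        sx, sy = 40.0, 55.0
        from starburst.imaging import RFMap
        grid = np.exp(-X ** 2 / (2 * sx ** 2) - Y ** 2 / (2 * sy ** 2))
        m = RFMap(grid=grid, pixel_size=10.0, extent=310.0)
        fx, fy, fwhm = fit_gaussian_rf(m)
        assert fx == pytest.approx(sx, rel=0.01)
        assert fy == pytest.approx(sy, rel=0.01)
        assert fwhm == pytest.approx(fwhm_from_sigma(sx), rel=0.01)

    def test_end_to_end_fwhm_recovery(self):
        resp, th, pos = gen_oriented_bar_responses(
            RFParams(center_width=100.0), center=(0.0, 0.0))
        m = reconstruct_rf_map(resp, th, pos)
        _, _, fwhm = fit_gaussian_rf(m)
        assert fwhm == pytest.approx(100.0, abs=10.0)
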