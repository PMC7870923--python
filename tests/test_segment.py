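"""Blob-detection pipeline: flattening, LoG ladder, maxima, threshold, mask."""

import math
import time

import numpy as np
import pytest

from evflim import DetectionConfig, SimulationConfig, integrate_intensity, render_ev_fov
from evflim.segment import (
    detections_to_mask,
    find_maxima_3d,
    flatten_background,
    log_filter_stack,
    match_centers,
    segment_evs,
    threshold_detections,
)


def _gaussian_blob(shape, center, sigma, amplitude=100.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


@pytest.fixture(scope="module")
def phantom_50():
    """Seeded 50-blob field at >= 10x noise contrast (256 px, defaults)."""
    config = SimulationConfig(
        fov_shape=(256, 256), n_evs=50, seed=17, photon_budget=(2000.0, 20000.0)
    )
    stack, truths = render_ev_fov(config)
    return integrate_intensity(stack), truths


class TestFlattenBackground:
    def test_constant_image_flattens_to_zero(self):
        out = flatten_background(np.full((64, 64), 7.0), 10.0)
        assert np.abs(out).max() < 1e-6

    def test_planar_gradient_does_not_disturb_detector_response(self):
        # flattening exists to make the detector insensitive to slow
        # background drift: compare LoG responses with and without a ramp
        img = _gaussian_blob((96, 96), (48, 48), 1.5, amplitude=200.0)
        rr, cc = np.mgrid[:96, :96]
        gradient = 0.5 * rr + 0.3 * cc
        scales = (1.0, 1.4, 2.0)
        r_plain = log_filter_stack(flatten_background(img, 20.0), scales)
        r_grad = log_filter_stack(flatten_background(img + gradient, 20.0), scales)
        peak = r_plain.max()
        assert abs(r_grad.max() - peak) <= 0.02 * peak
        interior = (slice(10, -10), slice(10, -10))
        assert np.abs((r_grad - r_plain)[interior]).max() <= 0.02 * peak

    def test_background_median_near_zero_on_sparse_dim_field(self):
        # the flattened-background statistic is meaningful for the sparse,
        # dim fields EV imaging produces (vesicle flux << background noise)
        config = SimulationConfig(n_evs=20, seed=19, photon_budget=(500.0, 2000.0))
        stack, truths = render_ev_fov(config)
        img = integrate_intensity(stack)
        flat = flatten_background(img.astype(float), 20.0)
        bg = np.ones(img.shape, dtype=bool)
        for t in truths:
            r, c = int(round(t.center[0])), int(round(t.center[1]))
            bg[max(r - 8, 0) : r + 9, max(c - 8, 0) : c + 9] = False
        noise_sd = np.std(flat[bg])
        assert abs(np.median(flat[bg])) < 0.1 * noise_sd


class TestLogFilter:
    def test_scale_selection_matches_blob_size(self):
        scales = (0.8, 0.8 * math.sqrt(2), 1.6, 1.6 * math.sqrt(2), 3.2)
        for sigma_blob in (0.9, 1.6, 2.8):
            img = _gaussian_blob((64, 64), (32, 32), sigma_blob)
            stack = log_filter_stack(img, scales)
            best = int(np.argmax(stack[32, 32, :]))
            nearest = int(np.argmin(np.abs(np.array(scales) - sigma_blob)))
            assert abs(best - nearest) <= 1

    def test_zero_image_zero_response(self):
        assert np.all(log_filter_stack(np.zeros((32, 32)), (1.0, 2.0)) == 0)

    def test_linearity(self):
        img = _gaussian_blob((48, 48), (24, 24), 2.0)
        r1 = log_filter_stack(img, (1.0, 2.0))
        r2 = log_filter_stack(2 * img, (1.0, 2.0))
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            log_filter_stack(np.zeros((8, 8)), ())


class TestFindMaxima:
    SCALES = (1.0, 1.4, 2.0)

    def test_single_blob_single_detection(self):
        img = _gaussian_blob((64, 64), (30, 40), 1.5)
        dets = find_maxima_3d(log_filter_stack(img, self.SCALES), self.SCALES)
        strong = [d for d in dets if d.response > 0.5 * max(x.response for x in dets)]
        assert len(strong) == 1
        assert abs(strong[0].center[0] - 30) <= 1 and abs(strong[0].center[1] - 40) <= 1

    def test_two_blobs_far_apart(self):
        img = _gaussian_blob((64, 64), (20, 20), 1.5) + _gaussian_blob(
            (64, 64), (20, 40), 1.5
        )
        dets = find_maxima_3d(log_filter_stack(img, self.SCALES), self.SCALES)
        strong = [d for d in dets if d.response > 0.5 * max(x.response for x in dets)]
        assert len(strong) == 2

    def test_constant_stack_yields_nothing(self):
        assert find_maxima_3d(np.ones((16, 16, 3)), self.SCALES) == []

    def test_isolated_plateau_yields_one_detection(self):
        stack = np.zeros((16, 16, 3))
        stack[5, 5:7, 1] = 3.0  # two equal-valued voxels above surroundings
        dets = find_maxima_3d(stack, self.SCALES)
        assert len(dets) == 1
        assert dets[0].center == (5, 5)  # earliest raster voxel

    def test_min_separation_keeps_larger_response(self):
        stack = np.zeros((16, 16, 3))
        stack[5, 5, 1] = 2.0
        stack[5, 8, 1] = 3.0
        dets = find_maxima_3d(stack, self.SCALES, min_separation=5.0)
        assert len(dets) == 1 and dets[0].center == (5, 8)


class TestThreshold:
    def test_huge_threshold_accepts_nothing(self, phantom_50):
        img, _ = phantom_50
        flat = flatten_background(img.astype(float), 20.0)
        dets = find_maxima_3d(log_filter_stack(flat, (1.0, 1.4, 2.0)), (1.0, 1.4, 2.0))
        out = threshold_detections(dets, flat, 1e9)
        assert not any(d.accepted for d in out)

    def test_monotone_in_threshold(self, phantom_50):
        img, _ = phantom_50
        flat = flatten_background(img.astype(float), 20.0)
        dets = find_maxima_3d(log_filter_stack(flat, (1.0, 1.4, 2.0)), (1.0, 1.4, 2.0))
        counts = [
            sum(d.accepted for d in threshold_detections(dets, flat, k))
            for k in (1.0, 3.0, 10.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_noise_accepts_positive_responses(self):
        img = _gaussian_blob((64, 64), (32, 32), 1.5)  # noise-free
        flat = np.zeros_like(img)
        dets = find_maxima_3d(log_filter_stack(img, (1.0, 1.4, 2.0)), (1.0, 1.4, 2.0))
        out = threshold_detections(dets, flat, 3.0)
        assert any(d.accepted and d.response > 0 for d in out)


class TestMask:
    def test_disk_pixel_count(self):
        from evflim.segment import BlobDetection

        det = BlobDetection(center=(10, 10), sigma=2.0, response=1.0, accepted=True)
        mask = detections_to_mask([det], (21, 21), mask_radius_factor=math.sqrt(2))
        # lattice points with r^2 <= 8 around the centre
        assert (mask.labels == 1).sum() == 25

    def test_no_detections_all_background(self):
        assert detections_to_mask([], (8, 8)).labels.sum() == 0

    def test_overlapping_disks_partition_by_distance(self):
        from evflim.segment import BlobDetection

        dets = [
            BlobDetection(center=(10, 8), sigma=3.0, response=2.0, accepted=True),
            BlobDetection(center=(10, 13), sigma=3.0, response=1.0, accepted=True),
        ]
        mask = detections_to_mask(dets, (21, 21))
        lab = mask.labels
        assert set(np.unique(lab)) == {0, 1, 2}
        own1 = np.argwhere(lab == 1)
        own2 = np.argwhere(lab == 2)
        d1 = ((own1 - [10, 8]) ** 2).sum(1)
        d1b = ((own1 - [10, 13]) ** 2).sum(1)
        assert np.all(d1 <= d1b)  # label-1 pixels are nearer centre 1 (ties -> 1)
        assert np.all(((own2 - [10, 13]) ** 2).sum(1) < ((own2 - [10, 8]) ** 2).sum(1))


class TestEndToEnd:
    def test_precision_recall_on_phantom(self, phantom_50):
        img, truths = phantom_50
        _, dets = segment_evs(img)
        acc = np.array([d.center for d in dets if d.accepted], dtype=float)
        truth = np.array([t.center for t in truths])
        m, nd, nt = match_centers(acc, truth, radius=3.0)
        assert m / nd >= 0.9  # precision
        assert m / nt >= 0.9  # recall

    def test_scale_permutation_invariance(self, phantom_50):
        img, _ = phantom_50
        base = DetectionConfig()
        permuted = DetectionConfig(scales=tuple(reversed(base.scales)))
        m1, d1 = segment_evs(img, base)
        m2, d2 = segment_evs(img, permuted)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        assert d1 == d2

    def test_translation_equivariance(self):
        config = SimulationConfig(
            fov_shape=(128, 128), n_evs=6, seed=23, margin_px=25.0,
            photon_budget=(5000.0, 20000.0),
        )
        stack, _ = render_ev_fov(config)
        img = integrate_intensity(stack)
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        _, d1 = segment_evs(img)
        _, d2 = segment_evs(shifted)
        c1 = sorted((d.center[0] + 7, d.center[1] - 5) for d in d1 if d.accepted)
        c2 = sorted(d.center for d in d2 if d.accepted)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1

    def test_detected_scale_tracks_blob_size(self):
        config = DetectionConfig()
        scales = np.array(config.scales)
        for sigma_blob in (0.9, 1.6, 2.6):
            img = _gaussian_blob((96, 96), (48, 48), sigma_blob, amplitude=500.0)
            noise = np.random.default_rng(1).poisson(5.0, img.shape)
            _, dets = segment_evs(img + noise, config)
            acc = [d for d in dets if d.accepted]
            assert acc
            best = max(acc, key=lambda d: d.response)
            idx = int(np.argmin(np.abs(scales - best.sigma)))
            true_idx = int(np.argmin(np.abs(scales - sigma_blob)))
            assert abs(idx - true_idx) <= 1

    def test_agrees_with_reference_blob_detector(self):
        """Cross-check against an independent multiscale LoG implementation."""
        skimage_feature = pytest.importorskip("skimage.feature")
        img = np.zeros((128, 128))
        centers = [(20, 20), (40, 90), (80, 50), (100, 100), (64, 20)]
        for r, c in centers:
            img += _gaussian_blob((128, 128), (r, c), 1.6, amplitude=300.0)
        _, dets = segment_evs(img)
        ours = np.array([d.center for d in dets if d.accepted], dtype=float)
        ref = skimage_feature.blob_log(
            img, min_sigma=0.8, max_sigma=3.2, num_sigma=8, threshold=1.0
        )[:, :2]
        m, nd, nt = match_centers(ours, ref, radius=2.0)
        assert nd == len(centers) and nt == len(centers) and m == len(centers)

    def test_runtime_on_full_protocol_geometry(self):
        config = SimulationConfig(n_evs=50, seed=29, photon_budget=(5000.0, 20000.0))
        stack, _ = render_ev_fov(config)
        img = integrate_intensity(stack)
        start = time.perf_counter()
        segment_evs(img)
        assert time.perf_counter() - start < 10.0
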