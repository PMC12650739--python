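"""Classical boundary-detection chain, each stage against an independent
oracle (brute-force medians, direct 2-D convolution, exhaustive Otsu
search, flood fill) plus the end-to-end ground-truth recovery check."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from organoidseg.classical import (PreprocessConfig, edge_magnitude, erode,
                                   extract_green_channel, fill_holes,
                                   label_particles, make_groundtruth,
                                   median_filter, otsu_threshold, propose_rois,
                                   threshold_binary)
from organoidseg.errors import DegenerateInputError, FormatError, ParameterError
from organoidseg.metrics import confusion, dice
from organoidseg.synth import SynthParams, generate_organoid_image


class TestGreenChannel:
    def test_rgb_selects_middle_plane(self):
        rng = np.random.default_rng(2)
        img = rng.random((9, 7, 3))
        assert np.array_equal(extract_green_channel(img), img[:, :, 1])

    def test_grayscale_identity(self):
        img = np.random.default_rng(0).random((5, 5))
        assert extract_green_channel(img) is img

    def test_constant_green_plane(self):
        img = np.stack([np.zeros((4, 4)), np.full((4, 4), 0.5),
                        np.ones((4, 4))], axis=-1)
        assert np.all(extract_green_channel(img) == 0.5)

    def test_bad_channel_count(self):
        with pytest.raises(FormatError):
            extract_green_channel(np.zeros((4, 4, 2)))


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((6, 6), 0.3)
        assert np.array_equal(median_filter(img, 1), img)

    def test_impulse_rejected(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert np.all(median_filter(img, 1) == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        img = rng.random((7, 7))
        got = median_filter(img, 1)
        padded = np.pad(img, 1, mode="edge")
        expected = np.empty_like(img)
        for r in range(7):
            for c in range(7):
                expected[r, c] = np.median(sorted(
                    padded[r:r + 3, c:c + 3].ravel()))
        assert np.allclose(got, expected)

    def test_radius_validated(self):
        with pytest.raises(ParameterError):
            median_filter(np.zeros((4, 4)), 0)


class TestEdgeMagnitude:
    def test_constant_image_zero(self):
        assert np.all(edge_magnitude(np.full((8, 8), 0.7), 1.0) == 0.0)

    def test_step_edge_response_symmetric(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        mag = edge_magnitude(img, 1.0)
        col_profile = mag.mean(axis=0)
        assert col_profile.argmax() in (7, 8)
        assert np.allclose(col_profile[:8], col_profile[15:7:-1], atol=1e-12)

    def test_matches_direct_2d_convolution_oracle(self):
        from organoidseg.classical import _gauss_kernels

        rng = np.random.default_rng(23)
        img = rng.random((16, 16))
        sigma = 1.0
        got = edge_magnitude(img, sigma)
        g, dg = _gauss_kernels(sigma)
        ky = np.outer(dg, g)   # row derivative
        kx = np.outer(g, dg)   # column derivative
        rad = len(g) // 2
        padded = np.pad(img, rad, mode="edge")
        gy = np.empty_like(img)
        gx = np.empty_like(img)
        for r in range(16):
            for c in range(16):
                win = padded[r:r + 2 * rad + 1, c:c + 2 * rad + 1]
                gy[r, c] = np.sum(win * ky)
                gx[r, c] = np.sum(win * kx)
        expected = np.hypot(gx, gy)
        expected /= expected.max()
        assert np.allclose(got, expected, atol=1e-6)

    def test_sigma_validated(self):
        with pytest.raises(ParameterError):
            edge_magnitude(np.zeros((4, 4)), 0.0)


class TestThreshold:
    def test_otsu_separates_bimodal_exactly(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((16, 16)) < 0.3, 0.2, 0.8)
        mask = threshold_binary(img, polarity="dark")
        assert np.array_equal(mask, img == 0.2)

    def test_fixed_threshold_partition(self):
        img = np.where(np.arange(16).reshape(4, 4) < 6, 0.4, 0.6)
        cfg = PreprocessConfig(threshold_method="fixed", fixed_threshold=0.5)
        mask = threshold_binary(img, cfg, polarity="dark")
        assert np.array_equal(mask, img == 0.4)
        bright = threshold_binary(img, cfg, polarity="bright")
        assert np.array_equal(bright, ~mask)

    @pytest.mark.parametrize("seed", range(25))
    def test_otsu_equals_exhaustive_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.clip(np.concatenate([
            rng.normal(0.35, 0.1, 200), rng.normal(0.75, 0.07, 120)
        ]), 0, 1).reshape(20, 16)
        thr = otsu_threshold(img)
        t_impl = int(round(thr * 256)) - 1
        bins = np.clip((img.ravel() * 256).astype(int), 0, 255)
        hist = np.bincount(bins, minlength=256).astype(float)
        centers = np.arange(256.0)
        best_t, best_var = None, -np.inf
        for t in range(255):
            w0, w1 = hist[:t + 1].sum(), hist[t + 1:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:t + 1] * centers[:t + 1]).sum() / w0
            m1 = (hist[t + 1:] * centers[t + 1:]).sum() / w1
            var_b = w0 * w1 * (m0 - m1) ** 2
            if var_b > best_var + 1e-9:
                best_var, best_t = var_b, t
        assert t_impl == best_t

    def test_otsu_agrees_with_skimage(self):
        # skimage bins over the data range, we bin over [0, 1]; thresholds
        # agree up to that binning difference and the partitions coincide
        # away from the threshold itself
        from skimage.filters import threshold_otsu as sk_otsu

        rng = np.random.default_rng(5)
        img = np.where(rng.random((32, 32)) < 0.4, 0.25, 0.8)
        img += rng.normal(0, 0.02, img.shape)
        img = np.clip(img, 0, 1)
        ours = otsu_threshold(img)
        theirs = float(sk_otsu(img, nbins=256))
        assert abs(ours - theirs) < 2 / 256
        disagree = (img < ours) ^ (img < theirs)
        assert disagree.mean() < 0.02

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            otsu_threshold(np.full((8, 8), 0.5))


class TestMorphology:
    def test_fill_holes_annulus(self):
        yy, xx = np.mgrid[0:21, 0:21]
        d = np.hypot(yy - 10, xx - 10)
        ring = (d >= 4) & (d <= 8)
        filled = fill_holes(ring)
        assert np.array_equal(filled, d <= 8)

    def test_fill_holes_identity_and_idempotence(self):
        rng = np.random.default_rng(0)
        for seed in range(50):
            mask = np.random.default_rng(seed).random((12, 12)) > 0.6
            once = fill_holes(mask)
            assert np.array_equal(fill_holes(once), once)
            assert (once & ~mask).sum() >= 0 and (mask & ~once).sum() == 0

    def test_erode_block_leaves_centre(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        out = erode(mask, 1)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        assert np.array_equal(out, expected)

    def test_erode_empty_mask(self):
        assert not erode(np.zeros((6, 6), dtype=bool), 1).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_erode_matches_brute_force_oracle(self, seed):
        mask = np.random.default_rng(seed).random((12, 12)) > 0.4
        got = erode(mask, 1)
        padded = np.pad(mask, 1, constant_values=False)
        expected = np.empty_like(mask)
        for r in range(12):
            for c in range(12):
                expected[r, c] = padded[r:r + 3, c:c + 3].all()
        assert np.array_equal(got, expected)

    def test_containment_chain(self):
        for seed in range(20):
            mask = np.random.default_rng(seed).random((16, 16)) > 0.5
            eroded = erode(mask, 1)
            filled = fill_holes(mask)
            assert not (eroded & ~mask).any()      # erode(m) subset of m
            assert not (mask & ~filled).any()      # m subset of fill_holes(m)
            assert eroded.sum() <= mask.sum() <= filled.sum()


def _flood_fill_components(mask):
    """Oracle: BFS 8-connected labelling in raster order of first pixel."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 1
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < mask.shape[0]
                                    and 0 <= xx < mask.shape[1]
                                    and mask[yy, xx] and labels[yy, xx] == 0):
                                labels[yy, xx] = nxt
                                stack.append((yy, xx))
                nxt += 1
    return labels


class TestParticles:
    def test_two_blocks_counted(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        labels, stats = label_particles(mask, min_area=1)
        assert len(stats) == 2
        assert all(s.area == 9 for s in stats)
        assert labels.max() == 2

    def test_disk_circularity_and_diameter(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = np.hypot(yy - 32, xx - 32) <= 20
        _, stats = label_particles(mask, min_area=1)
        (s,) = stats
        assert 0.85 <= s.circularity <= 1.0
        assert s.equivalent_diameter == pytest.approx(40, rel=0.03)
        assert s.equivalent_diameter**2 * np.pi / 4 == pytest.approx(s.area)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndi.binary_dilation(rng.random((20, 20)) > 0.85)
        labels, stats = label_particles(mask, min_area=1)
        oracle = _flood_fill_components(mask)
        assert labels.max() == oracle.max() == len(stats)
        for s in stats:
            assert np.array_equal(labels == s.label, oracle == s.label)
            assert s.area == (oracle == s.label).sum()

    def test_min_area_filter_erases(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:4, 0:4] = True   # area 16
        mask[8, 8] = True       # area 1
        labels, stats = label_particles(mask, min_area=5)
        assert len(stats) == 1 and stats[0].area == 16
        assert not labels[8, 8]

    def test_empty_mask(self):
        labels, stats = label_particles(np.zeros((6, 6), dtype=bool), 1)
        assert stats == [] and labels.max() == 0


class TestGroundtruthChain:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_low_noise_recovery(self, seed):
        image, truth = generate_organoid_image(
            128, SynthParams(noise_sigma=0.01), seed=seed)
        mask, stats = make_groundtruth(image)
        assert len(stats) == 1
        assert dice(confusion(mask, truth)) >= 0.85

    def test_blank_frame_yields_nothing(self):
        rng = np.random.default_rng(0)
        blank = np.clip(0.82 + rng.normal(0, 0.01, (128, 128)), 0, 1)
        mask, stats = make_groundtruth(blank)
        assert stats == [] and not mask.any()

    def test_output_is_hole_free(self):
        image, _ = generate_organoid_image(128, seed=5)
        mask, _ = make_groundtruth(image)
        assert np.array_equal(fill_holes(mask), mask)

    def test_rgb_input_accepted(self):
        image, truth = generate_organoid_image(
            128, SynthParams(rgb=True, noise_sigma=0.01), seed=7)
        mask, stats = make_groundtruth(image)
        assert len(stats) == 1
        assert dice(confusion(mask, truth)) >= 0.85


class TestProposeRois:
    def test_padding_and_clipping(self):
        from organoidseg.classical import ParticleStats

        s = ParticleStats(label=1, area=400, perimeter=80, circularity=0.8,
                          equivalent_diameter=22.6, centroid=(20.0, 20.0),
                          bbox=(10, 10, 20, 20))
        (box,) = propose_rois([s], margin=10, frame=(128, 128))
        assert box == (0, 0, 40, 40)

    def test_empty_stats(self):
        assert propose_rois([], margin=5, frame=(64, 64)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_boxes_contain_their_particles(self, seed):
        mask = np.random.default_rng(seed).random((32, 32)) > 0.9
        mask = ndi.binary_dilation(mask)
        labels, stats = label_particles(mask, min_area=1)
        boxes = propose_rois(stats, margin=3, frame=mask.shape)
        for s, (top, left, h, w) in zip(stats, boxes):
            inside = np.zeros_like(mask)
            inside[top:top + h, left:left + w] = True
            assert not ((labels == s.label) & ~inside).any()
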