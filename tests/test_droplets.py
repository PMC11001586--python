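"""Auto-thresholds, droplet segmentation and particle metrics."""

import math
from collections import deque

import numpy as np
import pytest
from skimage.filters import threshold_triangle as sk_triangle

from drosoquant import droplets, synthetic
from drosoquant.droplets import (
    DegenerateHistogramError,
    IntensityHistogram,
    SegmentationConfig,
)


def random_histogram(rng):
    """Random 256-bin histogram mixing sparse and smooth shapes."""
    kind = rng.integers(0, 3)
    if kind == 0:
        counts = rng.integers(0, 50, 256)
    elif kind == 1:  # unimodal peak + tail, the droplet-like shape
        x = np.arange(256)
        peak = rng.integers(5, 60)
        counts = (5000 * np.exp(-((x - peak) ** 2) / (2 * rng.uniform(3, 15) ** 2))).astype(int)
        counts[rng.integers(120, 256)] += rng.integers(1, 30)
    else:  # sparse
        counts = np.zeros(256, dtype=int)
        idx = rng.choice(256, size=rng.integers(2, 12), replace=False)
        counts[idx] = rng.integers(1, 100, idx.size)
    if np.count_nonzero(counts) < 2:
        counts[[10, 200]] = [5, 3]
    return IntensityHistogram(counts)


def triangle_oracle(hist):
    """Exhaustive point-to-chord search with explicit geometric distances."""
    h = hist.bin_counts.astype(float)
    nz = np.flatnonzero(h)
    peak = int(np.argmax(h))
    left, right = int(nz[0]), int(nz[-1])
    end = right if (right - peak) >= (peak - left) else left
    ax, ay, bx, by = peak, h[peak], end, h[end]
    chord = math.hypot(bx - ax, by - ay)
    best, best_d = None, -1.0
    for i in range(min(ax, bx), max(ax, bx) + 1):
        d = abs((bx - ax) * (ay - h[i]) - (ax - i) * (by - ay)) / chord
        if d > best_d + 1e-12:
            best_d, best = d, i
    return best


def renyi_order_oracle(hist, alpha):
    """Exhaustive per-order entropic-sum maximizer, written independently."""
    p = hist.bin_counts / hist.bin_counts.sum()
    nonzero = [i for i in range(256) if p[i] > 0]
    ents = {}
    cumulative = 0.0
    for t in range(256):
        cumulative += p[t]
        if not nonzero[0] <= t < nonzero[-1]:
            continue
        pb_mass, pf_mass = cumulative, 1.0 - cumulative
        back = [p[i] / pb_mass for i in range(t + 1) if p[i] > 0]
        fore = [p[i] / pf_mass for i in range(t + 1, 256) if p[i] > 0]
        if alpha == 1.0:
            ent = -sum(q * math.log(q) for q in back) - sum(
                q * math.log(q) for q in fore
            )
        else:
            ent = (
                math.log(sum(q**alpha for q in back))
                + math.log(sum(q**alpha for q in fore))
            ) / (1.0 - alpha)
        ents[t] = ent
    top = max(ents.values())
    # ties within float noise resolve to the lowest bin, the documented rule
    tol = 1e-10 * max(1.0, abs(top))
    return min(t for t, e in ents.items() if e >= top - tol)


def flood_fill_count(binary, connectivity=8):
    """Independent BFS flood-fill component count and total area."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    rows, cols = binary.shape
    for y in range(rows):
        for x in range(cols):
            if binary[y, x] and not seen[y, x]:
                q = deque([(y, x)])
                seen[y, x] = True
                size = 0
                while q:
                    cy, cx = q.popleft()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < rows and 0 <= nx < cols:
                            if binary[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                q.append((ny, nx))
                sizes.append(size)
    return sizes


class TestTriangleThreshold:
    def test_linear_decay_histogram_matches_brute_force(self):
        counts = np.zeros(256, dtype=int)
        counts[10:201] = np.linspace(1000, 1, 191).astype(int)
        hist = IntensityHistogram(counts)
        assert droplets.triangle_threshold(hist) == triangle_oracle(hist)

    def test_degenerate_single_bin_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[42] = 100
        with pytest.raises(DegenerateHistogramError):
            droplets.triangle_threshold(IntensityHistogram(counts))

    def test_matches_exhaustive_oracle_on_seeded_histograms(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            hist = random_histogram(rng)
            assert droplets.triangle_threshold(hist) == triangle_oracle(hist)

    def test_invariant_to_histogram_scaling(self):
        rng = np.random.default_rng(5)
        hist = random_histogram(rng)
        scaled = IntensityHistogram(hist.bin_counts * 7)
        assert droplets.triangle_threshold(hist) == droplets.triangle_threshold(scaled)

    def test_close_to_reference_implementation_on_droplet_like_image(self):
        # cross-check against scikit-image on an integer image whose
        # histogram bins align with ours (range 0..255)
        rng = np.random.default_rng(9)
        img = np.clip(rng.normal(40, 12, (128, 128)), 0, 255)
        img[20:40, 20:40] = 200
        img = np.round(img).astype(np.uint8)
        img.flat[:2] = (0, 255)  # pin the range so bins are integers
        hist = IntensityHistogram.from_pixels(img)
        t_bin = droplets.triangle_threshold(hist)
        width = (hist.intensity_max - hist.intensity_min) / 256
        t_intensity = hist.intensity_min + (t_bin + 1) * width
        assert abs(t_intensity - sk_triangle(img)) <= 5 * width


class TestRenyiEntropyThreshold:
    def test_per_order_maximizers_match_exhaustive_oracle(self):
        rng = np.random.default_rng(88)
        for _ in range(100):
            hist = random_histogram(rng)
            p = hist.bin_counts / hist.bin_counts.sum()
            for alpha in (0.5, 1.0, 2.0):
                got = droplets._renyi_entropy_maximizer(p, alpha)
                assert got == renyi_order_oracle(hist, alpha)

    def test_bimodal_threshold_lies_between_modes(self):
        counts = np.zeros(256, dtype=int)
        counts[20:31] = 500
        counts[200:211] = 400
        t = droplets.renyi_entropy_threshold(IntensityHistogram(counts))
        # foreground is strictly above the threshold bin, so the split
        # separates the modes when low-mode bins <= t < high-mode bins
        assert 30 <= t < 200

    def test_uniform_histogram_combination_rule(self):
        # all three per-order maximizers coincide at the middle bin, the
        # spacing weight w is zero, and the rule returns that bin
        hist = IntensityHistogram(np.full(256, 10, dtype=int))
        assert droplets.renyi_entropy_threshold(hist) == 127

    def test_invariant_to_histogram_scaling(self):
        rng = np.random.default_rng(6)
        hist = random_histogram(rng)
        scaled = IntensityHistogram(hist.bin_counts * 13)
        assert droplets.renyi_entropy_threshold(hist) == droplets.renyi_entropy_threshold(
            scaled
        )

    def test_degenerate_single_bin_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = 9
        with pytest.raises(DegenerateHistogramError):
            droplets.renyi_entropy_threshold(IntensityHistogram(counts))


class TestSegmentDroplets:
    def _two_square_scene(self):
        img = np.zeros((64, 64))
        img[:4, :4] = 1e-3  # faint non-uniform background
        img[10:15, 10:15] = 200.0
        img[40:45, 40:45] = 200.0
        return img

    def test_bright_squares_on_dark_background(self):
        binary = droplets.segment_droplets(
            self._two_square_scene(), config=SegmentationConfig(method="triangle")
        )
        assert binary[0, 10:15, 10:15].all()
        assert binary[0, 40:45, 40:45].all()
        assert binary.sum() == 50

    def test_mask_removes_square_and_shrinks_analyzed_area(self):
        img = self._two_square_scene()
        mask = np.zeros_like(img)
        mask[35:50, 35:50] = 1
        cfg = SegmentationConfig(method="triangle")
        m = droplets.analyze_droplets(img, exclusion_mask=mask, config=cfg)
        assert m.count == 1
        assert m.total_area_px == 25
        assert m.analyzed_px == 64 * 64 - 15 * 15

    def test_fully_masked_input_rejected(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError, match="excluded"):
            droplets.segment_droplets(img, exclusion_mask=np.ones_like(img))

    def test_foreground_equals_independent_threshold_application(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            stack, _ = synthetic.gen_droplet_scene(
                synthetic.DropletSceneParams(
                    image_size=(96, 96), n_droplets=6, seed=int(rng.integers(1e6))
                )
            )
            binary = droplets.segment_droplets(
                stack, config=SegmentationConfig(method="triangle")
            )
            for z in range(stack.shape[0]):
                hist = IntensityHistogram.from_pixels(stack[z])
                t = triangle_oracle(hist)
                expected = hist.bin_of(stack[z]) > t
                assert np.array_equal(binary[z], expected)

    def test_constant_extra_slice_changes_only_analyzed_area(self):
        img = self._two_square_scene()
        cfg = SegmentationConfig(method="triangle")
        base = droplets.analyze_droplets(img, config=cfg)
        padded = np.stack([img, np.zeros_like(img)])
        extra = droplets.analyze_droplets(padded, config=cfg)
        assert extra.count == base.count
        assert extra.total_area_px == base.total_area_px
        assert extra.analyzed_px == 2 * base.analyzed_px


class TestDropletMetrics:
    def test_two_squares_give_textbook_metrics(self):
        binary = np.zeros((100, 100), dtype=bool)
        binary[5:10, 5:10] = True
        binary[50:55, 50:55] = True
        m = droplets.droplet_metrics(binary)
        assert m.count == 2
        assert m.fractional_area == 0.005
        assert m.mean_size_px == 25

    def test_empty_foreground(self):
        m = droplets.droplet_metrics(np.zeros((10, 10), dtype=bool))
        assert m.count == 0
        assert m.fractional_area == 0.0
        assert m.mean_size_px is None

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_blobs(self, connectivity):
        rng = np.random.default_rng(13)
        for _ in range(100):
            binary = rng.random((24, 24)) < 0.35
            cfg = SegmentationConfig(connectivity=connectivity)
            m = droplets.droplet_metrics(binary, cfg)
            sizes = flood_fill_count(binary, connectivity)
            assert m.count == len(sizes)
            assert m.total_area_px == sum(sizes)

    def test_min_area_filter_drops_small_components(self):
        binary = np.zeros((20, 20), dtype=bool)
        binary[1, 1] = True  # singleton
        binary[5:9, 5:9] = True  # 16 px
        cfg = SegmentationConfig(min_area_px=4)
        m = droplets.droplet_metrics(binary, cfg)
        assert m.count == 1
        assert m.total_area_px == 16

    def test_mean_size_is_exactly_total_area_over_count(self, rng):
        for _ in range(20):
            binary = rng.random((30, 30)) < 0.3
            m = droplets.droplet_metrics(binary)
            if m.count:
                assert m.mean_size_px == m.total_area_px / m.count


class TestSceneRecovery:
    def test_disk_count_and_size_recovered(self):
        cfg = SegmentationConfig(method="triangle", min_area_px=4)
        recovered = []
        sizes = []
        for seed in range(5):
            stack, truth = synthetic.gen_droplet_scene(
                synthetic.DropletSceneParams(seed=seed)
            )
            m = droplets.analyze_droplets(stack, config=cfg)
            recovered.append(m.count == truth["count"])
            sizes.append(m.mean_size_px)
            assert m.mean_size_px == m.total_area_px / m.count
        assert np.mean(recovered) >= 0.8
        assert abs(np.mean(sizes) - math.pi * 16) / (math.pi * 16) < 0.15
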