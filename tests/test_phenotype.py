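"""Descriptor correctness against independent oracles and invariances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosynth import fixtures as fx
from phenosynth import phenotype as ph


def brute_force_dft(points: np.ndarray) -> np.ndarray:
    """O(N^2) direct-summation DFT oracle for a(u)."""
    s = points[:, 0] + 1j * points[:, 1]
    n = len(s)
    out = np.empty(n, dtype=complex)
    for u in range(n):
        acc = 0.0 + 0.0j
        for k in range(n):
            acc += s[k] * np.exp(-2j * np.pi * k * u / n)
        out[u] = acc / n
    return out


def circle_contour(radius=50.0, center=(80.0, 90.0), n=128):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
    return ph.ContourSequence(points=pts)


class TestContourExtraction:
    def test_disc_contour_at_planted_radius(self, disc_sprite):
        contour = ph.extract_contour(disc_sprite, n_points=128)
        assert len(contour) == 128
        centroid = contour.points.mean(axis=0)
        radii = np.linalg.norm(contour.points - centroid, axis=1)
        # generator base radius is 0.33 * canvas
        assert np.all(np.abs(radii - 0.33 * 256) < 1.0)

    def test_square_perimeter_preserved_by_resampling(self):
        rgba = np.zeros((128, 128, 4), dtype=np.uint8)
        rgba[30:90, 30:90, 3] = 255
        rgba[30:90, 30:90, :3] = 120
        sprite = fx.Sprite(pixels=rgba, species_id="square")
        contour = ph.extract_contour(sprite, n_points=256)
        closed = np.vstack([contour.points, contour.points[:1]])
        perimeter = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        side = 60.0
        assert abs(perimeter - 4 * side) / (4 * side) < 0.02

    def test_empty_foreground_rejected(self):
        rgba = np.zeros((64, 64, 4), dtype=np.uint8)
        sprite = fx.Sprite(pixels=rgba, species_id="empty")
        with pytest.raises(ValueError, match="empty foreground"):
            ph.extract_contour(sprite)

    def test_multiple_components_warns_and_takes_largest(self):
        rgba = np.zeros((128, 128, 4), dtype=np.uint8)
        rgba[20:80, 20:80, 3] = 255  # large blob
        rgba[100:110, 100:110, 3] = 255  # small distractor
        sprite = fx.Sprite(pixels=rgba, species_id="multi")
        with pytest.warns(UserWarning, match="components"):
            contour = ph.extract_contour(sprite, 64)
        assert contour.points[:, 0].max() < 90


class TestShapeDescriptor:
    def test_disc_coefficients_centroid_and_radius(self):
        contour = circle_contour(radius=50.0, center=(80.0, 90.0))
        a = ph.fourier_coefficients(contour)
        assert abs(a[0]) == pytest.approx(abs(80 + 90j), rel=1e-9)
        assert abs(a[1]) == pytest.approx(50.0, rel=1e-9)
        assert np.max(np.abs(a[2:-1])) < 1e-9

    def test_fft_equals_brute_force_dft(self):
        rng = np.random.default_rng(0)
        for n in (64, 128, 256):
            t = 2 * np.pi * np.arange(n) / n
            pts = np.column_stack(
                [
                    100 + 40 * np.cos(t) + rng.normal(0, 2, n),
                    120 + 25 * np.sin(t) + rng.normal(0, 2, n),
                ]
            )
            contour = ph.ContourSequence(points=pts)
            fast = ph.fourier_coefficients(contour)
            slow = brute_force_dft(pts)
            assert np.max(np.abs(fast - slow)) < 1e-9

    def test_standard_mode_translation_invariance(self):
        contour = circle_contour()
        d0 = ph.shape_descriptor(contour, mode="standard").normalized
        shifted = ph.ContourSequence(points=contour.points + [37.0, -12.0])
        d1 = ph.shape_descriptor(shifted, mode="standard").normalized
        assert np.max(np.abs(d0 - d1)) < 1e-6

    def test_paper_mode_matches_literal_normalization(self):
        contour = circle_contour(radius=50.0, center=(80.0, 90.0))
        d = ph.shape_descriptor(contour, n_terms=16, mode="paper")
        a = ph.fourier_coefficients(contour)
        assert np.allclose(d.normalized, np.abs(a[:16] / a[0]))

    def test_paper_mode_centroid_at_origin_is_error(self):
        contour = circle_contour(radius=50.0, center=(0.0, 0.0))
        with pytest.raises(ValueError, match="centroid"):
            ph.shape_descriptor(contour, mode="paper")

    def test_ellipse_second_harmonic_matches_oracle(self):
        n = 128
        t = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([100 + 60 * np.cos(t), 100 + 30 * np.sin(t)])
        contour = ph.ContourSequence(points=pts)
        d = ph.shape_descriptor(contour, n_terms=16, mode="standard")
        slow = brute_force_dft(pts)
        expected = np.abs(slow[2:18]) / np.abs(slow[1])
        assert np.max(np.abs(d.normalized - expected)) < 1e-9


class TestShapeDistance:
    def test_identical_zero_and_affine_map_zero(self):
        contour = circle_contour()
        rng = np.random.default_rng(1)
        wobbly = ph.ContourSequence(
            points=contour.points + rng.normal(0, 1.5, contour.points.shape)
        )
        d1 = ph.shape_descriptor(wobbly, mode="standard")
        assert ph.shape_distance(d1, d1) == pytest.approx(0.0, abs=1e-12)
        d2 = ph.ShapeDescriptor(
            coefficients=d1.coefficients,
            normalized=3.0 * d1.normalized + 0.7,
            mode="standard",
            n_terms=d1.n_terms,
        )
        assert ph.shape_distance(d1, d2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_pearson_arithmetic(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.3, 0.8, 0.4, 0.7,
                      0.15, 0.55, 0.25, 0.95, 0.35, 0.85, 0.45, 0.75])
        y = np.array([0.3, 0.1, 0.6, 0.2, 0.9, 0.4, 0.8, 0.5,
                      0.35, 0.15, 0.65, 0.25, 0.95, 0.45, 0.85, 0.55])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        rho = cov / (x.std() * y.std())
        assert ph.pearson_distance(x, y) == pytest.approx(1 - rho, abs=1e-12)

    def test_zero_variance_convention(self):
        const = np.full(16, 0.5)
        other = np.linspace(0, 1, 16)
        assert ph.pearson_distance(const, const.copy()) == 0.0
        assert ph.pearson_distance(const, other) == 2.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=8, max_size=8),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=8, max_size=8),
    )
    def test_range_and_symmetry(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        d = ph.pearson_distance(x, y)
        assert -1e-9 <= d <= 2 + 1e-9
        assert d == pytest.approx(ph.pearson_distance(y, x), abs=1e-12)


class TestColorDescriptor:
    def test_uniform_sprite_exact_mean_zero_variance(self):
        rgba = np.zeros((64, 64, 4), dtype=np.uint8)
        rgba[16:48, 16:48] = (200, 60, 60, 255)
        sprite = fx.Sprite(pixels=rgba, species_id="uniform")
        desc = ph.color_descriptor(sprite)
        from skimage import color as skcolor

        expected = skcolor.rgb2lab(
            np.array([[[200 / 255, 60 / 255, 60 / 255]]])
        )[0, 0]
        assert np.allclose(desc.lab_means, expected, atol=1e-9)
        assert np.allclose(desc.lab_vars, 0.0, atol=1e-12)

    def test_rates_sum_to_one(self, demo_sprites):
        for sprite in demo_sprites[:4]:
            desc = ph.color_descriptor(sprite)
            for rate in desc.rates:
                assert rate.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_level_lightness_weighted_mean(self):
        # half the foreground at L=20, half at L=80: weighted mean L = 50
        from skimage import color as skcolor

        rgb20 = np.clip(skcolor.lab2rgb(np.array([[[20.0, 0.0, 0.0]]])), 0, 1)
        rgb80 = np.clip(skcolor.lab2rgb(np.array([[[80.0, 0.0, 0.0]]])), 0, 1)
        rgba = np.zeros((64, 64, 4), dtype=np.uint8)
        rgba[16:48, 16:32, :3] = np.round(rgb20 * 255)
        rgba[16:48, 32:48, :3] = np.round(rgb80 * 255)
        rgba[16:48, 16:48, 3] = 255
        sprite = fx.Sprite(pixels=rgba, species_id="two")
        desc = ph.color_descriptor(sprite)
        l20 = skcolor.rgb2lab(np.round(rgb20 * 255) / 255.0)[0, 0, 0]
        l80 = skcolor.rgb2lab(np.round(rgb80 * 255) / 255.0)[0, 0, 0]
        assert desc.lab_means[0] == pytest.approx(0.5 * l20 + 0.5 * l80, abs=1e-9)
        assert desc.rates[0][np.nonzero(desc.rates[0])] == pytest.approx(0.5)

    def test_distance_is_euclidean_345(self):
        d1 = ph.ColorDescriptor(
            lab_means=np.array([50.0, 0.0, 0.0]), lab_vars=np.zeros(3),
            bin_width=20.0, rates=[], interval_means=[],
        )
        d2 = ph.ColorDescriptor(
            lab_means=np.array([50.0, 3.0, 4.0]), lab_vars=np.zeros(3),
            bin_width=20.0, rates=[], interval_means=[],
        )
        assert ph.color_distance(d1, d2) == pytest.approx(5.0, abs=1e-12)
        assert ph.color_distance(d2, d1) == ph.color_distance(d1, d2)


class TestTexture:
    def test_patches_inside_foreground_and_deterministic(self, disc_sprite):
        patches_a = ph.sample_texture_patches(disc_sprite, 8, 32, seed=4)
        patches_b = ph.sample_texture_patches(disc_sprite, 8, 32, seed=4)
        mask = disc_sprite.mask
        for pa, pb in zip(patches_a, patches_b):
            assert np.array_equal(pa, pb)
        # coverage contract via the exhaustive position oracle
        positions = ph.valid_patch_positions(disc_sprite, 32)
        p = 32
        for r, c in positions:
            assert mask[r : r + p, c : c + p].mean() >= 0.95

    def test_valid_positions_match_brute_force_enumeration(self):
        rgba = np.zeros((256, 256, 4), dtype=np.uint8)
        yy, xx = np.mgrid[0:256, 0:256]
        disc = (yy - 128) ** 2 + (xx - 128) ** 2 <= 100**2
        rgba[..., 3] = np.where(disc, 255, 0)
        rgba[..., 0] = 128
        sprite = fx.Sprite(pixels=rgba, species_id="disc100")
        fast = ph.valid_patch_positions(sprite, 32)
        mask = sprite.mask
        slow = [
            (r, c)
            for r in range(256 - 32 + 1)
            for c in range(256 - 32 + 1)
            if mask[r : r + 32, c : c + 32].sum() >= 0.95 * 32 * 32
        ]
        assert sorted(map(tuple, fast)) == slow

    def test_no_valid_position_raises(self):
        rgba = np.zeros((64, 64, 4), dtype=np.uint8)
        rgba[20:50, 20:50, 3] = 255
        sprite = fx.Sprite(pixels=rgba, species_id="small")
        with pytest.raises(ValueError, match="patch_size"):
            ph.sample_texture_patches(sprite, 4, 48)

    def test_constant_patch_single_bin(self):
        patch = np.full((32, 32), 77, dtype=np.uint8)
        desc = ph.texture_descriptor([patch])
        hist = desc.aggregate
        assert hist.max() == pytest.approx(1.0, abs=1e-12)
        assert hist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rotation_invariance_of_histogram(self, disc_sprite):
        patches = ph.sample_texture_patches(disc_sprite, 4, 32, seed=0)
        for patch in patches:
            h0 = ph.texture_descriptor([patch]).aggregate
            h90 = ph.texture_descriptor([np.rot90(patch)]).aggregate
            assert np.abs(h0 - h90).sum() < 0.05

    def test_distance_oracle_and_histogram_normalization(self, demo_sprites):
        pa = ph.sample_texture_patches(demo_sprites[0], 8, 32, seed=1)
        pb = ph.sample_texture_patches(demo_sprites[-1], 8, 32, seed=2)
        ta, tb = ph.texture_descriptor(pa), ph.texture_descriptor(pb)
        for hist in (*ta.patch_histograms, *tb.patch_histograms):
            assert hist.sum() == pytest.approx(1.0, abs=1e-12)
        x, y = ta.aggregate, tb.aggregate
        rho = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert ph.texture_distance(ta, tb) == pytest.approx(1 - rho, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_sprites_zero_matrix(self, disc_sprite):
        twin = fx.Sprite(pixels=disc_sprite.pixels.copy(), species_id="disc")
        m = ph.build_distance_matrix([disc_sprite, twin], "color")
        assert np.allclose(m.values, 0.0)

    @pytest.mark.parametrize("feature", ["shape", "color", "texture"])
    def test_symmetry_zero_diagonal_nonnegative(self, demo_sprites, feature):
        m = ph.build_distance_matrix(demo_sprites[:6], feature, seed=2)
        m.validate()

    def test_dataset_level_equals_mean_of_cross_pairs(self, demo_sprites):
        sprites = [s for s in demo_sprites if s.species_id in ("species_0", "species_1")][:6]
        assert len(sprites) == 6  # 3 + 3
        img = ph.build_distance_matrix(sprites, "color", level="image")
        ds = ph.build_distance_matrix(sprites, "color", level="dataset")
        idx_a = [i for i, s in enumerate(sprites) if s.species_id == "species_0"]
        idx_b = [i for i, s in enumerate(sprites) if s.species_id == "species_1"]
        oracle = np.mean([img.values[i, j] for i in idx_a for j in idx_b])
        assert ds.values[0, 1] == pytest.approx(oracle, abs=1e-12)


class TestStandardModeInvariances:
    """Invariance of the standard descriptor under similarity transforms."""

    def test_invariance_under_similarity_and_start_shift(self, demo_sprites):
        angles = np.linspace(0, 2 * np.pi, 7, endpoint=False)[1:]
        for sprite in demo_sprites[:3]:
            contour = ph.extract_contour(sprite)
            ref = ph.shape_descriptor(contour, mode="standard").normalized
            pts = contour.points
            for angle in angles:
                rot = np.array(
                    [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
                )
                moved = ph.ContourSequence(points=pts @ rot.T + [13.0, -8.0])
                d = ph.shape_descriptor(moved, mode="standard").normalized
                assert np.max(np.abs(d - ref)) < 1e-6
            for scale in (0.5, 2.0):
                d = ph.shape_descriptor(
                    ph.ContourSequence(points=pts * scale), mode="standard"
                ).normalized
                assert np.max(np.abs(d - ref)) < 1e-6
            shifted = ph.ContourSequence(points=np.roll(pts, 17, axis=0))
            d = ph.shape_descriptor(shifted, mode="standard").normalized
            assert np.max(np.abs(d - ref)) < 1e-6
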