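"""Image-quantification operations: thresholding, particles, classification,
lower-half integration, depth projections, ramped-threshold optimum and the
PI/H2B death ratio — each against an independent oracle where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from organoidquant.imaging import (
    ImageStack,
    binarize_channel,
    classify_particles,
    depth_coded_projection,
    find_particles,
    masks_from_labels,
    pi_h2b_death_ratio,
    quantify_lower_half,
    ramp_threshold_optimum,
)
from organoidquant.synthgen import OrganoidSimParams, make_organoid_stack

from conftest import flood_fill_components, midpoint_threshold


def _stack_from(arr, **kw):
    return ImageStack(data=np.asarray(arr), axes="ZYX", **kw)


class TestBinarize:
    def test_threshold_above_constant_gives_empty_mask(self):
        stack = _stack_from(np.full((2, 4, 4), 50.0))
        assert binarize_channel(stack, "H2B", 51).pixel_count == 0

    def test_threshold_is_inclusive(self):
        stack = _stack_from(np.full((2, 4, 4), 50.0))
        assert binarize_channel(stack, "H2B", 50).pixel_count == 2 * 4 * 4

    def test_midpoint_threshold_recovers_truth_foreground(self, small_stack):
        params, stack, truth = small_stack
        mask = binarize_channel(stack, "H2B", midpoint_threshold(params))
        assert mask.pixel_count == truth.foreground_voxel_count()

    def test_unknown_channel_rejected(self, small_stack):
        _, stack, _ = small_stack
        with pytest.raises(KeyError):
            binarize_channel(stack, "DAPI", 100)


class TestParticles:
    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, 1, 1] = mask[0, 2, 2] = True
        assert len(find_particles(mask, "slice2d", connectivity=8)) == 1
        assert len(find_particles(mask, "slice2d", connectivity=4)) == 2

    def test_empty_mask_gives_empty_set(self):
        assert len(find_particles(np.zeros((2, 4, 4), dtype=bool), "slice2d")) == 0

    def test_invalid_connectivity_rejected(self):
        mask = np.zeros((1, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            find_particles(mask, "slice2d", connectivity=6)
        with pytest.raises(ValueError):
            find_particles(mask, "volume3d", connectivity=8)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_per_slice_counts_match_flood_fill_oracle(self, connectivity, small_stack):
        params, stack, _ = small_stack
        mask = binarize_channel(stack, "H2B", midpoint_threshold(params)).mask
        particles = find_particles(mask, "slice2d", connectivity=connectivity)
        for zi in range(mask.shape[0]):
            oracle = flood_fill_components(mask[zi], connectivity)
            got = particles.particles[particles.particles["slice"] == zi]
            assert len(got) == len(oracle)
            assert sorted(got["n_px"]) == sorted(len(c) for c in oracle)

    def test_random_masks_match_flood_fill_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            mask = rng.random((1, 12, 12)) < 0.35
            particles = find_particles(mask, "slice2d", connectivity=8)
            oracle = flood_fill_components(mask[0], 8)
            assert sorted(particles.particles["n_px"]) == sorted(len(c) for c in oracle)


class TestClassify:
    def test_boundary_particle_is_alive(self):
        mask = np.zeros((1, 8, 20), dtype=bool)
        mask[0, 2:4, 0:5] = True  # 10 px
        mask[0, 5:8, 8:11] = True  # 9 px
        classified = classify_particles(find_particles(mask, "slice2d"), 10)
        labels = classified.particles.sort_values("n_px")["label"].tolist()
        assert labels == ["dead", "alive"]

    def test_masks_partition_the_foreground(self, small_stack):
        params, stack, _ = small_stack
        mask = binarize_channel(stack, "H2B", midpoint_threshold(params))
        classified = classify_particles(find_particles(mask, "volume3d"), 100)
        alive, dead = masks_from_labels(classified, mask.mask.shape)
        assert not (alive & dead).any()
        assert (alive | dead).sum() == mask.pixel_count


class TestLowerHalf:
    def test_foreground_confined_to_lower_half_is_fully_counted(self):
        alive = np.zeros((10, 6, 6), dtype=bool)
        alive[0:5, 2:4, 2:4] = True
        dead = np.zeros_like(alive)
        quant = quantify_lower_half(alive, dead, (0, 9))
        assert quant.alive_px == alive.sum()
        assert quant.z_range == (0, 4)

    def test_symmetric_organoid_splits_in_half(self):
        alive = np.zeros((10, 4, 4), dtype=bool)
        alive[2:8, 1:3, 1:3] = True  # symmetric over slices 2..7
        quant = quantify_lower_half(alive, np.zeros_like(alive), (2, 7))
        assert quant.alive_px == alive.sum() // 2

    def test_partition_identity_any_input(self):
        rng = np.random.default_rng(0)
        fg = rng.random((8, 10, 10)) < 0.3
        split = rng.random((8, 10, 10)) < 0.5
        alive, dead = fg & split, fg & ~split
        quant = quantify_lower_half(alive, dead, (1, 6))
        n_lower = (6 - 1 + 1) // 2
        assert quant.total_px == fg[1 : 1 + n_lower].sum()

    def test_extent_outside_stack_rejected(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            quantify_lower_half(m, m, (0, 7))


class TestDepthProjection:
    def test_single_plane_projects_to_itself(self):
        rng = np.random.default_rng(1)
        plane = rng.integers(0, 1000, (1, 16, 16)).astype(float)
        rgb = depth_coded_projection(plane, lut="turbo")
        norm = (plane[0] - plane[0].min()) / (plane[0].max() - plane[0].min())
        import matplotlib

        expected = matplotlib.colormaps["turbo"](np.zeros((16, 16)))[..., :3]
        assert np.allclose(rgb, expected * norm[..., None])

    def test_projection_matches_brute_force_max(self):
        from matplotlib.colors import ListedColormap

        white = ListedColormap([[1.0, 1.0, 1.0]])  # hue-free: channels = intensity
        rng = np.random.default_rng(2)
        for _ in range(100):
            vol = rng.integers(0, 500, (5, 8, 8)).astype(float)
            rgb = depth_coded_projection(vol, lut=white)
            brute = np.empty((8, 8))
            for y in range(8):
                for x in range(8):
                    brute[y, x] = max(vol[z, y, x] for z in range(5))
            norm = (brute - brute.min()) / (brute.max() - brute.min())
            assert np.allclose(rgb[..., 0], norm)

    def test_argmax_tie_resolves_to_lowest_z(self):
        rng = np.random.default_rng(5)
        plane = rng.integers(1, 100, (6, 6)).astype(float)
        vol = np.stack([plane, plane])  # two identical planes: every pixel ties
        rgb = depth_coded_projection(vol, lut="turbo")
        import matplotlib

        lut0 = np.array(matplotlib.colormaps["turbo"](0.0)[:3])
        norm = (plane - plane.min()) / (plane.max() - plane.min())
        assert np.allclose(rgb, lut0[None, None, :] * norm[..., None])


class TestRampThreshold:
    def test_two_level_image_recovers_foreground_exactly(self):
        img = np.full((10, 100), 10.0)
        img[:, :10] = 200.0  # 10% foreground
        scan = ramp_threshold_optimum(img, np.linspace(0, 200, 40))
        assert 10 < scan.optimum <= 200
        assert np.array_equal(img >= scan.optimum, img == 200.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            ramp_threshold_optimum(np.full((5, 5), 3.0))

    def test_optimum_equals_brute_force_argmax_of_score(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            img = np.concatenate(
                [rng.normal(100, 10, 400), rng.normal(400, 40, 100)]
            ).reshape(25, 20)
            grid = np.linspace(img.min(), img.max(), 50)
            scan = ramp_threshold_optimum(img, grid)
            # independent evaluation of the stated score
            area = np.array([(img >= T).sum() for T in grid], dtype=float)
            mean = np.array([img[img >= T].mean() for T in grid])
            na = (area - area.min()) / (area.max() - area.min())
            nm = (mean - mean.min()) / (mean.max() - mean.min())
            score = np.where(area > 0, nm - na, -np.inf)
            assert scan.optimum == grid[int(np.argmax(score))]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (40,), elements=st.floats(0, 1000, allow_nan=False))
    )
    def test_area_monotone_decreasing_mean_monotone_increasing(self, img):
        if np.ptp(img) < 1e-6:
            return
        scan = ramp_threshold_optimum(img, np.linspace(img.min(), img.max(), 10))
        assert np.all(np.diff(scan.area) <= 0)
        valid = scan.area > 0
        assert np.all(np.diff(scan.mean_intensity[valid]) >= -1e-9)


class TestDeathRatio:
    def test_pi_below_threshold_gives_zero(self):
        data = np.stack(
            [np.full((4, 8, 8), 500.0), np.full((4, 8, 8), 10.0)], axis=1
        )
        stack = ImageStack(data=data, axes="ZCYX", channel_names=("H2B", "PI"))
        ratio = pi_h2b_death_ratio(stack, t_h2b=100, t_pi=100)
        assert ratio.ratio == 0.0

    def test_ratio_matches_true_dead_voxel_fraction(self, small_stack):
        params, stack, truth = small_stack
        thr = midpoint_threshold(params)
        ratio = pi_h2b_death_ratio(stack, thr, thr)
        assert ratio.ratio == pytest.approx(truth.dead_voxel_fraction(), abs=0.05)

    def test_ratio_invariant_under_duplicating_the_field(self, small_stack):
        params, stack, _ = small_stack
        thr = midpoint_threshold(params)
        doubled = ImageStack(
            data=np.concatenate([stack.data, stack.data], axis=0),
            axes=stack.axes,
            channel_names=stack.channel_names,
        )
        r1 = pi_h2b_death_ratio(stack, thr, thr)
        r2 = pi_h2b_death_ratio(doubled, thr, thr)
        assert r2.ratio == pytest.approx(r1.ratio, abs=1e-12)
        assert r2.h2b_px == 2 * r1.h2b_px

    def test_empty_h2b_surface_rejected(self):
        data = np.stack([np.zeros((2, 4, 4)), np.zeros((2, 4, 4))], axis=1)
        stack = ImageStack(data=data, axes="ZCYX", channel_names=("H2B", "PI"))
        with pytest.raises(ValueError):
            pi_h2b_death_ratio(stack, t_h2b=10, t_pi=10)


class TestStackIO:
    def test_tiff_roundtrip_preserves_voxels_and_metadata(self, tmp_path, small_stack):
        _, stack, _ = small_stack
        path = tmp_path / "stack.tiff"
        stack.save_tiff(path)
        loaded = ImageStack.load_tiff(path)
        assert np.array_equal(loaded.data, stack.data)
        assert loaded.axes == stack.axes
        assert loaded.channel_names == stack.channel_names
        assert loaded.z_step_um == stack.z_step_um
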