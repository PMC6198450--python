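import numpy as np
import pytest

from conftest import COARSE_VOXEL
from repkin.imaging_coloc import (
    ImageStack,
    classify_sphase,
    coloc_profile,
    dna_content_stage,
    h_coefficient,
    local_mean_subtract,
    nuclear_mask,
    pearson_coloc,
    select_midplane,
)
from repkin.synthetic import ImageSimSpec, simulate_image


def ellipsoid_image(semi_axes=(3.0, 5.0, 5.0), voxel=COARSE_VOXEL, level=100.0):
    spec = ImageSimSpec(
        semi_axes=semi_axes, voxel_size=voxel, pattern=None, foci_count=0,
        noise=False, dna_level=level, background=0.0,
    )
    stack, truth = simulate_image(spec)
    return stack.channels["DNA"], truth


class TestNuclearMask:
    def test_ellipsoid_volume_recovered(self):
        # semi-axes (3, 5, 5) um -> analytic volume (4/3) * pi * 75 um^3
        dna, _ = ellipsoid_image()
        # dilation is a recall step for downstream inclusion tests; volume
        # accuracy of threshold + voxelization is measured without it
        nm = nuclear_mask(dna, COARSE_VOXEL, min_volume=100.0, dilate_iterations=0)
        assert nm.n_regions == 1
        analytic = 4.0 / 3.0 * np.pi * 75.0
        assert nm.volumes[1] == pytest.approx(analytic, rel=0.10)
        dilated = nuclear_mask(dna, COARSE_VOXEL, min_volume=100.0)
        assert dilated.volumes[1] > nm.volumes[1]

    def test_all_zero_image_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="no nuclear region"):
            nm = nuclear_mask(np.zeros((10, 20, 20)), COARSE_VOXEL)
        assert nm.n_regions == 0

    def test_min_volume_filter_removes_small_objects(self):
        dna, _ = ellipsoid_image()
        with pytest.warns(UserWarning, match="no nuclear region"):
            nm = nuclear_mask(dna, COARSE_VOXEL, min_volume=1_000.0)
        assert nm.n_regions == 0

    def test_two_separated_nuclei_get_two_labels(self):
        dna, _ = ellipsoid_image()
        pad = np.zeros_like(dna)
        two = np.concatenate([dna, pad, dna], axis=2)
        nm = nuclear_mask(two, COARSE_VOXEL, min_volume=100.0)
        assert nm.n_regions == 2
        assert nm.volumes[1] == pytest.approx(nm.volumes[2], rel=0.01)


class TestLocalMeanSubtract:
    def test_constant_image_becomes_zero(self):
        out = local_mean_subtract(np.full((3, 40, 40), 7.0), radius_px=5)
        assert np.allclose(out, 0.0)

    def test_single_bright_voxel_leaves_positive_residual(self):
        img = np.zeros((1, 41, 41))
        img[0, 20, 20] = 100.0
        out = local_mean_subtract(img, radius_px=5)
        assert out[0, 20, 20] > 90.0

    def test_gradient_removed_foci_retained(self, rng):
        """Planted foci on a smooth gradient: the filter keeps nearly all
        focal intensity while removing nearly all of the gradient."""
        shape = (3, 120, 120)
        yy = np.linspace(0, 50, shape[1])[None, :, None]
        gradient = np.broadcast_to(yy, shape).copy()
        foci = np.zeros(shape)
        for _ in range(15):
            z, y, x = 1, int(rng.integers(10, 110)), int(rng.integers(10, 110))
            foci[z, y, x] = 500.0
        out_g = local_mean_subtract(gradient, radius_px=10)
        out_f = local_mean_subtract(gradient + foci, radius_px=10) - out_g
        assert out_g.sum() <= 0.05 * gradient.sum()
        assert out_f.sum() >= 0.95 * foci.sum() * 0.95  # small window leakage


class TestColocCoefficients:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.mask = np.ones((1, 100, 100), dtype=bool)
        self.ch = rng.uniform(1, 10, size=(1, 100, 100))

    def test_pearson_self_and_complement(self):
        assert pearson_coloc(self.ch, self.ch, self.mask, 0).value == pytest.approx(1.0)
        assert pearson_coloc(self.ch, 11.0 - self.ch, self.mask, 0).value == (
            pytest.approx(-1.0)
        )

    def test_pearson_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        other = rng.uniform(1, 10, size=self.ch.shape)
        r = pearson_coloc(self.ch, other, self.mask, 0).value
        assert abs(r) < 3.0 / np.sqrt(self.mask.sum())

    def test_pearson_constant_channel_missing(self):
        r = pearson_coloc(self.ch, np.ones_like(self.ch), self.mask, 0)
        assert np.isnan(r.value) and r.reason == "constant_channel"

    def test_h_binary_self_product(self):
        """Identical binary channels with value 2 on half the voxels:
        H = mean(I^2) / mean(I)^2 = 2 / 1 = 2."""
        ch = np.zeros((1, 10, 10))
        ch[0, :5, :] = 2.0
        h = h_coefficient(ch, ch, np.ones_like(ch, bool), 0)
        assert h.value == pytest.approx(2.0)

    def test_h_permutation_null_is_one(self):
        rng = np.random.default_rng(9)
        perm = rng.permutation(self.ch.ravel()).reshape(self.ch.shape)
        h = h_coefficient(self.ch, perm, self.mask, 0).value
        # permutation null: sd of H estimated from the channel moments
        n = self.ch.size
        cv2 = (self.ch.std() / self.ch.mean()) ** 2
        assert abs(h - 1.0) < 3 * np.sqrt(cv2 * cv2 / n) + 3e-3

    def test_h_disjoint_supports_is_zero(self):
        a = np.zeros((1, 10, 10))
        b = np.zeros((1, 10, 10))
        a[0, :5], b[0, 5:] = 3.0, 4.0
        assert h_coefficient(a, b, np.ones_like(a, bool), 0).value == 0.0

    def test_h_zero_mean_missing(self):
        z = np.zeros((1, 5, 5))
        h = h_coefficient(z, z, np.ones_like(z, bool), 0)
        assert np.isnan(h.value) and h.reason == "zero_mean"

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        other = self.ch * 0.5 + rng.uniform(0, 5, self.ch.shape)
        h0 = h_coefficient(self.ch, other, self.mask, 0).value
        r0 = pearson_coloc(self.ch, other, self.mask, 0).value
        assert h_coefficient(3.7 * self.ch, other, self.mask, 0).value == (
            pytest.approx(h0)
        )
        assert pearson_coloc(self.ch, 9.1 * other, self.mask, 0).value == (
            pytest.approx(r0)
        )


class TestMidplane:
    def test_symmetric_nucleus_selects_central_plane(self):
        dna, truth = ellipsoid_image()
        mid = select_midplane(dna, truth["nucleus_mask"])
        assert abs(mid - dna.shape[0] // 2) <= 1

    def test_single_plane_stack(self):
        img = np.ones((1, 10, 10))
        assert select_midplane(img, np.ones_like(img, bool)) == 0

    def test_planted_brightest_plane_selected(self):
        img = np.ones((9, 10, 10))
        img[6] = 50.0
        assert select_midplane(img, np.ones_like(img, bool)) == 6

    def test_tie_breaks_to_lower_index(self):
        img = np.ones((4, 5, 5))
        assert select_midplane(img, np.ones_like(img, bool)) == 0


class TestMixingMonotonicity:
    def test_h_and_r_nondecreasing_in_alpha(self):
        """FISH = alpha * EdU + (1 - alpha) * independent: both mid-plane
        coefficients rise monotonically with the planted mixing."""
        hs, rs = [], []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = ImageSimSpec(
                pattern="early", coloc_alpha=alpha, voxel_size=COARSE_VOXEL, seed=11
            )
            stack, _ = simulate_image(spec)
            nm = nuclear_mask(stack.channels["DNA"], COARSE_VOXEL)
            edu = local_mean_subtract(stack.channels["EdU"], 4)
            fish = local_mean_subtract(stack.channels["FISH"], 4)
            res = coloc_profile(edu, fish, nm.any_mask, stack.channels["DNA"])
            hs.append(res.mid_h)
            rs.append(res.mid_pearson)
        assert all(b >= a - 0.02 for a, b in zip(hs, hs[1:]))
        assert all(b >= a - 0.02 for a, b in zip(rs, rs[1:]))
        assert hs[-1] > 2.0 and rs[-1] > 0.9

    def test_independent_channels_pearson_near_zero(self):
        spec = ImageSimSpec(
            pattern="early", coloc_alpha=0.0, voxel_size=COARSE_VOXEL, seed=12
        )
        stack, _ = simulate_image(spec)
        nm = nuclear_mask(stack.channels["DNA"], COARSE_VOXEL)
        edu = local_mean_subtract(stack.channels["EdU"], 4)
        fish = local_mean_subtract(stack.channels["FISH"], 4)
        res = coloc_profile(edu, fish, nm.any_mask, stack.channels["DNA"])
        # no planted mixing: correlation stays near zero (H itself is
        # heavy-tailed on sparse focal signals, tested cohort-wise elsewhere)
        assert abs(res.mid_pearson) < 0.15


class TestReplicationTimingOrdering:
    def test_planted_probe_gives_highest_h_in_its_substage(self):
        """An Alu-like probe (planted to colocalize with early-pattern EdU)
        scores higher H in early cells than a satIII-like probe planted to
        colocalize with the late pattern, and vice versa."""

        def mid_h(pattern, alpha, seed):
            spec = ImageSimSpec(
                pattern=pattern, coloc_alpha=alpha, voxel_size=COARSE_VOXEL,
                seed=seed,
            )
            stack, _ = simulate_image(spec)
            nm = nuclear_mask(stack.channels["DNA"], COARSE_VOXEL)
            edu = local_mean_subtract(stack.channels["EdU"], 4)
            fish = local_mean_subtract(stack.channels["FISH"], 4)
            res = coloc_profile(edu, fish, nm.any_mask, stack.channels["DNA"])
            return np.nanmean([p.value for p in res.h])

        # Alu-like: strong mixing with the early pattern, weak with late
        assert mid_h("early", 0.9, 51) > mid_h("late", 0.1, 52)
        # satIII-like: strong mixing with the late pattern, weak with early
        assert mid_h("late", 0.9, 53) > mid_h("early", 0.1, 54)


class TestSPhase:
    @pytest.mark.parametrize("pattern", ["early", "mid", "late"])
    def test_generator_pattern_recovered(self, pattern):
        spec = ImageSimSpec(pattern=pattern, voxel_size=COARSE_VOXEL, seed=21)
        stack, _ = simulate_image(spec)
        nm = nuclear_mask(stack.channels["DNA"], COARSE_VOXEL)
        edu = local_mean_subtract(stack.channels["EdU"], 4)
        call = classify_sphase(edu, nm.any_mask, COARSE_VOXEL)
        assert call.label == pattern

    def test_zero_edu_is_non_s(self):
        spec = ImageSimSpec(pattern=None, voxel_size=COARSE_VOXEL, seed=22)
        stack, _ = simulate_image(spec)
        nm = nuclear_mask(stack.channels["DNA"], COARSE_VOXEL)
        edu = local_mean_subtract(stack.channels["EdU"], 4)
        call = classify_sphase(edu, nm.any_mask, COARSE_VOXEL)
        assert call.label == "non-S"


class TestDnaContentStage:
    def test_two_populations_split(self, rng):
        n = 40
        dapi = np.concatenate([rng.normal(100, 5, n), rng.normal(200, 10, n)])
        vol = np.concatenate([rng.normal(500, 20, n), rng.normal(800, 30, n)])
        edu = np.zeros(2 * n, dtype=bool)
        stages = dna_content_stage(dapi, vol, edu)
        assert (stages[:n] == "G1").all()
        assert (stages[n:] == "G2").all()

    def test_all_edu_positive_all_s(self):
        stages = dna_content_stage([1, 2, 3], [1, 2, 3], [True, True, True])
        assert (stages == "S").all()

    def test_single_negative_cell_goes_to_g1(self):
        with pytest.warns(UserWarning, match="single EdU-negative"):
            stages = dna_content_stage([100, 150], [500, 600], [True, False])
        assert list(stages) == ["S", "G1"]

    def test_s_cells_between_g1_and_g2_in_content(self, rng):
        """Replicating cells have intermediate DNA content by construction."""
        g1 = rng.normal(100, 5, 30)
        g2 = rng.normal(200, 5, 30)
        s = rng.uniform(110, 190, 30)
        dapi = np.concatenate([g1, s, g2])
        vol = dapi * 5
        edu = np.concatenate([np.zeros(30), np.ones(30), np.zeros(30)]).astype(bool)
        stages = dna_content_stage(dapi, vol, edu)
        assert dapi[stages == "G1"].mean() < dapi[stages == "S"].mean()
        assert dapi[stages == "S"].mean() < dapi[stages == "G2"].mean()


class TestImageStackValidation:
    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ImageStack({"a": np.zeros((2, 3, 3)), "b": np.zeros((2, 4, 4))})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ImageStack({"a": np.full((1, 2, 2), -1.0)})
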