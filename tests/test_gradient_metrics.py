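from dataclasses import replace

import numpy as np
import pytest

from mitograd import gradient_metrics as gm
from mitograd import synthetic as syn

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-sigma Gaussian


# --------------------------------------------------------------------------
# brute-force morphology oracle: erosion/dilation by explicit set translation

def brute_erode(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.ones_like(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return out


def brute_dilate(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.zeros_like(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out |= padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return out


def _disk_image(radius=10, n=40, value=1000.0):
    yy, xx = np.mgrid[:n, :n]
    img = np.zeros((n, n))
    img[(yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2] = value
    return img


class TestReferenceMasks:
    def test_disk_matches_brute_force_morphology(self):
        img = _disk_image()
        masks = gm.reference_masks(img)
        whole = img > masks.threshold
        np.testing.assert_array_equal(masks.core, brute_erode(whole))
        np.testing.assert_array_equal(
            masks.rim, brute_dilate(brute_dilate(whole)) & ~brute_erode(whole)
        )
        # the rim is a hollow annulus: it never touches the object's center
        c = img.shape[0] // 2
        assert masks.core[c, c] and not masks.rim[c, c]

    def test_random_images_match_brute_force(self):
        """Pixel-exact agreement with set-translation erosion/dilation on
        random binary fields."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            img = (rng.random((64, 64)) < 0.45).astype(float) * 800.0
            img += rng.uniform(0, 1, img.shape)  # break Otsu ties
            try:
                masks = gm.reference_masks(img)
            except ValueError:
                continue
            whole = img > masks.threshold
            np.testing.assert_array_equal(masks.core, brute_erode(whole))
            np.testing.assert_array_equal(
                masks.rim, brute_dilate(brute_dilate(whole)) & ~brute_erode(whole)
            )

    def test_otsu_scale_invariance(self):
        img = _disk_image()
        a = gm.reference_masks(img)
        b = gm.reference_masks(img * 3.0)
        np.testing.assert_array_equal(a.whole, b.whole)
        np.testing.assert_array_equal(a.rim, b.rim)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no reference foreground"):
            gm.reference_masks(np.zeros((16, 16)))

    def test_thin_object_erosion_error(self):
        img = np.zeros((16, 16))
        img[8, 2:14] = 100.0  # 1-px-wide line: erosion empties it
        with pytest.raises(ValueError, match="erosion emptied"):
            gm.reference_masks(img)


class TestIbmAssociationIndex:
    def test_all_core_dye_gives_zero(self):
        img = _disk_image()
        masks = gm.reference_masks(img)
        obj = np.where(masks.core, 100.0, 0.0)
        assert gm.ibm_association_index(obj, masks).index == 0.0

    def test_uniform_dye_gives_one(self):
        img = _disk_image()
        masks = gm.reference_masks(img)
        obj = np.where(masks.core | masks.rim, 100.0, 0.0)
        assert gm.ibm_association_index(obj, masks).index == pytest.approx(1.0)

    def test_scaling_invariance(self):
        img = _disk_image()
        masks = gm.reference_masks(img)
        rng = np.random.default_rng(0)
        obj = rng.uniform(1, 50, img.shape)
        a = gm.ibm_association_index(obj, masks).index
        b = gm.ibm_association_index(obj * 7.5, masks).index
        assert a == pytest.approx(b, rel=1e-12)

    def test_rotation_invariance(self):
        img = _disk_image()
        img[12:16, 20:29] = 900.0  # break symmetry
        rng = np.random.default_rng(1)
        obj = rng.uniform(0, 80, img.shape)
        a = gm.ibm_association_index(obj, gm.reference_masks(img)).index
        b = gm.ibm_association_index(
            np.rot90(obj), gm.reference_masks(np.rot90(img))
        ).index
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_core_intensity_is_error_not_inf(self):
        img = _disk_image()
        masks = gm.reference_masks(img)
        obj = np.where(masks.rim, 100.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            gm.ibm_association_index(obj, masks)

    def test_monotone_in_rim_fraction(self, noise_free_scene):
        """At fixed geometry and optics, the measured index strictly
        increases with the true fraction of dye at the boundary membrane."""
        indices = []
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            frame, truth = syn.render_frame(
                replace(noise_free_scene, rim_fraction_override=f)
            )
            assert truth.rim_fraction == pytest.approx(f)
            masks = gm.reference_masks(frame.reference)
            indices.append(gm.ibm_association_index(frame.object, masks).index)
        assert np.all(np.diff(indices) > 0)


class TestCrossProfile:
    def test_width_averaging_is_identity_on_a_uniform_tube(self):
        img = np.tile(np.exp(-((np.arange(64) - 32.0) ** 2) / 18.0), (64, 1)) * 100
        wide = gm.cross_profile(img, img, ((32.0, 4.0), (32.0, 60.0)), width=20)
        narrow = gm.cross_profile(img, img, ((32.0, 4.0), (32.0, 60.0)), width=1)
        np.testing.assert_allclose(wide.values_ref, narrow.values_ref, rtol=1e-9)

    def test_gaussian_section_preserves_sigma(self):
        """A width-averaged section through an isotropic Gaussian is a 1D
        Gaussian of the same sigma (moment fit within 1%)."""
        sigma = 2.0
        yy, xx = np.mgrid[:81, :81]
        img = np.exp(-((yy - 40) ** 2 + (xx - 40) ** 2) / (2 * sigma**2))
        prof = gm.cross_profile(img, img, ((40.0, 10.0), (40.0, 70.0)), width=30,
                                spacing=1.0)
        p = prof.values_ref
        x = prof.positions
        mu = (p * x).sum() / p.sum()
        sd = np.sqrt((p * (x - mu) ** 2).sum() / p.sum())
        assert sd == pytest.approx(sigma, rel=0.01)

    def test_reversed_endpoints_reverse_profile(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 10, (32, 32))
        fwd = gm.cross_profile(img, img, ((10.0, 5.0), (10.0, 25.0)), width=4)
        rev = gm.cross_profile(img, img, ((10.0, 25.0), (10.0, 5.0)), width=4)
        np.testing.assert_allclose(fwd.values_ref, rev.values_ref[::-1], rtol=1e-9)

    def test_endpoint_outside_image_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError, match="outside"):
            gm.cross_profile(img, img, ((0.0, 0.0), (0.0, 40.0)))


class TestFwhmSubpixel:
    def test_triangle_is_exact(self):
        """Linear interpolation is exact on piecewise-linear data: a
        0-10-0 triangle over 10 unit steps has FWHM exactly 5."""
        x = np.arange(11.0)
        y = 10.0 - 2.0 * np.abs(x - 5.0)
        fwhm, (left, right) = gm.fwhm_subpixel(x, y)
        assert (left, right) == (2.5, 7.5)
        assert fwhm == 5.0

    @pytest.mark.parametrize("sigma,spacing", [(1.5, 1.0), (2.0, 1.0), (4.0, 1.0),
                                               (1.5, 0.5)])
    def test_gaussian_within_one_percent(self, sigma, spacing):
        x = np.arange(-10 * sigma, 10 * sigma + spacing / 2, spacing)
        y = np.exp(-(x**2) / (2 * sigma**2))
        fwhm, _ = gm.fwhm_subpixel(x, y)
        assert fwhm == pytest.approx(GAUSS_FWHM * sigma, rel=0.01)

    def test_monotone_ramp_not_resolved(self):
        x = np.arange(10.0)
        with pytest.raises(gm.ProfileNotResolvedError, match="not resolved"):
            gm.fwhm_subpixel(x, x)

    def test_unreached_half_max_not_resolved(self):
        x = np.arange(7.0)
        y = np.array([8.0, 9.0, 9.5, 10.0, 9.5, 9.0, 8.0])
        with pytest.raises(gm.ProfileNotResolvedError):
            gm.fwhm_subpixel(x, y)  # baseline 0: half-max 5 never crossed

    def test_plateau_at_half_max_uses_midpoint(self):
        x = np.arange(7.0)
        y = np.array([0.0, 5.0, 5.0, 10.0, 5.0, 5.0, 0.0])
        with pytest.warns(UserWarning, match="plateau"):
            fwhm, _ = gm.fwhm_subpixel(x, y)
        assert fwhm == pytest.approx(3.0)

    def test_minimum_baseline(self):
        x = np.arange(11.0)
        y = 10.0 - 2.0 * np.abs(x - 5.0) + 100.0  # triangle on a pedestal
        fwhm, _ = gm.fwhm_subpixel(x, y, baseline="minimum")
        assert fwhm == pytest.approx(5.0)


class TestDeltaFwhm:
    def _profile(self, sig_ref, sig_obj):
        x = np.arange(0, 40, 0.5)
        ref = np.exp(-((x - 20) ** 2) / (2 * sig_ref**2))
        obj = np.exp(-((x - 20) ** 2) / (2 * sig_obj**2))
        return gm.LineProfile(x, ref, obj, width=1, endpoints=((0, 0), (0, 39)),
                              pixel_size=32.0)

    def test_identical_channels_give_zero(self):
        res = gm.delta_fwhm(self._profile(2.0, 2.0))
        assert res.delta == pytest.approx(0.0, abs=1e-9)

    def test_narrower_object_gives_negative_delta(self):
        res = gm.delta_fwhm(self._profile(2.0, 1.0))
        assert res.delta == pytest.approx(-GAUSS_FWHM, rel=0.01)  # -2.3548 px

    def test_sign_convention_flips(self):
        res = gm.delta_fwhm(self._profile(2.0, 1.0), sign="ref-obj")
        assert res.delta == pytest.approx(GAUSS_FWHM, rel=0.01)

    def test_error_tagged_with_channel(self):
        x = np.arange(20.0)
        ref = np.exp(-((x - 10) ** 2) / 8.0)
        prof = gm.LineProfile(x, ref, x + 1.0, width=1,
                              endpoints=((0, 0), (0, 19)), pixel_size=32.0)
        with pytest.raises(gm.ProfileNotResolvedError, match="object channel"):
            gm.delta_fwhm(prof)

    def test_monotone_in_rim_fraction(self, noise_free_scene):
        """Rim-shifted object dye widens its cross profile relative to the
        reference: delta strictly increases with the true rim fraction."""
        deltas = []
        for f in (0.1, 0.5, 0.9):
            frame, _ = syn.render_frame(
                replace(noise_free_scene, rim_fraction_override=f)
            )
            masks = gm.reference_masks(frame.reference)
            ds = []
            for ep in gm.auto_profiles(masks):
                try:
                    prof = gm.cross_profile(
                        frame.reference, frame.object, ep, width=10
                    )
                    ds.append(gm.delta_fwhm(prof).delta)
                except (gm.ProfileNotResolvedError, ValueError):
                    continue
            deltas.append(np.median(ds))
        assert deltas[0] < deltas[1] < deltas[2]
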