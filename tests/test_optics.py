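"""Forward model: PSF kernels, blurring, stack composition, dual geometry."""

import numpy as np
import pytest

from cellstack3d import (
    LayerStack,
    PSFModel,
    SensorGeometry,
    blur,
    compose_stack,
    generate_cell_image,
    psf_kernel,
    subtract_overlap,
)


def brute_force_conv(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^2 K^2) zero-padded 'same' convolution, the oracle."""
    h, w = image.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    ii, jj = i - (a - rh), j - (b - rw)
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += image[ii, jj] * kernel[a, b]
            out[i, j] = acc
    return out


class TestPsfKernel:
    def test_zero_width_is_delta(self):
        k = psf_kernel(PSFModel(sigma0_px=0.0), 0.0)
        np.testing.assert_array_equal(k, [[1.0]])

    @pytest.mark.parametrize("kind", ["gaussian", "disc"])
    @pytest.mark.parametrize("depth", [0.0, 100.0, 500.0, 1000.0, 2000.0])
    def test_normalization_and_shape(self, kind, depth):
        k = psf_kernel(PSFModel(kind=kind), depth)
        assert abs(k.sum() - 1.0) <= 1e-9
        assert k.min() >= 0
        assert k.shape[0] % 2 == 1 and k.shape[0] == k.shape[1]

    def test_gaussian_pointwise_values(self):
        """sigma0=1, slope=4/mm, depth 500 um -> sigma = 3 px exactly."""
        model = PSFModel(sigma0_px=1.0, slope_px_per_mm=4.0)
        k = psf_kernel(model, 500.0)
        sigma = 3.0
        r = k.shape[0] // 2
        ax = np.arange(-r, r + 1)
        xx, yy = np.meshgrid(ax, ax)
        expected = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        expected /= expected.sum()
        np.testing.assert_allclose(k, expected, rtol=1e-12)

    def test_width_non_decreasing_in_depth(self):
        model = PSFModel()
        widths = [psf_kernel(model, d).shape[0] for d in np.linspace(0, 2000, 21)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_centro_symmetric(self):
        for kind in ("gaussian", "disc"):
            k = psf_kernel(PSFModel(kind=kind), 700.0)
            np.testing.assert_array_equal(k, k[::-1, ::-1])

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            psf_kernel(PSFModel(), -1.0)

    def test_measured_bank_nearest_neighbor(self):
        bank = {0.0: np.ones((3, 3)), 1000.0: np.ones((5, 5))}
        model = PSFModel(kind="measured", kernel_bank=bank)
        assert psf_kernel(model, 300.0).shape == (3, 3)
        assert psf_kernel(model, 800.0).shape == (5, 5)
        assert abs(psf_kernel(model, 800.0).sum() - 1.0) <= 1e-9

    def test_measured_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            PSFModel(kind="measured", kernel_bank={})


class TestBlur:
    def test_zero_image_stays_zero(self, psf):
        out = blur(np.zeros((51, 51)), 900.0, psf)
        assert np.all(out == 0)

    def test_impulse_response_is_kernel(self, psf):
        img = np.zeros((51, 51))
        img[25, 25] = 1.0
        out = blur(img, 600.0, psf)
        k = psf_kernel(psf, 600.0)
        r = k.shape[0] // 2
        np.testing.assert_allclose(out[25 - r : 26 + r, 25 - r : 26 + r], k, atol=1e-12)

    def test_matches_brute_force(self, psf, rng):
        img = rng.random((51, 51))
        out = blur(img, 700.0, psf)
        expected = brute_force_conv(img, psf_kernel(psf, 700.0))
        np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-9)

    def test_flux_conserved_for_interior_support(self, psf, rng):
        img = np.zeros((51, 51))
        img[10:41, 10:41] = rng.random((31, 31))
        out = blur(img, 300.0, psf)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_contrast_monotone_degradation(self, cell_image, psf):
        stds = [blur(cell_image, d, psf).std() for d in np.linspace(0, 2000, 9)]
        assert all(b <= a + 1e-9 for a, b in zip(stds, stds[1:]))


class TestComposeStack:
    def test_single_layer_equals_blur(self, cell_image, psf):
        stack = LayerStack(((cell_image, 400.0),))
        view = compose_stack(stack, psf, "A")
        np.testing.assert_array_equal(view.image, blur(cell_image, 400.0, psf))

    def test_sensor_b_effective_depth(self, cell_image, psf):
        geometry = SensorGeometry(separation_um=1000.0)
        stack = LayerStack(((cell_image, 300.0),))
        view_b = compose_stack(stack, psf, "B", geometry)
        np.testing.assert_allclose(view_b.image, blur(cell_image, 700.0, psf))

    def test_dual_view_mirror_symmetry(self, psf):
        imgs = [generate_cell_image(seed=s) for s in range(4)]
        depths = (100.0, 350.0, 620.0, 900.0)
        geometry = SensorGeometry(1000.0)
        stack = LayerStack(tuple(zip(imgs, depths)))
        mirrored = LayerStack(
            tuple(zip(imgs[::-1], [1000.0 - d for d in depths[::-1]]))
        )
        a = compose_stack(stack, psf, "A", geometry).image
        b = compose_stack(mirrored, psf, "B", geometry).image
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_effective_depths_sum_to_separation(self):
        geometry = SensorGeometry(1000.0)
        for d in (0.0, 123.4, 500.0, 987.6, 1000.0):
            assert geometry.effective_depth(d, "A") + geometry.effective_depth(d, "B") == 1000.0

    def test_linearity_over_layers(self, psf):
        imgs = [generate_cell_image(seed=s) for s in range(3)]
        depths = (100.0, 500.0, 900.0)
        stack = LayerStack(tuple(zip(imgs, depths)))
        total = compose_stack(stack, psf, "A").image
        parts = sum(
            compose_stack(LayerStack(((im, d),)), psf, "A").image
            for im, d in zip(imgs, depths)
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12)

    def test_layer_deeper_than_separation_rejected(self, cell_image, psf):
        stack = LayerStack(((cell_image, 1500.0),))
        with pytest.raises(ValueError):
            compose_stack(stack, psf, "A", SensorGeometry(1000.0))

    def test_depths_must_increase(self, cell_image):
        with pytest.raises(ValueError):
            LayerStack(((cell_image, 500.0), (cell_image, 300.0)))


class TestSubtractOverlap:
    def test_disjoint_masks_unchanged(self):
        a, b = generate_cell_image(1), generate_cell_image(2)
        from cellstack3d.phantom import CellImage, TumorMask

        m1 = np.zeros((51, 51), dtype=bool)
        m1[:10] = True
        m2 = np.zeros((51, 51), dtype=bool)
        m2[40:] = True
        a = CellImage(a.intensity, TumorMask(m1), a.stats, a.seed)
        b = CellImage(b.intensity, TumorMask(m2), b.stats, b.seed)
        ra, rb = subtract_overlap(a, b)
        assert ra is a and rb is b

    def test_identical_masks_cleared(self):
        a = generate_cell_image(3)
        from cellstack3d.phantom import CellImage

        b = CellImage(generate_cell_image(4).intensity, a.mask, a.stats, 4)
        ra, rb = subtract_overlap(a, b)
        assert not ra.mask.mask.any()
        assert not rb.mask.mask.any()

    def test_disjointness_and_untouched_pixels(self):
        for seed in range(10):
            a = generate_cell_image(100 + seed)
            b = generate_cell_image(200 + seed)
            overlap = a.mask.mask & b.mask.mask
            ra, rb = subtract_overlap(a, b)
            assert not (ra.mask.mask & rb.mask.mask).any()
            np.testing.assert_array_equal(
                ra.intensity[~overlap], a.intensity[~overlap]
            )
            np.testing.assert_array_equal(
                rb.intensity[~overlap], b.intensity[~overlap]
            )
            # masks outside the overlap are preserved
            np.testing.assert_array_equal(ra.mask.mask, a.mask.mask & ~overlap)
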