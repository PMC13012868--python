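"""The sieving core: resizing, background removal, area opening, the size
distribution and its moments — each validated against brute-force oracles
and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dropsieve.granulometry import (
    DiameterSchedule,
    Image,
    SizeDistribution,
    area_open,
    compute_moments,
    compute_size_distribution,
    normalize_distribution,
    remove_background,
    resize_image,
)
from dropsieve.synthetic import DropletSpec, FieldSpec, render_field

from ._oracles import (
    area_open_bruteforce,
    granulometry_losses_bruteforce,
    moments_direct,
    rolling_ball_background_oracle,
)

small_int_images = hnp.arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(4, 12), st.integers(4, 12)),
    elements=st.integers(0, 7),
)


class TestResize:
    def test_factor_one_is_identity(self, rng):
        img = Image(rng.uniform(0, 10, (32, 32)))
        out = resize_image(img, 1.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_checkerboard_halved_is_block_mean(self):
        board = np.indices((16, 16)).sum(axis=0) % 2 * 10.0
        out = resize_image(Image(board), 0.5)
        np.testing.assert_allclose(out.pixels, 5.0)

    def test_block_mean_preserves_global_mean(self, rng):
        img = Image(rng.uniform(0, 100, (64, 64)))
        out = resize_image(img, 0.5)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), abs=1e-6)
        assert out.shape == (32, 32)

    def test_pixel_size_rescaled(self):
        img = Image(np.ones((32, 32)), pixel_size=0.65)
        assert resize_image(img, 0.5).pixel_size == pytest.approx(1.30)

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.5])
    def test_bad_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            resize_image(Image(np.ones((32, 32))), factor)


class TestRemoveBackground:
    def test_constant_image_removed_entirely(self):
        out = remove_background(Image(np.full((64, 64), 37.0)), 10)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_zero_image_fixed_point(self):
        out = remove_background(Image(np.zeros((64, 64))), 5)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_spot_on_gradient_survives(self):
        """A small bright spot on a sloped background keeps ~its height after
        subtraction, and matches the grey-opening ball oracle."""
        rows = np.arange(96, dtype=float)[:, None] * 0.5
        background = 10.0 + rows * np.ones((96, 96))
        spot, _ = render_field(FieldSpec(shape=(96, 96), droplets=[DropletSpec((48, 48), 5, 100)]))
        img = background + spot.pixels
        out = remove_background(Image(img), 25)
        assert out.pixels.max() == pytest.approx(100, rel=0.10)
        oracle = img - rolling_ball_background_oracle(img, 25)
        assert oracle.max() == pytest.approx(100, rel=0.10)
        assert out.pixels.max() == pytest.approx(oracle.max(), rel=0.10)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            remove_background(Image(np.ones((32, 32))), 0.5)

    def test_output_nonnegative(self, rng):
        img = Image(rng.uniform(0, 50, (64, 64)))
        assert remove_background(img, 8).pixels.min() >= 0


class TestAreaOpen:
    def test_component_meeting_threshold_unchanged(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 10.0
        out = area_open(Image(img), 9)
        np.testing.assert_array_equal(out.pixels, img)

    def test_component_below_threshold_flattened(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 10.0
        out = area_open(Image(img), 10)
        assert out.pixels.sum() == 0.0
        assert (img - out.pixels).sum() == 90.0

    @pytest.mark.parametrize("threshold", [2, 5, 9])
    def test_matches_level_set_oracle(self, rng, threshold):
        img = rng.integers(0, 8, (12, 12))
        out = area_open(Image(img.astype(float)), threshold)
        np.testing.assert_array_equal(out.pixels, area_open_bruteforce(img, threshold).astype(float))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(img=small_int_images, threshold=st.integers(1, 20))
    def test_antiextensive_and_idempotent(self, img, threshold):
        opened = area_open(Image(img.astype(float)), threshold).pixels
        assert np.all(opened <= img)
        reopened = area_open(Image(opened), threshold).pixels
        np.testing.assert_array_equal(reopened, opened)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(img=small_int_images, bump=st.integers(0, 3), threshold=st.integers(1, 20))
    def test_increasing_operator(self, img, bump, threshold):
        """I <= J pixelwise implies open(I) <= open(J)."""
        lower = area_open(Image(img.astype(float)), threshold).pixels
        upper = area_open(Image((img + bump).astype(float)), threshold).pixels
        assert np.all(lower <= upper)


def schedule_for(thresholds, dx=1.0):
    """Schedule with explicit area thresholds on a unit-spaced diameter grid."""
    return DiameterSchedule(
        x=np.arange(1, len(thresholds) + 1, dtype=float) * dx,
        dx=dx,
        area_thresholds=np.asarray(thresholds, float),
    )


class TestSizeDistribution:
    def test_all_zero_image_yields_zero_flagged_spectrum(self):
        sched = DiameterSchedule.uniform(2, 10, 2)
        with pytest.warns(UserWarning, match="zero"):
            dist = compute_size_distribution(Image(np.zeros((30, 30))), sched)
        assert np.all(dist.y == 0)
        assert dist.empty

    def test_single_component_loss_lands_in_one_bin(self):
        """A 3x3, height-10 square (area 9) is removed entirely by the first
        opening whose area threshold exceeds 9."""
        img = np.zeros((30, 30))
        img[10:13, 10:13] = 10.0
        sched = schedule_for([4, 9, 10, 20])
        dist = compute_size_distribution(Image(img), sched)
        raw = dist.y * dist.mean_input_intensity
        np.testing.assert_allclose(raw, [0.0, 0.0, 90.0, 0.0], atol=1e-9)

    def test_two_disks_match_bruteforce_granulometry(self):
        """Per-bin losses on a two-disk image equal those of an independent
        level-set implementation differenced the same way."""
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 4.1**2] = 5  # area ~ 13
        img[(yy - 45) ** 2 + (xx - 45) ** 2 <= 12.5**2] = 2  # area ~ 49 scale
        sched = DiameterSchedule.uniform(2, 30, 2)
        dist = compute_size_distribution(Image(img), sched)
        expected = granulometry_losses_bruteforce(img.astype(int), sched.area_thresholds)
        np.testing.assert_allclose(dist.y * dist.mean_input_intensity, expected, atol=1e-9)

    def test_sieving_is_monotone_and_conservative(self, rng):
        """Cumulative loss is non-decreasing and totals input minus final
        opening, on random fields."""
        sched = DiameterSchedule.uniform(2, 16, 2)
        for seed in range(10):
            img = np.random.default_rng(seed).uniform(0, 10, (48, 48))
            dist = compute_size_distribution(Image(img), sched)
            raw = dist.y * dist.mean_input_intensity
            cum = np.cumsum(raw)
            assert np.all(np.diff(cum) >= -1e-9)
            assert cum[-1] == pytest.approx(dist.total_input_intensity - dist.residual_intensity, rel=1e-9)


class TestNormalize:
    def test_unit_mass_is_fixed_point(self):
        d = SizeDistribution(x=[1.0, 2.0], y=[2.0, 2.0], dx=0.25)
        out = normalize_distribution(d)
        np.testing.assert_allclose(out.y, [2.0, 2.0])

    def test_rescales_by_total_mass(self):
        d = SizeDistribution(x=[1.0, 2.0], y=[4.0, 4.0], dx=0.25)
        out = normalize_distribution(d)
        np.testing.assert_allclose(out.y, [2.0, 2.0])
        assert out.normalized

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=40),
    )
    def test_riemann_sum_is_one_after_normalization(self, y):
        dx = 0.7
        d = SizeDistribution(x=np.arange(1, len(y) + 1, dtype=float), y=np.array(y), dx=dx)
        out = normalize_distribution(d)
        assert abs(float(sum(v * dx for v in out.y)) - 1.0) <= 1e-12

    def test_empty_distribution_rejected(self):
        d = SizeDistribution(x=[1.0, 2.0], y=[0.0, 0.0], dx=1.0)
        with pytest.raises(ValueError, match="empty size distribution"):
            normalize_distribution(d)


class TestMoments:
    def test_point_mass_has_zero_variance_and_undefined_shape(self):
        d = SizeDistribution(x=[1.0, 2.0, 3.0], y=[0.0, 1.0, 0.0], dx=1.0, normalized=True)
        m = compute_moments(d)
        assert m.mean == pytest.approx(2.0)
        assert m.variance == pytest.approx(0.0)
        assert not m.defined
        assert m.skew is None and m.kurtosis is None

    def test_two_point_symmetric_distribution(self):
        d = SizeDistribution(x=[1.0, 2.0, 3.0], y=[0.5, 0.0, 0.5], dx=1.0, normalized=True)
        m = compute_moments(d)
        assert (m.mean, m.variance, m.skew, m.kurtosis) == pytest.approx((2.0, 1.0, 0.0, 1.0))

    def test_discretized_gaussian_recovers_its_parameters(self):
        x = np.linspace(0, 30, 61)
        dx = x[1] - x[0]
        y = np.exp(-0.5 * ((x - 15) / 3) ** 2)
        y /= y.sum() * dx
        m = compute_moments(SizeDistribution(x=x, y=y, dx=dx, normalized=True))
        mu_o, var_o, skew_o, kurt_o = moments_direct(x, y, dx)
        assert m.mean == pytest.approx(15.0, rel=0.01)
        assert m.variance == pytest.approx(9.0, rel=0.01)
        assert abs(m.skew) < 0.01
        assert m.kurtosis == pytest.approx(3.0, rel=0.01)
        assert (m.mean, m.variance, m.skew, m.kurtosis) == pytest.approx((mu_o, var_o, skew_o, kurt_o))

    def test_unnormalized_input_rejected(self):
        d = SizeDistribution(x=[1.0, 2.0], y=[1.0, 1.0], dx=1.0, normalized=False)
        with pytest.raises(ValueError, match="normalis"):
            compute_moments(d)

    def test_moments_scale_correctly_with_diameter_units(self):
        """x -> c*x scales mu by c and variance by c^2; skew and kurtosis are
        scale-free."""
        rng = np.random.default_rng(3)
        x = np.linspace(1, 20, 20)
        y = rng.uniform(0.1, 1.0, 20)
        dx = x[1] - x[0]
        base = compute_moments(normalize_distribution(SizeDistribution(x=x, y=y, dx=dx)))
        c = 3.7
        scaled = compute_moments(normalize_distribution(SizeDistribution(x=c * x, y=y, dx=c * dx)))
        assert scaled.mean == pytest.approx(c * base.mean, rel=1e-9)
        assert scaled.variance == pytest.approx(c**2 * base.variance, rel=1e-9)
        assert scaled.skew == pytest.approx(base.skew, rel=1e-9)
        assert scaled.kurtosis == pytest.approx(base.kurtosis, rel=1e-9)


class TestSchedule:
    def test_printed_area_formula_is_default(self):
        sched = DiameterSchedule.uniform(2, 10, 2)
        np.testing.assert_allclose(sched.area_thresholds, 2 * np.pi * (sched.x / 2) ** 2)

    def test_circle_formula_is_half_the_printed_one(self):
        printed = DiameterSchedule.uniform(2, 10, 2, "printed")
        circle = DiameterSchedule.uniform(2, 10, 2, "circle")
        np.testing.assert_allclose(printed.area_thresholds, 2 * circle.area_thresholds)

    def test_monodisperse_field_peaks_at_the_droplet_size(self):
        """End-to-end size recovery: a field of equal droplets produces a
        spectrum whose mean lies within 2*dx of the first schedule diameter
        whose area threshold exceeds the droplet pixel area."""
        droplets = [DropletSpec((r, c), 10, 100) for r in (20, 50, 80) for c in (20, 50, 80)]
        img, _ = render_field(FieldSpec(shape=(100, 100), droplets=droplets))
        pixel_area = np.count_nonzero(
            render_field(FieldSpec(shape=(100, 100), droplets=[droplets[0]]))[0].pixels
        )
        sched = DiameterSchedule.uniform(2, 20, 2)
        target = sched.x[np.argmax(sched.area_thresholds > pixel_area)]
        dist = normalize_distribution(compute_size_distribution(img, sched))
        m = compute_moments(dist)
        assert abs(m.mean - target) <= 2 * sched.dx
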