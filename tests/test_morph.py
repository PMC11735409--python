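"""Tests for organoid midline morphometrics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from axialquant.morph import (
    correlate,
    extract_midline,
    longest_positive_stretch,
    signal_area_fraction,
    standardized_profile,
    volume_fraction_ratio,
)
from axialquant.synthetic import (
    _arc_curve,
    curve_capsule_mask,
    notoroid_cohort,
    paint_area_fraction,
    stripe_signal,
)


@pytest.fixture(scope="module")
def capsule():
    curve = _arc_curve(800.0, 1 / 2000.0)
    mask, s_image, full_length = curve_capsule_mask(curve, 150.0, 2.0)
    return mask, s_image, full_length


class TestExtractMidline:
    def test_rectangle_length(self):
        mask = np.zeros((30, 120), bool)
        mask[10:20, 10:110] = True
        m = extract_midline(mask, pixel_size=1.0)
        assert m.arclength_um == pytest.approx(100.0, abs=2.0)

    def test_disc_length_is_diameter(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disc = (xx - 40) ** 2 + (yy - 40) ** 2 <= 30**2
        m = extract_midline(disc, pixel_size=1.0)
        assert m.arclength_um == pytest.approx(60.0, rel=0.05)

    def test_curved_capsule_length(self):
        curve = _arc_curve(800.0, 1 / 500.0)  # C-shaped
        mask, _, full_length = curve_capsule_mask(curve, 24.0, 2.0)
        m = extract_midline(mask, pixel_size=2.0)
        assert m.arclength_um == pytest.approx(full_length, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_midline(np.zeros((10, 10), bool))

    def test_thin_mask_falls_back_with_warning(self):
        mask = np.zeros((20, 60), bool)
        mask[10, 5:55] = True
        with pytest.warns(UserWarning, match="chord"):
            m = extract_midline(mask, pixel_size=1.0)
        assert m.arclength_um == pytest.approx(50.0, abs=3.0)

    def test_rotation_invariance(self):
        mask = np.zeros((160, 160), bool)
        mask[70:90, 20:140] = True
        base = extract_midline(mask, 1.0).arclength_um
        rot = ndi.rotate(mask.astype(float), 33.0, reshape=True, order=0) > 0.5
        rotated = extract_midline(rot, 1.0).arclength_um
        assert rotated == pytest.approx(base, rel=0.03)


class TestStandardizedProfile:
    def test_uniform_signal(self, capsule):
        mask, _, _ = capsule
        prof = standardized_profile(mask, np.full(mask.shape, 5.0), n_bins=20, pixel_size=2.0)
        assert np.allclose(prof.bin_values, 5.0)

    def test_stripe_bins_match_interval(self, capsule):
        mask, s_image, _ = capsule
        sig = stripe_signal(mask, s_image, (0.3, 0.7), rng=np.random.default_rng(0))
        prof = standardized_profile(mask, sig, n_bins=50, pixel_size=2.0, orient_bright_low=False)
        pos = np.nonzero(prof.bin_values >= 100.0)[0]
        assert pos.min() >= 50 * 0.3 - 1 and pos.max() <= 50 * 0.7 + 1

    def test_single_bin_is_global_max(self, capsule):
        mask, s_image, _ = capsule
        sig = stripe_signal(mask, s_image, (0.4, 0.6), rng=np.random.default_rng(1))
        prof = standardized_profile(mask, sig, n_bins=1, pixel_size=2.0, orient_bright_low=False)
        assert prof.bin_values[0] == sig[mask].max()

    def test_mirrored_mask_profile_matches_up_to_direction(self, capsule):
        """The midline's own direction is arbitrary, so a mirrored mask
        yields the same profile or its reverse; the brightness-orientation
        rule collapses both onto one standard direction."""
        mask, s_image, _ = capsule
        sig = stripe_signal(mask, s_image, (0.1, 0.3), rng=np.random.default_rng(2))
        a = standardized_profile(mask, sig, n_bins=25, pixel_size=2.0, orient_bright_low=False)
        b = standardized_profile(mask[:, ::-1], sig[:, ::-1], n_bins=25, pixel_size=2.0, orient_bright_low=False)
        ax = a.bin_values >= 100.0
        bx = b.bin_values >= 100.0
        assert min((ax != bx).sum(), (ax != bx[::-1]).sum()) <= 2
        ao = standardized_profile(mask, sig, n_bins=25, pixel_size=2.0)
        bo = standardized_profile(mask[:, ::-1], sig[:, ::-1], n_bins=25, pixel_size=2.0)
        assert ((ao.bin_values >= 100.0) != (bo.bin_values >= 100.0)).sum() <= 2

    def test_bright_low_orientation(self, capsule):
        mask, s_image, _ = capsule
        sig = stripe_signal(mask, s_image, (0.7, 0.95), rng=np.random.default_rng(3))
        prof = standardized_profile(mask, sig, n_bins=40, pixel_size=2.0, orient_bright_low=True)
        half = len(prof.bin_values) // 2
        assert prof.bin_values[:half].sum() >= prof.bin_values[half:].sum()


class TestStretchAndArea:
    def test_no_positive_bins(self, capsule):
        mask, _, _ = capsule
        prof = standardized_profile(mask, np.full(mask.shape, 1.0), n_bins=20, pixel_size=2.0)
        assert longest_positive_stretch(prof, threshold=10.0) == 0.0

    def test_all_positive_bins(self, capsule):
        mask, _, _ = capsule
        prof = standardized_profile(mask, np.full(mask.shape, 50.0), n_bins=20, pixel_size=2.0)
        assert longest_positive_stretch(prof, threshold=10.0) == 1.0

    def test_stripe_coverage_recovered(self, capsule):
        mask, s_image, _ = capsule
        sig = stripe_signal(mask, s_image, (0.3, 0.7), rng=np.random.default_rng(4))
        prof = standardized_profile(mask, sig, n_bins=50, pixel_size=2.0)
        got = longest_positive_stretch(prof, threshold=100.0)
        assert got == pytest.approx(0.40, abs=1 / 50 + 1e-9)

    def test_threshold_above_max_zero_fraction(self, capsule):
        mask, _, _ = capsule
        frac, _ = signal_area_fraction(mask, np.full(mask.shape, 5.0), threshold=10.0)
        assert frac == 0.0

    def test_threshold_at_min_full_fraction(self, capsule):
        mask, _, _ = capsule
        frac, _ = signal_area_fraction(mask, np.full(mask.shape, 5.0), threshold=5.0)
        assert frac == 1.0

    def test_three_percent_stripe_recovered(self, capsule):
        mask, s_image, _ = capsule
        sig, achieved = paint_area_fraction(mask, s_image, 0.03, rng=np.random.default_rng(5))
        frac, _ = signal_area_fraction(mask, sig, threshold=100.0)
        assert achieved == pytest.approx(0.03, abs=0.001)
        assert frac == pytest.approx(0.03, abs=0.005)

    def test_cohort_mean_coverage_recovered(self):
        cohort = notoroid_cohort(50, seed=13)
        true_cov, got = [], []
        for rec in cohort:
            mid = extract_midline(rec["mask"], rec["pixel_size"])
            prof = standardized_profile(
                rec["mask"], rec["signal"], n_bins=50, pixel_size=rec["pixel_size"], midline=mid
            )
            true_cov.append(rec["true_coverage"])
            got.append(longest_positive_stretch(prof, threshold=100.0))
        assert abs(np.mean(true_cov) - np.mean(got)) <= 0.03


class TestCorrelate:
    def test_exact_negative_line(self):
        x = np.arange(10.0)
        r, _ = correlate(x, -2 * x + 1)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = correlate([1, 2, 3], [6, 4, 5])
        assert r == pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_independent_vectors_near_zero(self, seed):
        rng = np.random.default_rng(seed)
        r, _ = correlate(rng.normal(size=500), rng.normal(size=500))
        assert abs(r) < 0.15

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="variance"):
            r, p = correlate([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_area_fraction_anticoupling_recovered(self):
        """Generator couples larger organoids with smaller bright fractions;
        the measured correlation recovers the negative sign decisively."""
        cohort = notoroid_cohort(50, seed=21, couple_area=True)
        areas = [rec["area_um2"] for rec in cohort]
        fracs = [signal_area_fraction(rec["mask"], rec["bright"], threshold=100.0)[0] for rec in cohort]
        r, p = correlate(areas, fracs)
        assert r < 0 and p < 0.01


class TestVolumeFractionRatio:
    def test_simple_ratios(self):
        out = volume_fraction_ratio([0.1, 0.2], [0.1, 0.1])
        assert np.allclose(out, [1.0, 2.0])

    def test_zero_denominator_flagged(self):
        out = volume_fraction_ratio([0.1], [0.0])
        assert np.isnan(out[0])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            volume_fraction_ratio([-0.1], [0.2])
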