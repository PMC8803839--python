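import dataclasses

import numpy as np
import pytest

import melaflim as mf
from melaflim.errors import ValidationError
from melaflim.slope import (
    BinnedStack,
    PseudoFlimConfig,
    blur_radius_px,
    compute_slope_image,
    melanin_mask,
    open_area_filter,
    temporal_bin,
    two_channel_slope,
)

NO_BLUR = PseudoFlimConfig(apply_blur=False)
EDGES3 = np.array([0.0, 2.0, 4.0, 6.0])


def _binned(values, md):
    values = np.asarray(values, dtype=float).reshape(1, 1, 1, -1)
    edges = np.arange(values.shape[-1] + 1) * 2.0
    return BinnedStack(counts=values, bin_edges=edges, metadata=md)


class TestTemporalBin:
    def test_invitro_binning_conserves_photons(self, md_invitro):
        """3128 x 4 ps channels -> 6 bins of 2 ns; photons conserved over [0, 12)."""
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(1, 4, 4, md_invitro.n_time_channels))
        stack = mf.FLIMStack(counts, md_invitro)
        binned = temporal_bin(stack, PseudoFlimConfig())
        assert binned.n_bins == 6
        centers = md_invitro.channel_centers()
        covered = counts[..., centers < 12.0].sum()
        assert binned.counts.sum() == covered

    def test_spike_lands_in_first_bin(self, md_invitro):
        counts = np.zeros((1, 1, 1, md_invitro.n_time_channels), dtype=np.int64)
        k = int(1.33 / md_invitro.time_channel_width)
        counts[..., k] = 100
        binned = temporal_bin(mf.FLIMStack(counts, md_invitro), PseudoFlimConfig())
        assert binned.counts[0, 0, 0, 0] == 100
        assert binned.counts[0, 0, 0, 1:].sum() == 0

    def test_clinical_stack_passes_through(self, md_clinical):
        """4 channels x 2.08 ns with ~2 ns bin request: identity."""
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(2, 5, 5, 4))
        stack = mf.FLIMStack(counts, md_clinical)
        for width in (2.0, 2.08):
            binned = temporal_bin(stack, PseudoFlimConfig(bin_width=width))
            np.testing.assert_array_equal(binned.counts, counts)
            assert binned.bin_width == pytest.approx(2.08)

    def test_bin_smaller_than_channel_rejected(self, md_clinical):
        stack = mf.FLIMStack(np.ones((1, 2, 2, 4), dtype=np.int64), md_clinical)
        with pytest.raises(ValidationError):
            temporal_bin(stack, PseudoFlimConfig(bin_width=1.0))

    def test_peak_outside_first_bin_warns(self):
        md = mf.AcquisitionMetadata(0.0488, 256, 12.5, 3.0, 1.02)
        counts = np.ones((1, 2, 2, 256), dtype=np.int64)
        with pytest.warns(UserWarning, match="outside the first"):
            temporal_bin(mf.FLIMStack(counts, md), PseudoFlimConfig())


class TestSlopeImage:
    def test_hand_computed_ols_example(self, md_clinical):
        """[100, 0, 0] -> ln[101, 1, 1] -> OLS slope -2.3077 -> value 231."""
        image = compute_slope_image(_binned([100, 0, 0], md_clinical), NO_BLUR)
        assert image.slope.ravel()[0] == 231

    def test_flat_decay_gives_zero(self, md_clinical):
        image = compute_slope_image(_binned([50, 50, 50], md_clinical), NO_BLUR)
        assert image.slope.ravel()[0] == 0

    def test_aligned_mono_exponential_slope_value(self, md_clinical):
        """Noiseless tau = 2.2 ns aligned to a bin edge: ln decrement w/tau
        = 0.909 per channel -> 8-bit value 91."""
        bins = 1e7 * np.exp(-np.arange(3) * 2.0 / 2.2)
        image = compute_slope_image(_binned(bins, md_clinical), NO_BLUR)
        assert image.slope.ravel()[0] == 91

    def test_slope_per_ns_equals_minus_inverse_tau(self, md_clinical):
        """Diagnostic mode (no +1 photon): raw slope / bin width = -1/tau."""
        config = PseudoFlimConfig(apply_blur=False, add_photon=0.0)
        for tau in (0.4, 1.1, 2.2):
            bins = np.exp(-np.arange(3) * 2.0 / tau) * 1e6
            image = compute_slope_image(_binned(bins, md_clinical), config)
            assert image.slope_per_ns.ravel()[0] == pytest.approx(-1.0 / tau, abs=1e-6)

    def test_slope_strictly_decreasing_in_tau(self, md_clinical):
        config = PseudoFlimConfig(apply_blur=False, add_photon=0.0)
        values = []
        for tau in (0.1, 0.3, 0.6, 1.0, 1.6, 2.2, 3.0):
            bins = np.exp(-np.arange(3) * 2.0 / tau) * 1e8
            image = compute_slope_image(_binned(bins, md_clinical), config)
            values.append(image.slope_per_ns.ravel()[0])
        assert np.all(np.diff(values) > 0)  # slopes less negative as tau grows

    def test_scale_invariance_without_added_photon(self, md_clinical):
        config = PseudoFlimConfig(apply_blur=False, add_photon=0.0)
        bins = np.array([400.0, 90.0, 21.0])
        base = compute_slope_image(_binned(bins, md_clinical), config)
        for factor in (2.0, 10.0, 0.5):
            scaled = compute_slope_image(_binned(bins * factor, md_clinical), config)
            assert scaled.slope_per_ns.ravel()[0] == pytest.approx(
                base.slope_per_ns.ravel()[0], abs=1e-12
            )

    def test_added_photon_bias_vanishes_at_high_counts(self, md_clinical):
        shape = np.array([1.0, 0.3, 0.1])
        diffs = []
        for scale in (1e2, 1e4, 1e6):
            with_one = compute_slope_image(_binned(shape * scale, md_clinical), NO_BLUR)
            without = compute_slope_image(
                _binned(shape * scale, md_clinical),
                PseudoFlimConfig(apply_blur=False, add_photon=0.0),
            )
            diffs.append(
                abs(
                    with_one.slope_per_ns.ravel()[0]
                    - without.slope_per_ns.ravel()[0]
                )
            )
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-5

    def test_blur_radius_formula(self):
        assert blur_radius_px(1.0, 0.255) == pytest.approx(
            np.sqrt((1.0 / 0.255**2) / np.pi)
        )

    def test_blur_spreads_within_slice_only(self, md_clinical):
        counts = np.zeros((2, 21, 21, 4), dtype=np.int64)
        counts[0, 10, 10] = [1000, 10, 1, 0]
        stack = mf.FLIMStack(counts, md_clinical)
        binned = temporal_bin(stack, PseudoFlimConfig())
        image = compute_slope_image(binned, PseudoFlimConfig())
        assert image.slope[0, 12, 12] > 0  # in-plane neighbor sees the spread
        assert image.slope[1].max() == 0  # nothing leaks across z


class TestTwoChannelVariant:
    def test_hand_example(self, md_clinical):
        """[100, 0]: the two-point slope is exactly y1 - y0 = -ln(101),
        so the scaled value 461.5 saturates the 8-bit range at 255."""
        image = two_channel_slope(_binned([100, 0], md_clinical), NO_BLUR)
        assert image.slope.ravel()[0] == 255
        raw = image.slope_per_ns.ravel()[0] * 2.0  # back to per-channel units
        assert raw == pytest.approx(-np.log(101.0), abs=1e-12)

    def test_flat_gives_zero(self, md_clinical):
        image = two_channel_slope(_binned([70, 70], md_clinical), NO_BLUR)
        assert image.slope.ravel()[0] == 0

    def test_agrees_with_three_channel_on_phantom_melanin(self, small_phantom):
        """2- and 3-channel masks agree on >= 90% of true melanin voxels."""
        _, stack, truth = small_phantom
        config = PseudoFlimConfig()
        binned = temporal_bin(stack, config)
        mask3 = melanin_mask(
            compute_slope_image(binned, config), config, stack.metadata.pixel_size
        )
        mask2 = melanin_mask(
            two_channel_slope(binned, config), config, stack.metadata.pixel_size
        )
        on_truth = truth.melanin_mask
        agreement = (
            mask3.mask[on_truth] == mask2.mask[on_truth]
        ).mean()
        assert agreement >= 0.9


class TestMelaninMask:
    def test_uniform_high_slope_all_true(self, md_clinical):
        slope = compute_slope_image(
            BinnedStack(
                np.tile([100.0, 0.0, 0.0], (1, 8, 8, 1)), EDGES3, md_clinical
            ),
            NO_BLUR,
        )
        mask = melanin_mask(slope, NO_BLUR, pixel_size=0.255)
        assert mask.mask.all()

    def test_isolated_pixel_removed_by_area_filter(self):
        """One 0.255 um pixel is 0.065 um^2 < 1 um^2: removed."""
        mask = np.zeros((1, 20, 20), dtype=bool)
        mask[0, 10, 10] = True
        assert not open_area_filter(mask, 0.255, 1.0).any()

    def test_5x5_block_retained(self):
        """A 5x5 block at 0.255 um/px is 1.63 um^2 >= 1 um^2: kept."""
        mask = np.zeros((1, 20, 20), dtype=bool)
        mask[0, 5:10, 5:10] = True
        np.testing.assert_array_equal(open_area_filter(mask, 0.255, 1.0), mask)

    def test_area_filter_idempotent(self):
        rng = np.random.default_rng(5)
        mask = rng.random((3, 30, 30)) < 0.3
        once = open_area_filter(mask, 0.255, 1.0)
        twice = open_area_filter(once, 0.255, 1.0)
        np.testing.assert_array_equal(once, twice)

    def test_threshold_nesting(self, small_phantom):
        _, stack, _ = small_phantom
        slope, _ = mf.run_pseudoflim_stack(stack)
        low = slope.slope > 70
        high = slope.slope > 120
        assert np.all(low[high])

    def test_missing_pixel_size_rejected(self, md_clinical):
        slope = compute_slope_image(_binned([100, 0, 0], md_clinical), NO_BLUR)
        with pytest.raises(ValidationError):
            melanin_mask(slope, NO_BLUR, pixel_size=None)


class TestRunPseudoflim:
    def test_all_background_stack_empty_mask(self, md_clinical):
        counts = np.random.default_rng(0).poisson(
            0.02, size=(4, 32, 32, 4)
        )
        stack = mf.FLIMStack(counts, md_clinical)
        _, mask = mf.run_pseudoflim_stack(stack)
        assert not mask.mask.any()

    def test_deterministic(self, small_phantom):
        _, stack, _ = small_phantom
        s1, m1 = mf.run_pseudoflim_stack(stack)
        s2, m2 = mf.run_pseudoflim_stack(stack)
        np.testing.assert_array_equal(s1.slope, s2.slope)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_sensitivity_monotone_in_photon_budget(self, md_clinical):
        """Mask recall on true melanin never improves as photons are cut."""
        recalls = []
        for scale in (1.0, 0.03, 0.01):
            spec = dataclasses.replace(
                mf.default_phantom_spec(seed=4, shape=(32, 40, 40)),
                melanin_params=mf.melanin_species(total_photons=300 * scale),
                epidermis_params=mf.keratinocyte_species(total_photons=80 * scale),
                dermis_params=mf.keratinocyte_species(total_photons=60 * scale),
            )
            stack, truth = mf.simulate_skin_stack(spec, md_clinical)
            _, mask = mf.run_pseudoflim_stack(stack)
            recalls.append(
                (mask.mask & truth.melanin_mask).sum() / truth.melanin_mask.sum()
            )
        assert recalls[0] + 0.02 >= recalls[1] + 1e-12
        assert recalls[1] + 0.02 >= recalls[2]
        assert recalls[0] > 0.9
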