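"""Phantom generation and simulated acquisition."""
import numpy as np
import pytest

from imsiq.core import AcquisitionSpec, ElementalImage, UNIT_UGKG
from imsiq.errors import GeometryError, SizingError
from imsiq.phantom import (
    PhantomSpec,
    STANDARD_LEVELS_UGKG,
    generate_fiber_map,
    generate_standard_block,
    render_concentration_field,
    simulate_linescans,
)


class TestFiberMap:
    def test_single_fiber_no_margin_covers_everything(self):
        spec = PhantomSpec(n_fibers=1, tissue_margin_um=0.0, seed=0)
        labels = generate_fiber_map(spec, 2.0)
        assert np.all(labels == 1)

    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec(seed=5)
        a = generate_fiber_map(spec, 1.0)
        b = generate_fiber_map(spec, 1.0)
        np.testing.assert_array_equal(a, b)

    def test_label_count_matches_fiber_count(self):
        spec = PhantomSpec(n_fibers=25, width_um=300, height_um=300, seed=2)
        labels = generate_fiber_map(spec, 1.0)
        # no margin: no background, labels 1..25 all realised
        assert set(np.unique(labels)) == set(range(1, 26))

    def test_margin_produces_background(self):
        spec = PhantomSpec(n_fibers=4, tissue_margin_um=30.0, seed=1)
        labels = generate_fiber_map(spec, 1.0)
        assert 0 in labels
        assert labels[0, 0] == 0

    def test_too_small_grid_rejected(self):
        spec = PhantomSpec(width_um=20, height_um=20, n_fibers=1)
        with pytest.raises(SizingError):
            generate_fiber_map(spec, 5.0)

    def test_overcrowded_fibers_rejected(self):
        with pytest.raises(SizingError):
            PhantomSpec(width_um=30, height_um=30, n_fibers=100, membrane_width_um=5)


class TestConcentrationField:
    def test_all_zero_when_all_levels_zero(self, small_phantom):
        spec, labels, _ = small_phantom
        z = spec.replace(c_membrane=0.0, c_interior=0.0, c_background=0.0)
        truth = render_concentration_field(labels, z, 1.0)
        assert np.all(truth.values == 0.0)

    def test_two_level_histogram_for_membrane_only(self, small_phantom):
        spec, labels, _ = small_phantom
        z = spec.replace(c_membrane=500.0, c_interior=0.0, c_background=0.0)
        truth = render_concentration_field(labels, z, 1.0)
        assert set(np.unique(truth.values)) == {0.0, 500.0}

    def test_membrane_fraction_monotone_in_width(self, small_phantom):
        spec, labels, _ = small_phantom
        fractions = []
        for w in (1.0, 2.0, 4.0):
            truth = render_concentration_field(labels, spec.replace(membrane_width_um=w), 1.0)
            fractions.append((truth.values == spec.c_membrane).mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_revertant_fibers_boosted(self, small_phantom):
        spec, labels, _ = small_phantom
        rv = spec.replace(revertant_fraction=1.0, revertant_boost=10.0)
        truth = render_concentration_field(labels, rv, 1.0)
        assert truth.values.max() == spec.c_membrane * 10.0

    def test_shape_mismatch_rejected(self, small_phantom):
        spec, labels, _ = small_phantom
        with pytest.raises(GeometryError):
            render_concentration_field(labels.ravel(), spec, 1.0)


class TestLineScanSimulation:
    def test_sample_spacing_gives_200_samples_over_300um(self, quiet_acq):
        # 30 um/s at 20 Hz -> 1.5 um spacing -> 200 samples per 300 um line
        truth = ElementalImage(np.full((300, 300), 10.0), 1.0, 1.0, UNIT_UGKG)
        scans = simulate_linescans(truth, quiet_acq)
        assert quiet_acq.sample_spacing_um == pytest.approx(1.5)
        assert all(len(s) == 200 for s in scans.scans)
        assert len(scans) == 20  # 300 um / 15 um pitch

    def test_zero_truth_zero_dark_gives_zero_intensity(self, quiet_acq):
        truth = ElementalImage(np.zeros((60, 60)), 1.0, 1.0, UNIT_UGKG)
        scans = simulate_linescans(truth, quiet_acq)
        assert all(np.all(s.intensities_cps["Gd158"] == 0) for s in scans.scans)

    def test_mass_balance_uniform_field(self, quiet_acq):
        # grand mean of recorded cps approaches sensitivity * c within 3 SE
        c = 100.0
        truth = ElementalImage(np.full((150, 150), c), 1.0, 1.0, UNIT_UGKG)
        scans = simulate_linescans(truth, quiet_acq)
        vals = np.concatenate(scans.intensities())
        # per-sample counts are Poisson(c * dwell); cps variance = c / dwell
        se = np.sqrt(c / quiet_acq.dwell_s / vals.size)
        assert abs(vals.mean() - c) < 3 * se

    def test_deterministic_for_fixed_seed(self, quiet_acq, small_phantom):
        _, _, truth = small_phantom
        a = simulate_linescans(truth, quiet_acq)
        b = simulate_linescans(truth, quiet_acq)
        for sa, sb in zip(a.scans, b.scans):
            np.testing.assert_array_equal(
                sa.intensities_cps["Gd158"], sb.intensities_cps["Gd158"]
            )

    def test_spot_averaging_smooths_checkerboard(self):
        yy, xx = np.meshgrid(np.arange(120), np.arange(120), indexing="ij")
        checker = np.where(((xx // 5) + (yy // 5)) % 2 == 0, 200.0, 0.0)
        truth = ElementalImage(checker, 1.0, 1.0, UNIT_UGKG)
        variances = []
        for spot in (5.0, 15.0):
            acq = AcquisitionSpec(
                spot_um=spot, sensitivity_cps_per_ugkg=1.0,
                flicker_fraction=0.0, dark_cps=0.0, seed=9,
            )
            scans = simulate_linescans(truth, acq)
            variances.append(np.var(np.concatenate(scans.intensities())))
        assert variances[1] < variances[0]

    def test_coarse_truth_grid_rejected(self, quiet_acq):
        truth = ElementalImage(np.full((20, 20), 5.0), 10.0, 10.0, UNIT_UGKG)
        with pytest.raises(GeometryError):
            simulate_linescans(truth, quiet_acq)


class TestStandardBlocks:
    def test_zero_concentration_zero_dark_all_zero(self, quiet_acq):
        scans = generate_standard_block(0.0, quiet_acq, (60.0, 60.0))
        assert all(np.all(v == 0) for v in scans.intensities())

    def test_table_levels_give_increasing_means(self):
        acq = AcquisitionSpec(seed=4)
        means = []
        for lv in STANDARD_LEVELS_UGKG:
            scans = generate_standard_block(lv, acq, (90.0, 90.0))
            means.append(np.mean(np.concatenate(scans.intensities())))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_sensitivity_doubles_mean(self):
        means = []
        for sens in (2.0, 4.0):
            acq = AcquisitionSpec(
                sensitivity_cps_per_ugkg=sens, dark_cps=0.0,
                flicker_fraction=0.0, seed=8,
            )
            scans = generate_standard_block(400.0, acq, (120.0, 120.0))
            means.append(np.mean(np.concatenate(scans.intensities())))
        assert means[1] == pytest.approx(2 * means[0], rel=0.02)

    def test_negative_concentration_rejected(self, quiet_acq):
        with pytest.raises(SizingError):
            generate_standard_block(-1.0, quiet_acq)
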