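import numpy as np
import pytest

from nanosip.constants import NATURAL_13C_FRACTION, NATURAL_15N_FRACTION
from nanosip.ion_imaging import accumulate
from nanosip.isotope_quant import (
    SubstrateSpec,
    coefficient_of_dispersion,
    effective_substrate_fraction,
)
from nanosip.synthetic_data import (
    GeneratorConfig,
    IonYields,
    TruthCell,
    generate_axenic,
    generate_killed_control,
    generate_strain_population,
    lognormal_sigma_for_cd,
    place_attached_bacterium,
    place_cells_grid,
    render_ion_stacks,
)


@pytest.fixture
def n_substrate():
    return SubstrateSpec(f_s_C_labeled=0.18, f_s_N_labeled=0.45, dilution_unlabeled=0.0)


class TestStrainPopulation:
    def test_zero_dispersion_identical_cells(self, n_substrate):
        f = generate_strain_population(0.08, 0.0, 1.0, n_substrate, 20, seed=1)
        assert np.allclose(f, f[0], atol=1e-15)

    def test_median_inversion_worked_example(self, n_substrate):
        # median f_f = f_i + 0.08 * (0.45 - f_i) at zero dispersion
        f = generate_strain_population(0.08, 0.0, 1.0, n_substrate, 5, seed=1)
        f_i = NATURAL_15N_FRACTION
        assert f[0] == pytest.approx(f_i + 0.08 * (0.45 - f_i), abs=1e-12)
        assert f[0] == pytest.approx(0.039371, abs=5e-6)

    def test_cd_recovery_large_sample(self, n_substrate):
        f = generate_strain_population(0.08, 0.30, 1.0, n_substrate, 10_000, seed=7)
        f_i = NATURAL_15N_FRACTION
        xnet = (f - f_i) / (0.45 - f_i)
        assert coefficient_of_dispersion(xnet) == pytest.approx(0.30, abs=0.02)
        assert np.median(xnet) == pytest.approx(0.08, rel=0.03)

    def test_invalid_dispersion_rejected(self, n_substrate):
        with pytest.raises(ValueError):
            generate_strain_population(0.08, 1.0, 1.0, n_substrate, 10, seed=1)

    def test_out_of_range_fraction_rejected(self, n_substrate):
        # a huge median with large dispersion pushes f_f past 1
        with pytest.raises(ValueError):
            generate_strain_population(0.99, 0.9, 1.0, n_substrate, 4000, seed=1)

    def test_precondition_on_total(self, n_substrate):
        with pytest.raises(ValueError):
            generate_strain_population(0.6, 0.1, 2.0, n_substrate, 10, seed=1)

    def test_sigma_closed_form(self):
        assert lognormal_sigma_for_cd(0.0) == 0.0
        # CD of the resulting lognormal quartiles equals the target
        for cd in (0.1, 0.3, 0.6):
            sigma = lognormal_sigma_for_cd(cd)
            q1, q3 = np.exp(-0.674489750196 * sigma), np.exp(0.674489750196 * sigma)
            assert (q3 - q1) / (q3 + q1) == pytest.approx(cd, abs=1e-9)


class TestRenderIonStacks:
    def test_seed_determinism(self, small_config):
        cells = place_cells_grid(5, 0.35, small_config, f15N=0.04)
        s1, t1 = render_ion_stacks(cells, small_config)
        s2, t2 = render_ion_stacks(cells, small_config)
        for sp in s1:
            np.testing.assert_array_equal(s1[sp].counts, s2[sp].counts)
        assert t1.equals(t2)

    def test_zero_background_off_cell_pixels(self):
        config = GeneratorConfig(
            pixels=64, cycles=3,
            ion_yields=IonYields(c2_cell=50, c2_background=0.0, cn_cell=50, cn_background=0.0),
            seed=5,
        )
        cells = [TruthCell(1, "bacterial", center=(32.0, 32.0), radii_um=(1.0, 1.0))]
        stacks, _ = render_ion_stacks(cells, config)
        mask = cells[0].mask(64, config.raster_um)
        for sp in stacks:
            assert stacks[sp].counts[:, ~mask].sum() == 0

    def test_poisson_ratio_oracle(self):
        """ROI-summed 15N/14N ratio lands within 3 Poisson SE of truth."""
        config = GeneratorConfig(pixels=64, cycles=24, seed=11,
                                 ion_yields=IonYields(cn_cell=200.0))
        f = NATURAL_15N_FRACTION
        cells = [TruthCell(1, "bacterial", center=(32.0, 32.0), radii_um=(1.55, 1.55), f15N_true=f)]
        stacks, truth = render_ion_stacks(cells, config)
        mask = cells[0].mask(64, config.raster_um)
        n_px = int(mask.sum())
        minor = stacks["12C15N"].counts[:, mask].sum()
        major = stacks["12C14N"].counts[:, mask].sum()
        true_ratio = f / (1 - f)
        expected_minor = n_px * config.cycles * 200.0 * true_ratio
        expected_major = n_px * config.cycles * 200.0
        se = true_ratio * np.sqrt(1 / expected_minor + 1 / expected_major)
        assert abs(minor / major - true_ratio) < 3 * se
        assert true_ratio == pytest.approx(0.003676, abs=1e-6)

    def test_count_conservation(self, small_config):
        cells = place_cells_grid(4, 0.5, small_config)
        stacks, _ = render_ion_stacks(cells, small_config)
        from nanosip.synthetic_data import _mean_images

        means, _ = _mean_images(cells, small_config)
        for sp in stacks:
            expected = means[sp].sum() * small_config.cycles
            observed = stacks[sp].counts.sum()
            assert abs(observed - expected) < 5 * np.sqrt(expected)

    def test_noiseless_round_trip(self, small_config):
        f15 = 0.0421
        f13 = 0.0233
        cells = place_cells_grid(3, 0.5, small_config, f13C=f13, f15N=f15)
        stacks, _ = render_ion_stacks(cells, small_config, noiseless=True)
        mask = cells[0].mask(small_config.pixels, small_config.raster_um)
        ratio_n = (
            stacks["12C15N"].counts[:, mask].sum() / stacks["12C14N"].counts[:, mask].sum()
        )
        ratio_c = (
            stacks["13C12C"].counts[:, mask].sum() / stacks["12C2"].counts[:, mask].sum()
        )
        assert ratio_n / (1 + ratio_n) == pytest.approx(f15, abs=1e-9)
        assert ratio_c / (2 + ratio_c) == pytest.approx(f13, abs=1e-9)

    def test_overlapping_algal_cells_error(self, small_config):
        cells = [
            TruthCell(1, "algal", center=(40.0, 40.0), radii_um=(2.0, 2.0)),
            TruthCell(2, "algal", center=(42.0, 42.0), radii_um=(2.0, 2.0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            render_ion_stacks(cells, small_config)

    def test_cell_outside_raster_rejected(self, small_config):
        cells = [TruthCell(1, "bacterial", center=(500.0, 10.0))]
        with pytest.raises(ValueError, match="outside"):
            render_ion_stacks(cells, small_config)

    def test_accumulated_counts_match_truth_area(self, small_config):
        cells = place_cells_grid(2, 0.5, small_config)
        stacks, truth = render_ion_stacks(cells, small_config, noiseless=True)
        total_cn = accumulate(stacks["12C14N"]).sum()
        n_cell_px = truth["area_px"].sum()
        n_bg_px = small_config.pixels**2 - n_cell_px
        expected = small_config.cycles * (n_cell_px * 200.0 + n_bg_px * 0.5)
        assert total_cn == pytest.approx(expected, rel=1e-12)


class TestKilledAndAxenic:
    def test_killed_truth_at_natural_abundance(self, small_config):
        _, truth = generate_killed_control(small_config, n_cells=10)
        assert np.allclose(truth["f13C_true"], NATURAL_13C_FRACTION)
        assert np.allclose(truth["f15N_true"], NATURAL_15N_FRACTION)

    def test_killed_pipeline_xnet_near_zero(self, small_config, n_substrate):
        from nanosip.isotope_quant import quantify_rois, records_to_frame
        from nanosip.segmentation import classify_and_flag, segment_cn

        stacks, truth = generate_killed_control(small_config, n_cells=12)
        labels = segment_cn(accumulate(stacks["12C14N"]), min_area_px=5)
        rois = classify_and_flag(labels, algal_min_area_px=80, raster_um=20.0)
        records = quantify_rois(stacks, rois, n_substrate)
        df = records_to_frame(records)
        assert abs(df["xnet_N_daily"].median()) < 0.2  # %/day, pure noise

    def test_axenic_enriched_subpopulation(self, small_config):
        _, truth = generate_axenic(
            small_config, n_cells=40, radius_um=1.0, enriched_subpopulation_fraction=0.18
        )
        enriched = truth["f13C_true"] > NATURAL_13C_FRACTION
        assert enriched.sum() == 7  # 18% of 40, rounded


class TestPlacement:
    def test_grid_capacity_error(self, small_config):
        with pytest.raises(ValueError, match="holds only"):
            place_cells_grid(10_000, 1.0, small_config)

    def test_attached_bacterium_near_host(self, small_config):
        host = TruthCell(1, "algal", center=(64.0, 64.0), radii_um=(2.0, 2.0))
        bact = place_attached_bacterium(host, 0.35, small_config, cell_id=2)
        px_per_um = small_config.pixels / small_config.raster_um
        dist = np.hypot(
            bact.center[0] - host.center[0], bact.center[1] - host.center[1]
        )
        boundary_gap = dist - (2.0 + 0.35) * px_per_um
        assert 0.0 <= boundary_gap <= 2.0
        assert bact.attached_to == 1

    def test_invalid_truth_cell(self):
        with pytest.raises(ValueError):
            TruthCell(1, "algal", center=(0, 0), f13C_true=1.5)
        with pytest.raises(ValueError):
            TruthCell(1, "algal", center=(0, 0), radii_um=(0.0, 1.0))
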