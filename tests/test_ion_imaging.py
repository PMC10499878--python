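import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosip.ion_imaging import (
    IonImageStack,
    accumulate,
    apply_shifts,
    correct_dead_time,
    import_tiff_stack,
    ratio_image,
    read_experiment_h5,
    register_cycles,
    write_experiment_h5,
)


def _stack(counts, species="12C14N", **kw):
    return IonImageStack(species=species, counts=np.asarray(counts), **kw)


def _textured_pair(shift):
    """Two-cycle stack where cycle 1 is cycle 0 moved by `shift` (dy, dx)."""
    rng = np.random.default_rng(9)
    base = rng.poisson(50, size=(32, 32)).astype(float)
    base[10:18, 12:20] += 400  # a bright blob so NCC has structure
    dy, dx = shift
    moved = np.zeros_like(base)
    moved[max(dy, 0) : 32 + min(dy, 0), max(dx, 0) : 32 + min(dx, 0)] = base[
        max(-dy, 0) : 32 + min(-dy, 0), max(-dx, 0) : 32 + min(-dx, 0)
    ]
    return _stack(np.stack([base, moved]))


def _ssd_oracle(ref, img, max_shift):
    """Brute-force shift search minimizing SSD over the overlap region."""
    best, best_val = (0, 0), np.inf
    h, w = ref.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys_src = slice(max(-dy, 0), h + min(-dy, 0))
            xs_src = slice(max(-dx, 0), w + min(-dx, 0))
            diff = ref[ys, xs] - img[ys_src, xs_src]
            val = (diff**2).mean()
            if val < best_val - 1e-12:
                best, best_val = (dy, dx), val
    return best


class TestDeadTime:
    def test_identity_at_zero_tau(self):
        stack = _stack(np.random.default_rng(0).poisson(50, (3, 8, 8)))
        out = correct_dead_time(stack, tau_ns=0.0)
        np.testing.assert_array_equal(out.counts, stack.counts)

    def test_hand_arithmetic(self):
        # 100 counts in 1 ms is 1e5 cps; at tau = 44 ns, m*tau = 0.0044
        stack = _stack(np.full((1, 1, 1), 100), dwell_ms=1.0)
        out = correct_dead_time(stack, tau_ns=44.0)
        assert out.counts[0, 0, 0] == pytest.approx(100 / (1 - 0.0044), abs=1e-10)
        assert out.counts[0, 0, 0] == pytest.approx(100.4419, abs=1e-4)

    def test_saturation_error(self):
        # m * tau = 1 exactly: 1e4 counts in 1 ms at tau = 100000 ns
        stack = _stack(np.full((1, 1, 1), 10_000), dwell_ms=1.0)
        with pytest.raises(ValueError, match="saturation"):
            correct_dead_time(stack, tau_ns=100_000.0)

    def test_output_at_least_input(self):
        stack = _stack(np.random.default_rng(1).poisson(80, (2, 16, 16)))
        out = correct_dead_time(stack, tau_ns=44.0)
        assert np.all(out.counts >= stack.counts)

    @given(m1=st.integers(0, 400), m2=st.integers(0, 400))
    @settings(max_examples=50)
    def test_strictly_increasing_in_rate(self, m1, m2):
        lo, hi = sorted((m1, m2))
        stack = _stack(np.array([[[lo, hi]]]), dwell_ms=1.0)
        out = correct_dead_time(stack, tau_ns=44.0)
        if lo < hi:
            assert out.counts[0, 0, 0] < out.counts[0, 0, 1]
        else:
            assert out.counts[0, 0, 0] == out.counts[0, 0, 1]

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            correct_dead_time(_stack(np.zeros((1, 2, 2))), tau_ns=-1.0)


class TestRegistration:
    def test_identical_cycles_zero_shifts(self):
        base = np.random.default_rng(3).poisson(50, (16, 16)).astype(float)
        stacks = {"12C14N": _stack(np.stack([base, base, base]))}
        shifts, _ = register_cycles(stacks, max_shift_px=4)
        assert shifts == [(0, 0), (0, 0), (0, 0)]

    @pytest.mark.parametrize("planted", [(2, -3), (-1, 4), (3, 3)])
    def test_planted_shift_recovered(self, planted):
        stacks = {"12C14N": _textured_pair(planted)}
        shifts, aligned = register_cycles(stacks, max_shift_px=5)
        assert shifts[1] == (-planted[0], -planted[1])
        # oracle: brute-force SSD search agrees
        ref = stacks["12C14N"].counts[0]
        img = stacks["12C14N"].counts[1]
        assert _ssd_oracle(ref, img, 5) == shifts[1]
        # aligned cycle matches the reference away from zero-filled borders
        np.testing.assert_allclose(aligned["12C14N"].counts[1][5:-5, 5:-5],
                                   ref[5:-5, 5:-5])

    def test_flat_images_tie_break_to_zero(self):
        stacks = {"12C14N": _stack(np.full((3, 16, 16), 7.0))}
        shifts, _ = register_cycles(stacks, max_shift_px=4)
        assert shifts == [(0, 0)] * 3

    def test_same_shift_applied_to_all_species(self):
        s = _textured_pair((2, 1))
        stacks = {"12C14N": s, "12C15N": _stack(s.counts * 0.0037)}
        shifts, aligned = register_cycles(stacks, max_shift_px=4)
        assert aligned["12C15N"].cycle_shifts == shifts

    def test_max_shift_too_large(self):
        stacks = {"12C14N": _stack(np.zeros((2, 16, 16)))}
        with pytest.raises(ValueError):
            register_cycles(stacks, max_shift_px=8)

    def test_single_cycle_rejected(self):
        stacks = {"12C14N": _stack(np.zeros((1, 16, 16)))}
        with pytest.raises(ValueError):
            register_cycles(stacks, max_shift_px=2)

    def test_missing_reference_species(self):
        stacks = {"12C2": _stack(np.zeros((2, 16, 16)), species="12C2")}
        with pytest.raises(ValueError, match="reference"):
            register_cycles(stacks, max_shift_px=2)


class TestAccumulate:
    def test_single_cycle_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(accumulate(_stack(img[None])), img)

    def test_two_cycles_of_ones(self):
        stack = _stack(np.ones((2, 4, 4)))
        np.testing.assert_array_equal(accumulate(stack), np.full((4, 4), 2.0))

    def test_conserves_counts_zero_shift(self):
        counts = np.random.default_rng(5).poisson(30, (4, 8, 8))
        assert accumulate(_stack(counts)).sum() == counts.sum()

    def test_registered_peak_height(self):
        """After registration, the accumulated blob peak is cycles x per-cycle peak."""
        base = np.zeros((24, 24))
        base[10, 10] = 100.0
        base[11, 10] = 80.0  # asymmetric texture
        shifted = np.zeros_like(base)
        shifted[12, 13] = 100.0
        shifted[13, 13] = 80.0
        stacks = {"12C14N": _stack(np.stack([base, shifted]))}
        shifts, aligned = register_cycles(stacks, max_shift_px=5)
        acc = accumulate(aligned["12C14N"])
        assert acc[10, 10] == pytest.approx(200.0)


class TestRatioImage:
    def test_equal_images_unit_ratio(self):
        img = np.full((4, 4), 10.0)
        out = ratio_image(img, img, min_denominator_counts=1.0)
        assert np.all(out.values[out.valid_mask] == 1.0)
        assert out.valid_mask.all()

    def test_below_threshold_invalid(self):
        num = np.ones((2, 2))
        den = np.array([[10.0, 0.5], [10.0, 10.0]])
        out = ratio_image(num, den, min_denominator_counts=1.0)
        assert not out.valid_mask[0, 1]
        assert np.isnan(out.values[0, 1])

    def test_natural_abundance_noiseless(self, small_config):
        from nanosip.synthetic_data import generate_killed_control, place_cells_grid, render_ion_stacks

        cells = place_cells_grid(3, 0.5, small_config)
        stacks, _ = render_ion_stacks(cells, small_config, noiseless=True)
        num = accumulate(stacks["12C15N"])
        den = accumulate(stacks["12C14N"])
        out = ratio_image(num, den, min_denominator_counts=1.0)
        mask = cells[0].mask(small_config.pixels, small_config.raster_um)
        np.testing.assert_allclose(out.values[mask], 0.003676, atol=1e-12)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ratio_image(np.ones((2, 2)), np.ones((2, 2)), min_denominator_counts=0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ratio_image(np.ones((2, 2)), np.ones((3, 3)))


class TestIO:
    def test_h5_round_trip(self, tmp_path, small_config):
        from nanosip.synthetic_data import place_cells_grid, render_ion_stacks

        cells = place_cells_grid(3, 0.5, small_config)
        stacks, _ = render_ion_stacks(cells, small_config)
        path = tmp_path / "exp.h5"
        write_experiment_h5(path, stacks, seed=small_config.seed)
        loaded = read_experiment_h5(path)
        assert set(loaded) == {"12C2", "13C12C", "12C14N", "12C15N"}
        for sp in stacks:
            np.testing.assert_array_equal(loaded[sp].counts, stacks[sp].counts)
            assert loaded[sp].raster_um == stacks[sp].raster_um

    def test_tiff_import(self, tmp_path):
        import tifffile

        counts = np.random.default_rng(0).poisson(20, (3, 16, 16)).astype(np.uint16)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, counts, photometric="minisblack")
        stack = import_tiff_stack(path, "12C14N")
        np.testing.assert_array_equal(stack.counts, counts)
        with pytest.raises(ValueError):
            import_tiff_stack(path, "not_a_species")

    def test_apply_shifts_requires_one_per_cycle(self):
        with pytest.raises(ValueError):
            apply_shifts(_stack(np.zeros((3, 4, 4))), [(0, 0)])
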