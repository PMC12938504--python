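"""Frame rendering, registration, binarization, diameter counting, Eq-style compliance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftsim.errors import MeasurementError, PipelineError
from graftsim.imaging import (
    binarize,
    compliance_eq1,
    compliance_pipeline,
    measure_outer_diameter,
    register_frames,
    render_frames,
    station_columns,
    synthetic_compliance_fixture,
)
from graftsim.phantom import PhantomSpec
from graftsim.waveforms import SignalTrace


def _clean_stack(d_mm=4.0, n=3, mmpp=0.01, shape=(600, 40)):
    return render_frames(
        [d_mm] * n, mmpp, frame_shape=shape, frame_rate=30.0
    )


class TestRenderFrames:
    def test_band_height_rounds_to_diameter_in_every_column(self):
        stack = _clean_stack(d_mm=4.009, mmpp=0.01)
        mask = binarize(stack.frames[0])
        counts = mask.sum(axis=0)
        assert np.all(counts == round(4.009 / 0.01))

    def test_band_height_within_one_pixel_for_any_diameter(self):
        for d_mm in (3.791, 4.003, 4.2504):
            stack = _clean_stack(d_mm=d_mm, mmpp=0.01)
            counts = binarize(stack.frames[0]).sum(axis=0)
            assert len(set(counts.tolist())) == 1  # identical in every column
            assert abs(counts[0] - d_mm / 0.01) <= 1.0

    def test_jitter_offsets_recorded_in_metadata(self):
        stack = render_frames(
            [4.0] * 10, 0.01, frame_shape=(600, 40), jitter_px=2.0, seed=5
        )
        assert "jitter_px" in stack.metadata
        assert len(stack.metadata["jitter_px"]) == 10
        assert np.any(stack.metadata["jitter_px"] != 0.0)

    def test_seeded_render_is_deterministic(self):
        kw = dict(mm_per_pixel=0.01, frame_shape=(600, 40), noise_sd=0.05,
                  jitter_px=1.0, seed=9)
        a = render_frames([4.0] * 5, **kw)
        b = render_frames([4.0] * 5, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError):
            render_frames([7.0], 0.01, frame_shape=(600, 40))


class TestRegisterFrames:
    def test_zero_jitter_identity_shifts(self):
        stack = _clean_stack(n=4)
        reg = register_frames(stack)
        assert np.all(reg.metadata["registration_shifts"] == 0)

    def test_known_integer_shifts_recovered(self):
        base = _clean_stack(n=1).frames[0]
        shifts_true = [0, 3, -5, 8]
        frames = np.stack([np.roll(base, s, axis=0) for s in shifts_true])
        stack = _clean_stack(n=4)
        stack.frames = frames
        reg = register_frames(stack)
        got = reg.metadata["registration_shifts"][:, 0]
        assert list(got) == [0, -3, 5, -8]  # correcting shifts negate the applied ones
        for f in reg.frames:
            assert np.array_equal(f, base)

    def test_single_frame_unchanged(self):
        stack = _clean_stack(n=1)
        reg = register_frames(stack)
        assert np.array_equal(reg.frames, stack.frames)

    def test_featureless_stack_warns_and_skips(self):
        stack = _clean_stack(n=3)
        stack.frames = np.zeros_like(stack.frames)
        with pytest.warns(UserWarning):
            reg = register_frames(stack)
        assert np.all(reg.metadata["registration_shifts"] == 0)

    def test_registration_idempotent_within_one_pixel(self):
        stack = render_frames(
            [4.0] * 6, 0.01, frame_shape=(600, 40), jitter_px=3.0, seed=2
        )
        once = register_frames(stack)
        twice = register_frames(once)
        assert np.abs(twice.metadata["registration_shifts"]).max() <= 1

    def test_residual_misalignment_below_one_pixel(self):
        stack = render_frames(
            [4.0] * 8, 0.01, frame_shape=(600, 40), jitter_px=3.0, seed=4
        )
        reg = register_frames(stack)
        est = -reg.metadata["registration_shifts"][:, 0]
        true = stack.metadata["jitter_px"] - stack.metadata["jitter_px"][0]
        assert np.abs(est - true).max() <= 1.0


class TestBinarize:
    def test_two_level_frame_exact_recovery(self):
        stack = _clean_stack()
        truth = stack.frames[0] > 127
        mask = binarize(stack.frames[0])
        # interior pixels recovered exactly; only anti-aliased edge rows differ
        assert np.mean(mask == truth) > 0.995

    def test_noisy_frame_high_pixel_agreement(self):
        clean = _clean_stack(n=1).frames[0]
        noisy = render_frames(
            [4.0], 0.01, frame_shape=(600, 40), noise_sd=0.04, seed=3
        ).frames[0]
        truth = binarize(clean)
        mask = binarize(noisy)
        assert np.mean(mask == truth) >= 0.99

    def test_inverted_contrast_with_polarity_flag(self):
        frame = _clean_stack().frames[0]
        inverted = 255 - frame
        assert np.array_equal(binarize(frame), binarize(inverted, invert=True))

    def test_degenerate_frame_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.full((50, 50), 128, dtype=np.uint8))


class TestMeasureOuterDiameter:
    def test_uniform_band(self):
        mask = np.zeros((600, 40), dtype=np.uint8)
        mask[100:500] = 1  # 400 px tall band
        d, stations = measure_outer_diameter(mask, 0.01)
        assert d == pytest.approx(4.00)
        assert stations == pytest.approx([4.00] * 10)

    def test_tapered_band_frame_value_is_station_mean(self):
        mask = np.zeros((600, 40), dtype=np.uint8)
        cols = station_columns(40, 10)
        heights = np.linspace(100, 500, 40).astype(int)
        for x in range(40):
            mask[:heights[x], x] = 1
        d, stations = measure_outer_diameter(mask, 0.01)
        expected = np.array([heights[c] for c in cols]) * 0.01
        assert stations == pytest.approx(expected)
        assert d == pytest.approx(expected.mean())

    def test_station_placement_avoids_borders(self):
        cols = station_columns(40, 10)
        assert len(cols) == 10
        assert cols[0] > 0 or 0.5 / 10 * 40 >= 1  # (i+0.5)/10 fractions
        assert cols[-1] < 39
        assert np.all(np.diff(cols) == np.diff(cols)[0])  # evenly spaced

    def test_empty_station_column_flagged(self):
        mask = np.zeros((600, 40), dtype=np.uint8)
        mask[100:500, :10] = 1  # band missing from most columns
        with pytest.raises(MeasurementError):
            measure_outer_diameter(mask, 0.01)

    def test_quantization_floor_on_noiseless_fixture(self):
        # per-station diameter error below one pixel without noise/jitter
        stack = _clean_stack(d_mm=4.0037, mmpp=0.01)
        _, stations = measure_outer_diameter(binarize(stack.frames[0]), 0.01)
        assert np.abs(stations - 4.0037).max() <= 0.01


class TestComplianceEq1:
    def test_equal_diameters_give_zero(self):
        assert compliance_eq1(3.2, 3.2, 80.0, 120.0) == 0.0

    @pytest.mark.parametrize(
        "d1,d2,p1,p2,expected",
        [
            # direct two-point evaluation of the bench pressure-diameter rows
            (3.215, 3.224, 52.37, 92.01, 0.706200281538539),
            (3.227, 3.237, 79.67, 120.72, 0.754897301883826),
            (3.242, 3.253, 110.13, 152.67, 0.797594570788267),
        ],
    )
    def test_worked_values(self, d1, d2, p1, p2, expected):
        assert compliance_eq1(d1, d2, p1, p2) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(0.1, 10.0))
    def test_diameter_scale_invariance(self, scale):
        c0 = compliance_eq1(3.2, 3.25, 80.0, 120.0)
        c1 = compliance_eq1(3.2 * scale, 3.25 * scale, 80.0, 120.0)
        assert c1 == pytest.approx(c0, rel=1e-12)

    def test_invalid_pressure_order_rejected(self):
        with pytest.raises(ValueError):
            compliance_eq1(3.2, 3.25, 120.0, 80.0)


@pytest.fixture(scope="module")
def fixture_run():
    stack, pressure, truth = synthetic_compliance_fixture(0.778, seed=0)
    return stack, pressure, truth


class TestCompliancePipeline:
    def test_recovers_ground_truth_compliance(self, fixture_run):
        stack, pressure, truth = fixture_run
        res = compliance_pipeline(stack, pressure, truth["phantom"])
        assert res.C_mean == pytest.approx(0.778, rel=0.02)

    def test_result_internally_consistent(self, fixture_run):
        stack, pressure, truth = fixture_run
        res = compliance_pipeline(stack, pressure, truth["phantom"])
        assert res.DPmin <= res.DPmax
        assert res.Pmin < res.Pmax
        assert res.C == pytest.approx(
            compliance_eq1(res.DPmin, res.DPmax, res.Pmin, res.Pmax), abs=1e-12
        )

    def test_rigid_phantom_reads_near_zero(self):
        # a rigid tube: measured compliance at the quantization floor
        spec = PhantomSpec(inner_diameter_ref=3.2, distension_coeff=0.0,
                           reference_pressure=80.0)
        t = np.arange(int(8 * 50)) / 50.0
        p = 100.0 - 20.0 * np.cos(2 * np.pi * t)
        stack = render_frames(
            np.full(len(t), 4.0), 0.002, frame_rate=50.0, noise_sd=0.01,
            jitter_px=1.0, taper_px=1.0, seed=1,
        )
        tp = np.arange(int(8 * 40)) / 40.0
        pressure = SignalTrace(100.0 - 20.0 * np.cos(2 * np.pi * tp), 40.0)
        res = compliance_pipeline(stack, pressure, spec)
        assert abs(res.C_mean) < 0.08  # well under the smallest real compliance

    def test_normotensive_anchor_diameters_recovered(self):
        # phantom calibrated to the bench anchors reproduces them
        stack, pressure, truth = synthetic_compliance_fixture(
            0.754897301883826, p_min=79.67, p_max=120.72, seed=2,
            inner_diameter=3.227,
        )
        res = compliance_pipeline(stack, pressure, truth["phantom"])
        assert res.DPmin == pytest.approx(3.227, abs=0.003)
        assert res.DPmax == pytest.approx(3.237, abs=0.003)

    def test_too_short_stack_rejected(self):
        stack, pressure, truth = synthetic_compliance_fixture(0.778, duration=3.0, seed=0)
        with pytest.raises(PipelineError):
            compliance_pipeline(stack, pressure, truth["phantom"])
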