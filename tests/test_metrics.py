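"""The penetration readouts: MGV/px, surface, MPD, SCT, Δ and aggregates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from penetrakit.metrics import (
    PenetrationMetrics,
    SurfaceDetectionError,
    SurfaceLine,
    aggregate_group,
    crossing_flags,
    delta_mpd_sct,
    detect_surface,
    mgv_per_px,
    mpd,
    relative_to_reference,
    sct,
    sct_ratio,
)
from penetrakit.synthetic_data import DrugSpec, TissueSpec, cornea_spec, generate_section, skin_spec
from penetrakit.thresholding import RetainedMask, apply_threshold, derive_threshold
from tests.conftest import make_image


def mask_from_grey(grey):
    grey = np.asarray(grey, dtype=float)
    mask = grey > 0
    return RetainedMask(mask=mask, retained_grey=np.where(mask, grey, 0.0), n_retained=int(mask.sum()))


def flat_surface(row, width):
    return SurfaceLine(
        row_by_col=np.full(width, float(row)), valid_cols=np.ones(width, dtype=bool)
    )


class TestMgvPerPx:
    def test_zero_mask_is_zero(self):
        assert mgv_per_px(mask_from_grey(np.zeros((4, 4)))) == 0.0

    def test_small_frame_arithmetic(self):
        assert mgv_per_px(mask_from_grey([[0, 0], [100, 100]])) == pytest.approx(50.0)

    def test_matches_double_loop_oracle(self, rng):
        grey = rng.uniform(0, 255, size=(12, 9)) * rng.integers(0, 2, size=(12, 9))
        mask = mask_from_grey(grey)
        total = 0.0
        for r in range(12):
            for c in range(9):
                total += mask.retained_grey[r, c]
        assert mgv_per_px(mask) == pytest.approx(total / (12 * 9))


class TestDetectSurface:
    def test_noiseless_flat_surface_found_exactly(self):
        spec = TissueSpec(
            height_px=120, width_px=90, surface_row_px=40, surface_roughness_px=0.0,
            sct_um=20.0, noise_sd=0.0,
        )
        img, _ = generate_section(spec, None, seed=0)
        surface = detect_surface(img)
        assert surface.valid_cols.all()
        assert np.all(np.abs(surface.row_by_col - 40) <= 1)

    def test_tissue_filling_whole_frame_gives_row_zero(self):
        img = make_image(np.full((60, 40, 3), 40, dtype=np.uint8))
        surface = detect_surface(img)
        assert np.all(surface.row_by_col == 0)

    def test_all_zero_image_errors(self):
        img = make_image(np.zeros((60, 40, 3), dtype=np.uint8))
        with pytest.raises(SurfaceDetectionError, match="no surface"):
            detect_surface(img)

    def test_noisy_default_sections_within_two_rows(self, small_skin_spec):
        img, truth = generate_section(small_skin_spec, None, seed=9)
        surface = detect_surface(img)
        valid = surface.valid_cols
        assert valid.mean() > 0.9
        err = np.abs(surface.row_by_col[valid] - truth.surface_row_by_col[valid])
        assert np.median(err) <= 2


class TestMpd:
    def test_single_retained_pixel(self):
        grey = np.zeros((100, 10))
        grey[70, 4] = 50.0
        res = mpd(mask_from_grey(grey), flat_surface(40, 10), 1.0)
        assert res.mpd_um == pytest.approx(30.0)
        assert not res.no_signal

    def test_empty_mask_flags_no_signal(self):
        res = mpd(mask_from_grey(np.zeros((20, 10))), flat_surface(5, 10), 1.0)
        assert res.mpd_um == 0.0
        assert res.no_signal

    def test_pixels_above_surface_are_discarded(self):
        grey = np.zeros((50, 6))
        grey[10, 2] = 90.0  # above the surface: exterior junk
        grey[35, 3] = 90.0
        res = mpd(mask_from_grey(grey), flat_surface(30, 6), 2.0)
        assert res.mpd_um == pytest.approx(10.0)  # (35-30) px * 2 um/px
        assert res.n_depths == 1

    def test_deep_fraction_averages_deepest_pixels(self):
        grey = np.zeros((200, 1))
        grey[110:200] = 1.0  # depths 10..99 um below surface row 100
        res = mpd(mask_from_grey(grey), flat_surface(100, 1), 1.0, deep_fraction=0.1)
        # deepest ceil(0.1 * 90) = 9 of the depths 10..99: 91..99 -> mean 95
        assert res.mpd_um == pytest.approx(95.0)

    def test_recovers_generator_truth_on_cornea(self, small_cornea_spec):
        drug = DrugSpec(amplitude=200.0, true_depth_um=50.0)
        img, _ = generate_section(small_cornea_spec, drug, seed=4)
        blanks = [generate_section(small_cornea_spec, None, seed=40 + k)[0] for k in range(3)]
        profile = derive_threshold(blanks)
        res = mpd(apply_threshold(img, profile), detect_surface(img), 1.0)
        assert 45.0 <= res.mpd_um <= 55.0


class TestSct:
    def test_recovers_noiseless_band_thickness(self):
        spec = skin_spec(
            height_px=160, width_px=120, surface_row_px=40,
            surface_roughness_px=0.0, sct_um=29.0, noise_sd=0.0,
        )
        img, _ = generate_section(spec, None, seed=0)
        value = sct(img, detect_surface(img), 1.0)
        assert value == pytest.approx(29.0, abs=1.0)

    def test_no_band_rendered_gives_zero(self):
        spec = skin_spec(
            height_px=160, width_px=120, surface_row_px=40,
            surface_roughness_px=0.0, sct_um=0.0, noise_sd=0.0,
        )
        img, _ = generate_section(spec, None, seed=0, tissue="skin")
        assert sct(img, detect_surface(img), 1.0) == 0.0

    def test_cornea_guard(self, small_cornea_spec):
        img, _ = generate_section(small_cornea_spec, None, seed=1)
        with pytest.raises(ValueError, match="undefined for cornea"):
            sct(img, detect_surface(img), 1.0)


class TestDeltaMpdSct:
    @pytest.mark.parametrize(
        "mpd_um,sct_um,expected",
        [(62, 30, -32), (39, 29, -10), (38, 27, -11), (57, 30, -27), (30, 30, 0)],
    )
    def test_printed_convention(self, mpd_um, sct_um, expected):
        assert delta_mpd_sct(mpd_um, sct_um) == expected

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 500), st.floats(0, 500))
    def test_antisymmetry_and_zero_iff_equal(self, m, s):
        assert delta_mpd_sct(m, s) == -delta_mpd_sct(s, m)
        assert (delta_mpd_sct(m, s) == 0) == (m == s)

    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            delta_mpd_sct(-1, 5)
        with pytest.raises(ValueError):
            delta_mpd_sct(float("nan"), 5)


class TestCrossingFlags:
    @pytest.mark.parametrize(
        "mpd_um,sct_um,expected",
        [(62, 30, (True, False)), (20, 30, (False, False)), (101, 30, (True, True))],
    )
    def test_barrier_criteria(self, mpd_um, sct_um, expected):
        assert crossing_flags(mpd_um, sct_um, epidermis_um=100) == expected

    def test_absent_sct_leaves_crossing_undefined(self):
        crossed, dermis = crossing_flags(50, None)
        assert crossed is None and dermis is False


class TestRelativeToReference:
    def test_reference_is_exactly_100(self):
        rel = relative_to_reference({"a": 1.0, "b": 2.0, "c": 4.0}, "a")
        assert rel == {"a": 100.0, "b": 200.0, "c": 400.0}

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError, match="undefined relative"):
            relative_to_reference({"a": 0.0, "b": 2.0}, "a")


class TestSctRatio:
    @pytest.mark.parametrize("a,b,expected", [(30, 30, 100), (0, 25, 0), (1.33, 1.0, 133)])
    def test_integer_percent(self, a, b, expected):
        assert sct_ratio(a, b) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            sct_ratio(10, 0)


class TestAggregateGroup:
    def test_closed_form_mean_and_sd(self):
        ms = [PenetrationMetrics(mgv_per_px=v, mpd_um=v, sct_um=v) for v in (37.0, 39.0, 41.0)]
        gs = aggregate_group(ms)
        assert gs.mean.mpd_um == pytest.approx(39.0)
        assert gs.sd["mpd_um"] == pytest.approx(2.0)
        assert gs.n_images == 3

    def test_single_image_sd_absent(self):
        gs = aggregate_group([PenetrationMetrics(mgv_per_px=5.0, mpd_um=10.0)])
        assert gs.mean.mgv_per_px == 5.0
        assert gs.sd["mgv_per_px"] is None

    def test_mixed_sct_presence_rejected(self):
        ms = [
            PenetrationMetrics(mgv_per_px=1.0, mpd_um=1.0, sct_um=5.0),
            PenetrationMetrics(mgv_per_px=1.0, mpd_um=1.0, sct_um=None),
        ]
        with pytest.raises(ValueError, match="mixes"):
            aggregate_group(ms)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.uniform(0, 100, size=12)
        ms = [PenetrationMetrics(mgv_per_px=v, mpd_um=2 * v) for v in vals]
        gs = aggregate_group(ms)
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert gs.mean.mgv_per_px == pytest.approx(mean, rel=1e-9)
        assert gs.sd["mgv_per_px"] == pytest.approx(sd, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])


class TestMgvMonotonicity:
    def test_strictly_increasing_in_amplitude_noiseless(self):
        spec = cornea_spec(
            height_px=140, width_px=100, surface_row_px=40,
            surface_roughness_px=0.0, noise_sd=0.0,
        )
        values = []
        for amp in (20.0, 60.0, 120.0, 200.0):
            img, _ = generate_section(spec, DrugSpec(amplitude=amp, true_depth_um=40.0), seed=2)
            values.append(mgv_per_px(apply_threshold(img, None)))
        assert all(a < b for a, b in zip(values, values[1:]))
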