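"""Flow statistics: region series, A-P profiles, compression, coherence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexflow.flows import (
    ANTERIOR_CORTEX,
    POSTERIOR_CORTEX,
    RegionSpec,
    ap_profile,
    build_kymograph,
    compression_profile,
    compression_rate,
    cosine_similarity,
    cosine_vs_distance,
    pixel_to_position,
    region_velocity_series,
)
from cortexflow.imagestack import ImageSequence
from cortexflow.simulate import DEFAULT_PIXEL_SIZE_UM

from conftest import make_field, make_series


class TestPixelCalibration:
    @pytest.mark.parametrize(
        "index,expected",
        [(108, 19.2), (109, 19.4), (192, 34.1), (1, 0.2)],
    )
    def test_subregion_bounds(self, index, expected):
        """The anterior/posterior sub-region bounds in um."""
        assert pixel_to_position(index) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pixel_to_position(0)
        with pytest.raises(ValueError):
            pixel_to_position(193)

    def test_standard_regions_tile_the_roi(self):
        assert ANTERIOR_CORTEX.um_span == (0.2, 19.2)
        assert POSTERIOR_CORTEX.um_span == (19.4, 34.1)
        with pytest.raises(ValueError):
            RegionSpec("bad", (0, 10))


class TestRegionVelocitySeries:
    def test_uniform_field_reported_exactly(self):
        fld = make_field(np.full((4, 16), -3.0), spacing_um=2.0)
        df = region_velocity_series(make_series([fld, fld]))
        assert np.allclose(df.vx_um_min, -3.0)

    def test_hand_built_field_means(self):
        # anchors at 2,4 um (anterior) and 22,24 um (posterior)
        vx = np.array([[1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 9.0, 11.0]])
        fld = make_field(vx, spacing_um=2.0)
        fld.x_px = np.array([1.0, 3.0, 21.0, 23.0])  # x_um = 2, 4, 22, 24
        df = region_velocity_series(make_series([fld]))
        ant = df[df.region == "anterior_cortex"].vx_um_min.iloc[0]
        post = df[df.region == "posterior_cortex"].vx_um_min.iloc[0]
        assert ant == pytest.approx(np.mean([1, 2, 3, 4]))
        assert post == pytest.approx(np.mean([5, 7, 9, 11]))

    def test_empty_region_gives_missing_not_zero(self):
        fld = make_field(np.full((2, 3), 1.0), spacing_um=2.0)  # x_um up to 6
        df = region_velocity_series(make_series([fld]))
        post = df[df.region == "posterior_cortex"]
        assert post.vx_um_min.isna().all()

    def test_alignment_shifts_timestamps(self):
        fld = make_field(np.ones((2, 2)))
        df = region_velocity_series(make_series([fld, fld], dt_s=5.0), align_event_s=5.0)
        assert sorted(df.t_s.unique()) == [-5.0, 0.0]


class TestApProfile:
    def test_uniform_field_flat_profile(self):
        fld = make_field(np.full((3, 8), -2.5))
        prof = ap_profile(make_series([fld, fld]), 0.0, 50.0)
        np.testing.assert_allclose(prof.mean_vx_um_min, -2.5)

    def test_linear_field_linear_profile(self):
        x_um = np.arange(1, 9) * 2.0
        vx = np.tile(-0.3 * x_um, (3, 1))
        fld = make_field(vx, spacing_um=2.0)
        prof = ap_profile(make_series([fld]), 0.0, 50.0)
        slope = np.polyfit(prof.positions_um, prof.mean_vx_um_min, 1)[0]
        assert slope == pytest.approx(-0.3, abs=1e-12)

    def test_dv_independent_field_equals_x_section(self):
        row = np.array([1.0, -2.0, 3.5, 0.0, -1.0])
        fld = make_field(np.tile(row, (4, 1)))
        prof = ap_profile(make_series([fld]), 0.0, 50.0)
        np.testing.assert_allclose(prof.mean_vx_um_min, row, atol=1e-12)
        np.testing.assert_allclose(prof.sem_um_min, 0.0, atol=1e-12)

    def test_empty_window_rejected(self):
        fld = make_field(np.ones((2, 2)))
        with pytest.raises(ValueError, match="window"):
            ap_profile(make_series([fld]), 100.0, 50.0)


class TestCompressionRate:
    def test_uniform_flow_zero_everywhere(self):
        x = np.arange(10) * 2.0
        np.testing.assert_array_equal(compression_rate(x, np.full(10, -3.0)), 0.0)

    def test_linear_profile_constant_rate(self):
        """Vx = -a*x (um/min) gives rate a/60 s^-1 uniformly, machine precision."""
        x = np.arange(12) * 3.0
        a = 0.9
        rate = compression_rate(x, -a * x)
        np.testing.assert_allclose(rate, a / 60.0, rtol=1e-14)

    def test_piecewise_profile_matches_hand_central_differences(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        v = np.array([0.0, 0.0, -6.0, -12.0, -12.0])  # um/min
        rate = compression_rate(x, v)
        # hand-computed: one-sided ends, central interior, v in um/s
        expected = -np.array([0.0, -3.0, -6.0, -3.0, 0.0]) / 60.0
        np.testing.assert_allclose(rate, expected, atol=1e-15)

    def test_telescoping_integral_consistency(self):
        rng = np.random.default_rng(5)
        x = np.arange(15) * 1.5  # uniform grid, as produced by PIV
        v = rng.normal(size=15)
        rate = compression_rate(x, v)
        # trapezoid integral of -dVx/dx telescopes to Vx(start) - Vx(end)
        integral = np.trapezoid(rate, x)
        assert integral == pytest.approx((v[0] - v[-1]) / 60.0, abs=1e-12)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            compression_rate(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="increasing"):
            compression_rate(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_converging_profile_positive_in_equatorial_band(self):
        x_um = np.arange(1, 18) * 2.0  # 2..34 um
        vx = np.tile(-4.5 / (1 + np.exp(-(x_um - 17.0) / 4.0)), (3, 1))
        fld = make_field(vx, spacing_um=2.0)
        series = make_series([fld] * 22, dt_s=5.0)  # timestamps reach 105 s
        prof = compression_profile(series)
        assert prof.rates_s.shape[0] == 7  # 10-s bins from 25 to 95 s
        assert np.all(prof.equatorial_mean_s > 0)


class TestCosineSimilarity:
    def test_paper_anchor_identity(self):
        v = np.array([2.0, -1.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_antiparallel_and_orthogonal(self):
        assert cosine_similarity((1, 2), (-1, -2)) == pytest.approx(-1.0)
        assert cosine_similarity((1, 0), (0, 1)) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity((0, 0), (1, 1))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        vx=st.floats(-100, 100), vy=st.floats(-100, 100),
        wx=st.floats(-100, 100), wy=st.floats(-100, 100),
        a=st.floats(0.01, 100), b=st.floats(0.01, 100),
    )
    def test_symmetric_scale_invariant_bounded(self, vx, vy, wx, wy, a, b):
        v, w = np.array([vx, vy]), np.array([wx, wy])
        if np.linalg.norm(v) < 1e-6 or np.linalg.norm(w) < 1e-6:
            return
        c = cosine_similarity(v, w)
        assert -1.0 - 1e-9 <= c <= 1.0 + 1e-9
        assert c == pytest.approx(cosine_similarity(w, v))
        assert c == pytest.approx(cosine_similarity(a * v, b * w), abs=1e-6)


class TestCosineVsDistance:
    def test_uniform_field_curve_is_one(self):
        fld = make_field(np.full((3, 6), -2.0))
        curve = cosine_vs_distance(make_series([fld]))
        np.testing.assert_allclose(curve.mean_cosine, 1.0, atol=1e-12)
        assert np.all(curve.distance_um > 0)  # self-pair bin excluded

    def test_opposite_halves_far_bins_approach_minus_one(self):
        vx = np.ones((2, 12))
        vx[:, 6:] = -1.0
        fld = make_field(vx, spacing_um=2.0)
        curve = cosine_vs_distance(make_series([fld]))
        assert curve.mean_cosine[-1] == pytest.approx(-1.0)
        assert curve.mean_cosine[0] > 0.5

    def test_three_vector_toy_matches_brute_force(self):
        # vectors at x_um = 2, 4, 6 on one row
        fld = make_field(np.array([[1.0, 1.0, -1.0]]), spacing_um=2.0)
        fld.vy = np.array([[0.0, 1.0, 0.0]])
        curve = cosine_vs_distance(make_series([fld]), bin_width_um=2.0)
        c01 = cosine_similarity((1, 0), (1, 1))
        c12 = cosine_similarity((1, 1), (-1, 0))
        c02 = cosine_similarity((1, 0), (-1, 0))
        np.testing.assert_allclose(
            curve.mean_cosine, [np.mean([c01, c12]), c02], atol=1e-12
        )
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_zero_vectors_excluded_and_tallied(self):
        vx = np.array([[0.0, 1.0, 1.0]])
        fld = make_field(vx, spacing_um=2.0)
        curve = cosine_vs_distance(make_series([fld]))
        assert curve.n_zero_excluded == 1
        assert curve.n_pairs.sum() == 1


class TestKymograph:
    def _movie(self, frames):
        return ImageSequence(
            np.asarray(frames, float),
            pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
            frame_interval_s=5.0,
        )

    def test_static_movie_columns_identical(self):
        rng = np.random.default_rng(0)
        frame = rng.random((32, 180)) * 100
        movie = self._movie([frame] * 6)
        kymo = build_kymograph(movie, strip=(10, 14, 150, 5))
        assert kymo.data.shape == (150, 6)
        for col in range(1, 6):
            np.testing.assert_array_equal(kymo.data[:, col], kymo.data[:, 0])

    def test_moving_particle_traces_line_of_programmed_slope(self):
        n_frames, vx = 8, 3.0  # px/frame
        frames = np.zeros((n_frames, 32, 180))
        for f in range(n_frames):
            frames[f, 14:19, int(20 + vx * f)] = 100.0
        kymo = build_kymograph(self._movie(frames), strip=(0, 14, 180, 5))
        peaks = kymo.data.argmax(axis=0)
        slopes = np.diff(peaks)
        np.testing.assert_array_equal(slopes, vx)

    def test_strip_outside_frame_rejected(self):
        movie = self._movie(np.zeros((2, 32, 100)))
        with pytest.raises(ValueError, match="strip"):
            build_kymograph(movie, strip=(0, 30, 100, 5))
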