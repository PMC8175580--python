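import numpy as np
import pytest

from minslab.patterns import (AnalysisError, MovieStack, classify_correlation,
                              classify_pattern, classify_pattern_kymo,
                              correct_stack, pair_correlation_1d,
                              spatial_wavelength, temporal_period,
                              temporal_period_kymo, topbottom_correlation)
from minslab.synthetic import ArtifactSpec, WaveSpec, add_artifacts, gen_pair, gen_stack


def stack_of(cls, wavelength=50.0, period=120.0, **kw):
    return gen_stack(WaveSpec(wave_class=cls, wavelength=wavelength,
                              period=period, **kw))


class TestSpatialWavelength:
    def test_plane_sinusoid_recovered_within_one_pixel(self):
        st = stack_of("traveling", wavelength=50.0, duration=600)
        assert spatial_wavelength(st) == pytest.approx(50.0, abs=1.0)

    def test_rotation_invariance(self):
        a = stack_of("traveling", wavelength=50.0, duration=600)
        b = stack_of("traveling", wavelength=50.0, duration=600,
                     direction=np.deg2rad(37))
        wa, wb = spatial_wavelength(a), spatial_wavelength(b)
        assert wa == pytest.approx(wb, abs=1.0)

    def test_pixel_size_equivariance(self):
        """Rescaling the pixel size rescales the output exactly."""
        st = stack_of("traveling", wavelength=50.0, duration=600)
        st2 = MovieStack(st.data, pixel_size=2.0, frame_interval=st.frame_interval)
        assert spatial_wavelength(st2) == pytest.approx(2 * spatial_wavelength(st))

    def test_white_noise_rarely_detects_a_wavelength(self):
        detections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            st = MovieStack(rng.normal(100, 5, (10, 64, 64)), 1.0, 30.0)
            if spatial_wavelength(st) is not None:
                detections += 1
        assert detections <= 5


class TestTemporalPeriod:
    def test_uniform_oscillation(self):
        st = stack_of("homogeneous", period=120.0, frame_interval=30.0,
                      duration=1200)
        assert temporal_period(st) == pytest.approx(120.0, abs=30.0)

    def test_static_stack_gives_none(self):
        st = MovieStack(np.full((20, 64, 64), 50.0), 1.0, 30.0)
        assert temporal_period(st) is None

    def test_period_invariant_under_phase_gradient(self):
        """Phase waves share the period of the uniform oscillation."""
        uni = stack_of("homogeneous", period=120.0, duration=1200)
        pw = gen_stack(WaveSpec(wave_class="phase_wave", period=120.0,
                                duration=1200, phase_gradient=0.03))
        assert temporal_period(pw) == pytest.approx(temporal_period(uni), abs=30.0)

    def test_frame_interval_equivariance(self):
        st = stack_of("homogeneous", period=120.0, duration=1200)
        st2 = MovieStack(st.data, st.pixel_size, frame_interval=60.0)
        assert temporal_period(st2) == pytest.approx(2 * temporal_period(st))


class TestCorrection:
    def test_clean_stack_passes_through(self):
        st = stack_of("traveling", duration=1200)
        out = correct_stack(st)
        a = (out.data - out.data.mean()).ravel()
        b = (st.data - st.data.mean()).ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.999

    def test_correction_formula_instance(self):
        """(movie − static)/illum: 100 = (100 − 20)/0.8 for one pixel."""
        assert (100.0 - 20.0) / 0.8 == pytest.approx(100.0)

    def test_artifact_round_trip(self):
        """Vignette + specks + 20% bleach + noise are removed to < 5% RMSE
        of the wave amplitude."""
        spec = WaveSpec(wave_class="traveling", wavelength=50, period=120,
                        duration=1500, frame_interval=30, seed=2)
        clean = gen_stack(spec)
        dirty = add_artifacts(clean, ArtifactSpec(seed=3))
        corr = correct_stack(dirty)
        c = corr.data - corr.data.mean(axis=0, keepdims=True)
        cl = clean.data - clean.data.mean(axis=0, keepdims=True)
        scale = (c * cl).sum() / (c * c).sum()
        rmse = np.sqrt(np.mean((scale * c - cl) ** 2))
        assert rmse / spec.amplitude < 0.05

    def test_too_few_frames_rejected(self):
        st = MovieStack(np.ones((5, 32, 32)), 1.0, 30.0)
        with pytest.raises(AnalysisError, match="10 frames"):
            correct_stack(st)


class TestTopBottomCorrelation:
    def test_identical_planes_fully_correlated(self):
        top, bottom = gen_pair(WaveSpec(wave_class="traveling", duration=900),
                               phase_shift=0.0, decorrelate=0.0)
        rep = topbottom_correlation(top, bottom, cell_size=10.0)
        assert rep.fractions["correlated"] == 1.0
        assert np.nanmin(rep.correlations) > 0.999

    def test_antiphase_planes_anticorrelated(self):
        top, bottom = gen_pair(WaveSpec(wave_class="traveling", duration=900),
                               phase_shift=np.pi, decorrelate=0.0)
        rep = topbottom_correlation(top, bottom, cell_size=10.0)
        assert rep.fractions["anticorrelated"] == 1.0

    def test_independent_noise_uncorrelated(self):
        # window length sets the sampling floor: E|r| ~ sqrt(2/(pi*T)) = 0.08
        rng = np.random.default_rng(0)
        shape = (100, 140, 140)
        top = MovieStack(rng.normal(100, 10, shape), 1.0, 30.0)
        bottom = MovieStack(rng.normal(100, 10, shape), 1.0, 30.0)
        rep = topbottom_correlation(top, bottom, cell_size=10.0)
        vals = rep.values
        assert len(vals) >= 190
        assert np.abs(vals).mean() < 0.1
        assert rep.fractions["correlated"] < 0.05
        assert rep.fractions["anticorrelated"] < 0.05

    def test_symmetry_in_plane_order(self):
        top, bottom = gen_pair(WaveSpec(wave_class="traveling", duration=900),
                               phase_shift=1.0, decorrelate=0.3, seed=4)
        r1 = topbottom_correlation(top, bottom, cell_size=10.0)
        r2 = topbottom_correlation(bottom, top, cell_size=10.0)
        np.testing.assert_array_equal(r1.correlations, r2.correlations)

    def test_constant_cells_are_excluded(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100, 5, (30, 20, 20))
        b = rng.normal(100, 5, (30, 20, 20))
        a[:, :10, :10] = 50.0  # one constant cell
        b[:, :10, :10] = 60.0
        top = MovieStack(a, 1.0, 30.0)
        bottom = MovieStack(b, 1.0, 30.0)
        rep = topbottom_correlation(top, bottom, cell_size=10.0)
        assert rep.n_undefined == 1
        assert len(rep.values) == 3

    def test_mismatched_calibration_rejected(self):
        a = MovieStack(np.ones((12, 20, 20)), 1.0, 30.0)
        b = MovieStack(np.ones((12, 20, 20)), 0.5, 30.0)
        with pytest.raises(AnalysisError):
            topbottom_correlation(a, b)


class TestClassifyCorrelation:
    def test_threshold_arithmetic(self):
        f = classify_correlation([0.9, -0.5, 0.1])
        assert f == {"correlated": pytest.approx(1 / 3),
                     "anticorrelated": pytest.approx(1 / 3),
                     "neither": pytest.approx(1 / 3)}

    def test_all_ones(self):
        f = classify_correlation(np.ones(10))
        assert f["correlated"] == 1.0

    def test_boundary_values_are_neither(self):
        f = classify_correlation([0.7, -0.3])
        assert f["neither"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        f = classify_correlation(rng.uniform(-1, 1, 100))
        assert sum(f.values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            classify_correlation([])


class TestClassifyPattern:
    @pytest.mark.parametrize("cls,expect", [
        ("traveling", "traveling_wave"),
        ("standing", "standing_wave"),
        ("homogeneous", "homogeneous_oscillation"),
    ])
    def test_generator_classes_recovered(self, cls, expect):
        st = stack_of(cls, wavelength=28.0, period=120.0, duration=1200,
                      shape=(192, 192))
        assert classify_pattern(st).pattern_class == expect

    def test_static_input_indeterminate(self):
        st = MovieStack(np.full((20, 64, 64), 10.0), 1.0, 30.0)
        lab = classify_pattern(st)
        assert lab.pattern_class == "indeterminate"

    def test_too_short_movie_indeterminate(self):
        st = stack_of("traveling", period=120.0, duration=240.0)
        lab = classify_pattern(st)
        assert lab.pattern_class == "indeterminate"

    def test_kymograph_traveling_wave(self):
        x = (np.arange(160) + 0.5) * 0.5
        t = np.arange(0, 120, 1.0)
        kymo = 10 + np.cos(2 * np.pi / 20 * x[:, None] - 2 * np.pi / 15 * t[None, :])
        lab = classify_pattern_kymo(kymo, 0.5, 1.0)
        assert lab.pattern_class == "traveling_wave"


class TestPairCorrelation1D:
    def test_inphase_and_antiphase(self):
        x = (np.arange(120) + 0.5) * 0.5
        t = np.arange(0, 100, 1.0)
        wave = 10 + np.cos(2 * np.pi / 15 * x[:, None] - 0.4 * t[None, :]).T
        rep = pair_correlation_1d(wave, wave, 0.5, 1.0, cell_size=10.0)
        assert rep.fractions["correlated"] == 1.0
        rep2 = pair_correlation_1d(wave, 20 - wave + 0.0, 0.5, 1.0, cell_size=10.0)
        assert rep2.fractions["anticorrelated"] == 1.0
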