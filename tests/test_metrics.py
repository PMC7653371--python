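import itertools

import numpy as np
import pytest

import suturemetrics as sm
from suturemetrics.metrics import EstimationError
from conftest import rigid_transform


def signal_of(values):
    return sm.DeviationSignal(values=np.asarray(values, float), chord_length=1.0)


class TestSinuosityIndex:
    def test_collinear_is_exactly_one(self):
        pts = np.column_stack([np.linspace(0, 7, 23), np.linspace(0, 7, 23) * 2])
        assert sm.sinuosity_index(pts) == 1.0

    def test_one_iff_collinear_on_integer_grid(self):
        # brute-force collinearity oracle over all 3-point configurations
        grid = list(itertools.product(range(3), range(3)))
        for a, b, c in itertools.product(grid, repeat=3):
            pts = np.array([a, b, c], dtype=float)
            if np.array_equal(pts[0], pts[2]):
                continue  # no chord
            u, v = pts[1] - pts[0], pts[2] - pts[0]
            cross = u[0] * v[1] - u[1] * v[0]
            mono = np.dot(pts[1] - pts[0], pts[2] - pts[1]) >= 0
            collinear = cross == 0 and mono  # b between a and c, in order
            si = sm.sinuosity_index(pts)
            if collinear:
                assert si == 1.0
            else:
                assert si > 1.0 + 1e-12

    def test_dense_semicircle_is_half_pi(self, semicircle):
        assert sm.sinuosity_index(semicircle.coords) == pytest.approx(np.pi / 2, abs=1e-4)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(sm.DegenerateChordError):
            sm.sinuosity_index(np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]]))

    def test_similarity_invariant(self, sine_wave, rng):
        si = sm.sinuosity_index(sine_wave.coords)
        for _ in range(5):
            moved = rigid_transform(
                sine_wave.coords, rng.uniform(0, 2 * np.pi), rng.uniform(-9, 9, 2), rng.uniform(0.1, 10)
            )
            assert abs(sm.sinuosity_index(moved) - si) < 1e-6


class TestDetectLobes:
    def test_flat_signal_has_no_lobes(self):
        assert sm.detect_lobes(signal_of(np.zeros(100))) == (0, 0)

    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_pure_sine_counts_every_extremum_as_major(self, k):
        t = np.linspace(0, 1, 1000)
        sig = signal_of(np.sin(2 * np.pi * k * t))
        assert sm.detect_lobes(sig) == (2 * k, 0)

    def test_two_scale_signal_separates_major_and_minor(self):
        # amplitude-1 carrier with an amplitude-0.2 ripple: the ripple's
        # extrema are prominent at ~0.4, between the thresholds
        t = np.linspace(0, 1, 4000)
        sig = signal_of(np.sin(2 * np.pi * 3 * t) + 0.2 * np.sin(2 * np.pi * 40 * t))
        major, minor = sm.detect_lobes(sig, major_frac=0.5, minor_frac=0.05)
        assert major == 6
        assert minor > 20

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            sm.detect_lobes(signal_of(np.ones(10)), major_frac=0.1, minor_frac=0.5)


class TestComplexityFactor:
    def test_zero_lobe_baseline(self):
        assert sm.complexity_factor(0, 0) == pytest.approx(0.2)

    def test_strictly_increasing_in_each_count(self):
        for m, k in itertools.product(range(21), range(21)):
            assert sm.complexity_factor(m + 1, k) > sm.complexity_factor(m, k)
            assert sm.complexity_factor(m, k + 1) > sm.complexity_factor(m, k)

    def test_sci_is_bilinear_product(self):
        assert sm.suture_complexity_index(1.0, 3.7) == pytest.approx(3.7)
        assert sm.suture_complexity_index(2.0, 3.7) == pytest.approx(2 * 3.7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sm.complexity_factor(-1, 0)


class TestFdBoxcount:
    def test_straight_line_dimension_one(self):
        t = np.linspace(0, 1, 500)
        assert sm.fd_boxcount(signal_of(0.3 * t * (1 - t))).estimate == pytest.approx(1.0, abs=0.05)
        # sloped but smooth tent profile
        tent = np.minimum(t, 1 - t)
        assert sm.fd_boxcount(signal_of(tent)).estimate == pytest.approx(1.0, abs=0.05)

    def test_koch_profile_matches_theory(self):
        curve = sm.resample_equidistant(sm.koch_profile(4), 512)
        sig = sm.deviation_signal(curve.coords)
        assert sm.fd_boxcount(sig).raw == pytest.approx(np.log(4) / np.log(3), abs=0.08)

    def test_short_signal_rejected(self):
        with pytest.raises(EstimationError):
            sm.fd_boxcount(signal_of(np.zeros(32)))


class TestFdMadogram:
    def test_linear_ramp_dimension_one(self):
        tent = np.minimum(np.linspace(0, 1, 512), np.linspace(1, 0, 512))
        fd = sm.fd_madogram(signal_of(tent))
        assert fd.estimate == pytest.approx(1.0, abs=0.05)
        assert fd.hurst == pytest.approx(1.0, abs=0.05)

    def test_brownian_motion_dimension(self):
        # D = 2 - H identity under simulation at H = 0.5
        ds = [sm.fd_madogram(sm.generate_fbm(0.5, 1024, seed=s)).raw for s in range(100)]
        assert np.mean(ds) == pytest.approx(1.5, abs=0.05)

    def test_constant_signal_flagged_degenerate(self):
        fd = sm.fd_madogram(signal_of(np.zeros(256)))
        assert fd.estimate == 1.0
        assert fd.degenerate

    def test_clamped_into_unit_interval(self):
        for s in range(5):
            sig = sm.generate_fbm(0.1, 256, seed=s)
            fd = sm.fd_madogram(sig)
            assert 1.0 <= fd.estimate <= 2.0

    def test_bad_lag_rejected(self):
        with pytest.raises(ValueError):
            sm.fd_madogram(signal_of(np.zeros(256)), max_lag=200)


class TestStft:
    def test_zero_signal_zero_coefficients(self):
        m = sm.stft(signal_of(np.zeros(200)), window_length=50, hop=25)
        assert np.abs(m.coefficients).max() == 0.0
        assert m.windows == (200 - 50) // 25 + 1

    def test_single_window_equals_direct_dft(self, rng):
        v = rng.standard_normal(128)
        m = sm.stft(signal_of(v), window_length=128, hop=128, taper="boxcar")
        assert m.windows == 1
        np.testing.assert_allclose(m.coefficients[0], np.fft.rfft(v), atol=1e-10)

    def test_integer_bin_sine_concentrates_energy(self):
        n, w = 400, 100
        t = np.arange(n)
        v = np.sin(2 * np.pi * 5 * t / w)  # exactly bin 5 of each window
        m = sm.stft(signal_of(v), window_length=w, hop=w // 2, taper="boxcar")
        power = np.abs(m.coefficients) ** 2
        assert np.all(power[:, 5] / power.sum(axis=1) > 0.99)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            sm.stft(signal_of(np.zeros(30)), window_length=50)


class TestPsdScore:
    def test_zero_signal_zero_score(self):
        m = sm.stft(signal_of(np.zeros(500)))
        assert sm.psd_score(m) == 0.0

    def test_quadratic_amplitude_scaling(self, rng):
        v = rng.standard_normal(500)
        raw = sm.psd_score(sm.stft(signal_of(v)))
        scaled = sm.psd_score(sm.stft(signal_of(3.0 * v)))
        assert scaled == pytest.approx(9.0 * raw, rel=1e-12)

    def test_log10_normalization_monotone(self, rng):
        v = rng.standard_normal(500)
        m = sm.stft(signal_of(v))
        raw = sm.psd_score(m, "raw")
        assert sm.psd_score(m, "log10") == pytest.approx(np.log10(1 + raw))


class TestComputeAll:
    def test_straight_segment_record(self, straight_curve):
        rec = sm.compute_all(straight_curve)
        assert rec.si == 1.0
        assert rec.fd_box == pytest.approx(1.0, abs=0.05)
        assert rec.fd_mad == pytest.approx(1.0, abs=0.05)
        assert rec.psd == pytest.approx(0.0, abs=1e-12)
        assert (rec.major_lobes, rec.minor_lobes) == (0, 0)
        assert rec.sci == pytest.approx(0.2)

    def test_deterministic(self, sine_wave):
        a = sm.compute_all(sine_wave)
        b = sm.compute_all(sine_wave)
        assert a == b

    def test_rigid_motion_invariance_of_all_scores(self, sine_wave, rng):
        base = sm.compute_all(sine_wave)
        moved = rigid_transform(sine_wave.coords, rng.uniform(0, 2 * np.pi), rng.uniform(-4, 4, 2))
        rec = sm.compute_all(sine_wave.with_coords(moved))
        assert rec.si == pytest.approx(base.si, abs=1e-9)
        assert rec.sci == pytest.approx(base.sci, abs=1e-6)
        assert rec.fd_box == pytest.approx(base.fd_box, abs=1e-6)
        assert rec.fd_mad == pytest.approx(base.fd_mad, abs=1e-6)
        assert rec.psd == pytest.approx(base.psd, rel=1e-6)

    def test_scale_invariance_of_si_and_fd(self, sine_wave):
        base = sm.compute_all(sine_wave)
        scaled = sm.compute_all(sine_wave.with_coords(sine_wave.coords * 37.0))
        assert scaled.si == pytest.approx(base.si, abs=1e-9)
        assert scaled.fd_box == pytest.approx(base.fd_box, abs=1e-9)
        assert scaled.fd_mad == pytest.approx(base.fd_mad, abs=1e-9)

    def test_error_carries_specimen_id(self):
        loop = sm.LandmarkCurve("ring", [(0, 0), (1, 1), (0, 1), (0, 0)])
        resampled = sm.resample_equidistant(loop, 128)
        with pytest.raises(sm.DegenerateChordError, match="ring"):
            sm.compute_all(resampled)


class TestMonotonicity:
    def test_si_and_psd_increase_with_amplitude(self):
        scores = []
        for amp in (0.02, 0.05, 0.1, 0.2):
            c = sm.generate_suture(sm.SutureParams(amplitude=amp, frequency=8, seed=3))
            rec = sm.compute_all(c.with_coords(sm.center_and_scale(c.coords)))
            scores.append((rec.si, rec.psd))
        sis, psds = zip(*scores)
        assert all(b > a for a, b in zip(sis, sis[1:]))
        assert all(b > a for a, b in zip(psds, psds[1:]))

    def test_major_lobes_increase_with_frequency(self):
        counts = []
        for freq in (4, 8, 16):
            c = sm.generate_suture(sm.SutureParams(amplitude=0.05, frequency=freq, seed=3))
            counts.append(sm.compute_all(c).major_lobes)
        assert counts == [8, 16, 32]
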