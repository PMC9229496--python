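"""Signal construction, conditioning, and extrema detection.

The extrema detector is checked against an independent brute-force oracle
that re-derives local extrema, prominence (by its definition: height above
the higher of the two lowest descents to higher ground), the spacing rule
(drop the lower of two peaks closer than the minimum separation, higher
peaks claiming their window first) and the max/min alternation cleanup.
"""

import numpy as np
import pytest

from gaitstage.errors import (
    DegenerateSignalError,
    GridMismatchError,
    InsufficientCyclesError,
    NonUniformGridError,
    NoOverlapError,
    OutOfSupportError,
)
from gaitstage.io_keypoints import LandmarkTrack
from gaitstage.signals import (
    GaitSignal,
    build_type1,
    build_type2,
    fft_denoise,
    find_extrema,
    normalize_amplitude,
    overlap_window,
    resample_to_grid,
)


def _sig(values, dt=0.01, **kw):
    values = np.asarray(values, dtype=float)
    return GaitSignal(kind="synthetic", times=np.arange(len(values)) * dt, values=values, **kw)


def _track(name, times, x, y=None):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return LandmarkTrack(name=name, times=np.asarray(times, dtype=float), x=x, y=y)


class TestBuildType1:
    def test_antiphase_sines_double(self):
        t = np.linspace(0, 3, 301)
        left = _track("LAnkle", t, np.sin(2 * np.pi * t))
        right = _track("RAnkle", t, -np.sin(2 * np.pi * t))
        sig = build_type1(left, right)
        np.testing.assert_allclose(sig.values, 2 * np.sin(2 * np.pi * t), atol=1e-12)

    def test_identical_tracks_degenerate(self):
        t = np.linspace(0, 1, 50)
        track = _track("LAnkle", t, np.sin(t))
        with pytest.raises(DegenerateSignalError):
            build_type1(track, _track("RAnkle", t, np.sin(t)))

    def test_grid_mismatch_instructs_resample(self):
        a = _track("LAnkle", np.linspace(0, 1, 50), np.sin(np.linspace(0, 1, 50)))
        b = _track("RAnkle", np.linspace(0, 1, 60), np.cos(np.linspace(0, 1, 60)))
        with pytest.raises(GridMismatchError, match="resample"):
            build_type1(a, b)

    def test_simulator_peak_to_peak_is_twice_step_amplitude(self, normal_series):
        from gaitstage.io_keypoints import select_landmarks
        from gaitstage.synthesis import normal_gait

        la, ra = select_landmarks(normal_series, ["LAnkle", "RAnkle"], gap_policy="drop")
        sig = build_type1(la, ra)
        amp = normal_gait().step_amplitude_px
        # T1 = 2A sin(2 pi f t); jitter of a few px rides on top
        assert np.ptp(sig.values) == pytest.approx(4 * amp, rel=0.1)


class TestBuildType2:
    def test_constant_y_gives_all_zero(self):
        track = _track("LHeel", np.linspace(0, 1, 20), np.zeros(20), y=np.full(20, 440.0))
        sig = build_type2(track)
        np.testing.assert_array_equal(sig.values, 0.0)

    def test_image_down_flip_puts_ground_contact_at_minima(self):
        # image coords: foot at its lowest (largest y) at integer t
        t = np.linspace(0, 3, 601)
        y = 500 - 30 * np.abs(np.sin(np.pi * t))
        sig = build_type2(_track("LHeel", t, np.zeros_like(t), y=y))
        e = find_extrema(resample_to_grid(sig, 0, 3, 601), min_prominence=0.2, min_separation=0.3)
        for tm in e.minima_times:
            assert min(abs(tm - k) for k in range(4)) < 0.02

    def test_pd_preset_has_smaller_clearance_peaks(self, normal_series, pd_series):
        from gaitstage.io_keypoints import select_landmarks

        peaks = {}
        for label, series in [("normal", normal_series), ("pd", pd_series)]:
            (heel,) = select_landmarks(series, ["LHeel"], gap_policy="drop")
            peaks[label] = np.max(build_type2(heel).values)
        # preset clearance parameters are 12 vs 35 px; jitter rides on top
        assert peaks["pd"] < peaks["normal"] - 10


class TestNormalize:
    def test_divides_by_max_abs(self):
        sig = normalize_amplitude(_sig([2.0, -4.0, 1.0]))
        np.testing.assert_allclose(sig.values, [0.5, -1.0, 0.25])
        assert sig.normalized

    def test_idempotent(self, rng):
        sig = normalize_amplitude(_sig(rng.normal(size=64)))
        again = normalize_amplitude(sig)
        np.testing.assert_array_equal(sig.values, again.values)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalize_amplitude(_sig(np.zeros(10)))


class TestResample:
    def test_linear_ramp_exact(self):
        t = np.linspace(0, 1, 101)
        sig = GaitSignal(kind="T1", times=t, values=t.copy())
        out = resample_to_grid(sig, 0, 1, 11)
        np.testing.assert_allclose(out.values, np.linspace(0, 1, 11), atol=1e-15)

    def test_identity_on_own_grid(self):
        t = np.linspace(0, 2, 64)
        sig = GaitSignal(kind="T1", times=t, values=np.sin(t))
        out = resample_to_grid(sig, 0, 2, 64)
        np.testing.assert_allclose(out.values, sig.values, atol=1e-12)

    def test_affine_signal_is_exact_anywhere(self):
        t = np.linspace(0, 5, 57)
        sig = GaitSignal(kind="T1", times=t, values=3.0 * t - 1.25)
        out = resample_to_grid(sig, 0.7, 4.1, 23)
        np.testing.assert_allclose(out.values, 3.0 * out.times - 1.25, atol=1e-12)

    def test_dense_sine_error_below_1e3(self):
        t = np.arange(0, 2, 0.01)  # 100 Hz sampling
        sig = GaitSignal(kind="T1", times=t, values=np.sin(2 * np.pi * t))
        out = resample_to_grid(sig, 0, t[-1], 1000)
        assert np.max(np.abs(out.values - np.sin(2 * np.pi * out.times))) < 1e-3

    def test_never_extrapolates(self):
        sig = _sig(np.arange(10), dt=0.1)
        with pytest.raises(OutOfSupportError):
            resample_to_grid(sig, -0.5, 0.5, 10)


class TestOverlapWindow:
    def test_partial_overlap(self):
        a = GaitSignal(kind="T1", times=np.linspace(0, 10, 50), values=np.ones(50))
        b = GaitSignal(kind="T1", times=np.linspace(3, 12, 50), values=np.ones(50))
        assert overlap_window(a, b) == (3.0, 10.0)

    def test_identical_supports(self):
        a = GaitSignal(kind="T1", times=np.linspace(1, 9, 30), values=np.ones(30))
        assert overlap_window(a, a) == (1.0, 9.0)

    def test_disjoint_errors(self):
        a = GaitSignal(kind="T1", times=np.linspace(0, 1, 30), values=np.ones(30))
        b = GaitSignal(kind="T1", times=np.linspace(2, 3, 30), values=np.ones(30))
        with pytest.raises(NoOverlapError):
            overlap_window(a, b)


class TestFftDenoise:
    def test_keep_all_is_identity(self, rng):
        sig = _sig(rng.normal(size=200))
        out = fft_denoise(sig, keep_fraction=1.0)
        np.testing.assert_allclose(out.values, sig.values, atol=1e-10)

    def test_mean_preserved_for_any_cutoff(self, rng):
        sig = _sig(rng.normal(size=257) + 3.7)
        for frac in (0.05, 0.1, 0.33, 0.9):
            out = fft_denoise(sig, keep_fraction=frac)
            assert np.mean(out.values) == pytest.approx(np.mean(sig.values), abs=1e-12)

    def test_pure_sine_below_cutoff_unchanged(self):
        n, dt = 1000, 0.01  # fs=100, nyquist 50
        t = np.arange(n) * dt
        sig = GaitSignal(kind="T1", times=t, values=np.sin(2 * np.pi * 2.0 * t))
        out = fft_denoise(sig, keep_fraction=0.2)  # keeps up to 10 Hz
        np.testing.assert_allclose(out.values, sig.values, atol=1e-8)

    def test_high_frequency_component_removed(self):
        n, dt = 1000, 0.01
        t = np.arange(n) * dt
        low = np.sin(2 * np.pi * 1.0 * t)
        high = 0.5 * np.sin(2 * np.pi * 30.0 * t)  # 30 Hz spike, above cutoff
        sig = GaitSignal(kind="T1", times=t, values=low + high)
        out = fft_denoise(sig, keep_fraction=0.2)
        np.testing.assert_allclose(out.values, low, atol=1e-6)

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.35, 0.6, 0.8, 1.0, 1.3])
        sig = GaitSignal(kind="T1", times=t, values=np.sin(t))
        with pytest.raises(NonUniformGridError):
            fft_denoise(sig)


# --------------------------------------------------------------------------
# brute-force extrema oracle
# --------------------------------------------------------------------------

def _brute_prominence(values, i):
    """Height of peak i above the higher of its two descent bases."""
    left = values[: i + 1]
    higher_left = np.nonzero(left[:-1] > values[i])[0]
    lo = higher_left[-1] + 1 if len(higher_left) else 0
    base_left = np.min(left[lo:])
    right = values[i:]
    higher_right = np.nonzero(right[1:] > values[i])[0]
    hi = i + higher_right[0] + 1 if len(higher_right) else len(values)
    base_right = np.min(values[i:hi])
    return values[i] - max(base_left, base_right)


def _brute_peaks(values, prominence, distance):
    """All strict local maxima, spacing-pruned by height, prominence-gated."""
    cand = [i for i in range(1, len(values) - 1)
            if values[i - 1] < values[i] > values[i + 1]]
    keep = np.ones(len(cand), dtype=bool)
    order = sorted(range(len(cand)), key=lambda k: values[cand[k]], reverse=True)
    for k in order:
        if not keep[k]:
            continue
        for j in range(len(cand)):
            if j != k and keep[j] and abs(cand[j] - cand[k]) < distance:
                keep[j] = False
    return [i for k, i in enumerate(cand)
            if keep[k] and _brute_prominence(values, i) >= prominence]


def _brute_alternate(times, values, signs):
    out = []
    for t, v, s in zip(times, values, signs):
        if out and out[-1][2] == s:
            if (s > 0 and v > out[-1][1]) or (s < 0 and v < out[-1][1]):
                out[-1] = (t, v, s)
        else:
            out.append((t, v, s))
    return out


def _brute_extrema(signal, min_prominence, min_separation):
    dt = signal.times[1] - signal.times[0]
    distance = max(1, int(round(min_separation / dt)))
    prom = min_prominence * np.ptp(signal.values)
    imax = _brute_peaks(signal.values, prom, distance)
    imin = _brute_peaks(-signal.values, prom, distance)
    events = sorted(
        [(signal.times[i], signal.values[i], +1) for i in imax]
        + [(signal.times[i], signal.values[i], -1) for i in imin]
    )
    return _brute_alternate(*zip(*events)) if events else []


class TestFindExtrema:
    def test_sine_extrema_at_closed_form_times(self):
        t = np.linspace(0, 3, 601)
        sig = GaitSignal(kind="T1", times=t, values=np.sin(2 * np.pi * t))
        e = find_extrema(sig, min_prominence=0.1, min_separation=0.25)
        dt = t[1] - t[0]
        np.testing.assert_allclose(e.maxima_times, [0.25, 1.25, 2.25], atol=dt)
        np.testing.assert_allclose(e.minima_times, [0.75, 1.75, 2.75], atol=dt)

    def test_small_ripple_below_prominence_ignored(self):
        t = np.linspace(0, 2, 401)
        sig = GaitSignal(
            kind="T1", times=t,
            values=np.sin(2 * np.pi * t) + 0.01 * np.sin(2 * np.pi * 40 * t),
        )
        e = find_extrema(sig, min_prominence=0.1, min_separation=0.1)
        assert len(e.maxima_times) == 2
        assert len(e.minima_times) == 2

    def test_merged_alternates_strictly(self, exemplars):
        for sig in (*exemplars[0], *exemplars[1]):
            e = find_extrema(sig)
            assert np.all(e.merged_signs[1:] != e.merged_signs[:-1])
            assert np.all(np.diff(e.merged_times) > 0)

    def test_extrema_times_lie_on_the_grid(self):
        t = np.linspace(0, 3, 601)
        sig = GaitSignal(kind="T1", times=t, values=np.sin(2 * np.pi * t))
        e = find_extrema(sig)
        for tm in e.merged_times:
            assert np.min(np.abs(t - tm)) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_matches_brute_force_oracle_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        values = np.cumsum(rng.normal(size=200))
        sig = _sig(values, dt=0.02)
        got = find_extrema(sig, min_prominence=0.1, min_separation=0.1)
        expected = _brute_extrema(sig, min_prominence=0.1, min_separation=0.1)
        assert len(expected) >= 2
        np.testing.assert_allclose(got.merged_times, [e[0] for e in expected], atol=1e-12)
        np.testing.assert_allclose(got.merged_values, [e[1] for e in expected], atol=1e-12)
        np.testing.assert_array_equal(got.merged_signs, [e[2] for e in expected])

    def test_fewer_than_two_extrema_errors(self):
        sig = _sig(np.linspace(0, 1, 50))  # monotone ramp
        with pytest.raises((InsufficientCyclesError, DegenerateSignalError)):
            find_extrema(sig)
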