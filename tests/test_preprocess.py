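import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorspiral import derive_channels, segment_strokes, spectrum
from tremorspiral.errors import InsufficientDataError
from tremorspiral.preprocess import RHO_CAP, band_power_fraction

from conftest import make_recording


def _rec_from_states(states):
    n = len(states)
    return make_recording(
        t=np.arange(n) * 0.005,
        x=np.linspace(0, 10, n),
        y=np.linspace(0, 5, n),
        pen_down=np.asarray(states, dtype=bool),
    )


class TestSegmentation:
    def test_explicit_state_sequence(self):
        strokes = segment_strokes(_rec_from_states([1, 1, 0, 0, 1]))
        assert [(s.start, s.end, s.pen_down) for s in strokes] == [
            (0, 2, True), (2, 4, False), (4, 5, True)
        ]

    def test_all_down_is_single_stroke(self, all_down_recording):
        strokes = segment_strokes(all_down_recording)
        assert len(strokes) == 1
        assert strokes[0].pen_down

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.booleans(), min_size=2, max_size=60).filter(any))
    def test_stroke_count_equals_transitions_plus_one(self, states):
        strokes = segment_strokes(_rec_from_states(states))
        transitions = sum(a != b for a, b in zip(states, states[1:]))
        assert len(strokes) == transitions + 1
        # partition: lengths sum to n, ranges abut, states alternate
        assert sum(len(s) for s in strokes) == len(states)
        for a, b in zip(strokes, strokes[1:]):
            assert a.end == b.start
            assert a.pen_down != b.pen_down


class TestDerivedChannels:
    def test_uniform_circle_kinematics(self):
        """v = r*omega, rho = r, a_c = r*omega^2 for circular motion."""
        r, omega, rate = 100.0, 4.0, 200.0
        t = np.arange(0, 3 * 2 * np.pi / omega, 1 / rate)  # 3 full turns
        rec = make_recording(t, r * np.cos(omega * t), r * np.sin(omega * t))
        cs = derive_channels(rec, "down")
        interior = slice(5, -5)
        np.testing.assert_allclose(cs["v"][interior], r * omega, rtol=1e-3)
        np.testing.assert_allclose(cs["rho"][interior], r, rtol=1e-2)
        np.testing.assert_allclose(cs["ac"][interior], r * omega**2, rtol=1e-2)
        # origin is the pen-down centroid, so R matches up to discretisation
        np.testing.assert_allclose(cs["R"], r, rtol=5e-3)

    def test_straight_line_limit(self):
        t = np.arange(200) * 0.005
        rec = make_recording(t, 3.0 + 10.0 * t, 1.0 + 5.0 * t)
        cs = derive_channels(rec, "down")
        interior = slice(2, -2)
        np.testing.assert_allclose(cs["a"][interior], 0.0, atol=1e-8)
        assert np.all(cs["rho"][interior] == RHO_CAP)  # curvature guard
        np.testing.assert_allclose(
            cs["phi"][interior], np.arctan2(5.0, 10.0), atol=1e-9
        )

    def test_spiral_radius_affine_in_angle(self, quiet_recording):
        """For r = a + b*theta the R channel is affine in unwrapped Z,
        up to the once-per-revolution ripple from the centroid origin
        sitting one pitch off the true spiral centre."""
        cs = derive_channels(quiet_recording, "down")
        z, r = cs["Z"], cs["R"]
        m = z > z.min() + 2 * np.pi  # innermost turn: origin error dominates
        z, r = z[m], r[m]
        affine = np.column_stack([np.ones_like(z), z])
        resid_affine = r - affine @ np.linalg.lstsq(affine, r, rcond=None)[0]
        # affine fit already captures almost all of the radial span
        assert np.max(np.abs(resid_affine)) < 0.05 * np.ptp(r)
        harmonic = np.column_stack([affine, np.cos(z), np.sin(z)])
        resid = r - harmonic @ np.linalg.lstsq(harmonic, r, rcond=None)[0]
        # with the origin ripple removed the relation is affine to < 1%
        assert np.max(np.abs(resid)) < 0.01 * np.ptp(r)

    def test_polar_roundtrip(self, tremor_recording):
        cs = derive_channels(tremor_recording, "down")
        cx, cy = cs.origin
        np.testing.assert_allclose(cs["Rcos"] + cx, cs["x"], atol=1e-9)
        np.testing.assert_allclose(cs["Rsin"] + cy, cs["y"], atol=1e-9)

    @pytest.mark.parametrize("segment", ["down", "up", "full"])
    def test_all_channels_finite(self, tremor_recording, segment):
        cs = derive_channels(tremor_recording, segment)
        for name in cs.names():
            assert np.all(np.isfinite(cs[name])), name

    def test_channels_share_length(self, tremor_recording):
        cs = derive_channels(tremor_recording, "down")
        lengths = {len(cs[name]) for name in cs.names()}
        assert lengths == {cs.n_samples}

    def test_short_segment_rejected(self):
        rec = make_recording(
            t=np.arange(5) * 0.005,
            x=np.arange(5.0), y=np.arange(5.0),
            pen_down=np.array([1, 1, 1, 1, 0], dtype=bool),
        )
        with pytest.raises(InsufficientDataError):
            derive_channels(rec, "up")


class TestSpectrum:
    rate = 200.0

    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(0, 4, 1 / self.rate)
        freqs, mag = spectrum(np.sin(2 * np.pi * 6.0 * t), self.rate)
        assert abs(freqs[np.argmax(mag)] - 6.0) < self.rate / len(t) / 2 + 0.1

    def test_constant_channel_is_silent(self):
        freqs, mag = spectrum(np.full(256, 3.7), self.rate)
        np.testing.assert_allclose(mag, 0.0, atol=1e-12)

    def test_two_tone_amplitude_ratio_preserved(self):
        t = np.arange(0, 8, 1 / self.rate)
        x = 2.0 * np.sin(2 * np.pi * 5.0 * t) + 1.0 * np.sin(2 * np.pi * 9.0 * t)
        freqs, mag = spectrum(x, self.rate)
        a5 = mag[np.argmin(np.abs(freqs - 5.0))]
        a9 = mag[np.argmin(np.abs(freqs - 9.0))]
        assert abs(a5 / a9 - 2.0) < 0.1  # within 5%

    def test_too_short_channel_rejected(self):
        with pytest.raises(InsufficientDataError):
            spectrum(np.arange(5.0), self.rate)

    def test_band_power_fraction_bounds(self):
        t = np.arange(0, 4, 1 / self.rate)
        frac = band_power_fraction(np.sin(2 * np.pi * 6.0 * t), self.rate, 4, 12)
        assert 0.95 < frac <= 1.0
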