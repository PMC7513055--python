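import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorspiral import (
    NonlinearConfig,
    WindowPlan,
    castiglioni_fd,
    extract_nonlinear,
    higuchi_fd,
    peak_distortion,
    shannon_entropy,
    windowed_profile,
)
from tremorspiral.errors import InsufficientDataError
from tremorspiral.pipeline import extract_features, resolve_feature_sets

from conftest import colored_noise


class TestHiguchi:
    def test_linear_ramp_has_dimension_one(self):
        assert higuchi_fd(np.arange(500.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_has_dimension_two(self):
        rng = np.random.default_rng(0)
        assert higuchi_fd(rng.standard_normal(2048), kmax=8) == pytest.approx(
            2.0, abs=0.1
        )

    def test_constant_series_convention(self):
        assert higuchi_fd(np.full(100, 3.0)) == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            higuchi_fd(np.arange(10.0), kmax=8)

    def test_roughness_ordering_on_colored_noise(self):
        """Estimated FD increases with spectral roughness: rank
        correlation > 0.9 over five 1/f^beta levels."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        betas = [3.0, 2.5, 2.0, 1.5, 1.0]  # smooth -> rough
        means = [
            np.mean([higuchi_fd(colored_noise(rng, 1024, b)) for _ in range(12)])
            for b in betas
        ]
        rho = spearmanr(-np.array(betas), means).statistic
        assert rho > 0.9
        assert all(1.0 - 0.1 <= m <= 2.0 + 0.1 for m in means)


class TestCastiglioni:
    def test_hand_computed_example(self):
        # L = 2.5, d = 1.5, n = 3 -> ln 3 / (ln 3 + ln 0.6)
        expected = np.log(3) / (np.log(3) + np.log(1.5 / 2.5))
        assert castiglioni_fd([0.0, 1.0, 0.5, 1.5]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(1.869, abs=1e-3)

    def test_monotone_ramp_is_degenerate(self):
        assert castiglioni_fd(np.linspace(0, 5, 50)) == 1.0

    def test_constant_series_convention(self):
        assert castiglioni_fd(np.full(10, 2.0)) == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        # well-scaled values so a*x + b cannot absorb the series' variation
        st.lists(st.integers(-1000, 1000), min_size=3, max_size=50).filter(
            lambda xs: len(set(xs)) > 1
        ),
        st.floats(0.1, 10.0),
        st.floats(-50, 50),
    )
    def test_affine_invariance(self, xs, a, b):
        x = np.asarray(xs, dtype=float) / 10.0
        assert castiglioni_fd(a * x + b) == pytest.approx(
            castiglioni_fd(x), rel=1e-9
        )

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_direct_formula_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.standard_normal(64))  # random walk, non-degenerate
        L = float(np.abs(np.diff(x)).sum())
        d = float(np.max(np.abs(x - x[0])))
        n = len(x) - 1
        expected = np.log(n) / (np.log(n) + np.log(d / L))
        assert castiglioni_fd(x) == pytest.approx(expected, rel=1e-12)


class TestEntropy:
    def test_uniform_four_bins_is_two_bits(self):
        series = np.repeat([0.0, 1.0, 2.0, 3.0], 10)
        assert shannon_entropy(series, bins=4) == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_8_4_2_2_histogram(self):
        # counts (8, 4, 2, 2) -> H = 1.75 bits
        series = np.array([0.1] * 8 + [1.1] * 4 + [2.1] * 2 + [3.1, 3.9])
        assert shannon_entropy(series, bins=4) == pytest.approx(1.75, abs=1e-12)

    def test_constant_series_has_zero_entropy(self):
        assert shannon_entropy(np.full(32, 1.23), bins=4) == 0.0

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=16, max_size=200),
        st.sampled_from([2, 4, 8, 16]),
    )
    def test_entropy_bounds(self, xs, bins):
        h = shannon_entropy(np.asarray(xs), bins=bins)
        assert 0.0 <= h <= np.log2(bins) + 1e-12


class TestWindowedProfile:
    def test_single_window_collapses_aggregates(self):
        x = np.random.default_rng(0).standard_normal(128)
        plan = WindowPlan(window_len=128, overlap=0.0, min_windows=1)
        prof = windowed_profile(x, plan, "higuchi", kmax=8)
        aggs = prof.aggregates
        assert len(prof.per_window_values) == 1
        assert len({round(v, 12) for v in aggs.values()}) == 1
        assert aggs["mean"] == pytest.approx(higuchi_fd(x, kmax=8))

    def test_stationary_series_has_low_dispersion(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2048)
        prof = windowed_profile(x, WindowPlan(), "higuchi", kmax=8)
        aggs = prof.aggregates
        assert aggs["max"] - aggs["min"] < 0.35
        assert aggs["mean"] == pytest.approx(higuchi_fd(x, kmax=8), abs=0.15)

    def test_smooth_then_noisy_contrast(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 4 * np.pi, 1024)
        x = np.concatenate([np.sin(t), rng.standard_normal(1024)])
        prof = windowed_profile(x, WindowPlan(), "higuchi", kmax=8)
        aggs = prof.aggregates
        assert aggs["max"] - aggs["min"] > 0.3

    def test_too_few_windows_names_required_length(self):
        with pytest.raises(InsufficientDataError, match="320"):
            windowed_profile(np.arange(100.0), WindowPlan(), "higuchi")

    def test_aggregates_recomputable_from_values(self):
        x = np.random.default_rng(3).standard_normal(1024)
        prof = windowed_profile(x, WindowPlan(), "entropy", bins=16)
        v = prof.per_window_values
        assert prof.aggregates["min"] == np.min(v)
        assert prof.aggregates["median"] == np.median(v)


class TestPeakDistortion:
    def test_monotone_series_has_no_peaks(self):
        assert peak_distortion(np.arange(100.0), prominence=0.1) == 0.0

    def test_sinusoid_extrema_rate(self):
        f, rate = 5.0, 200.0
        t = np.arange(0, 4, 1 / rate)
        score = peak_distortion(np.sin(2 * np.pi * f * t), 0.5, rate_hz=rate)
        assert score == pytest.approx(2 * f, rel=0.1)

    def test_tremor_ripple_increases_score(self):
        rate = 200.0
        t = np.arange(0, 4, 1 / rate)
        clean = np.sin(2 * np.pi * 1.0 * t)
        rippled = clean + 0.3 * np.sin(2 * np.pi * 8.0 * t)
        assert peak_distortion(rippled, 0.1, rate) > peak_distortion(
            clean, 0.1, rate
        )


@pytest.fixture(scope="module")
def matrix(tremor_recording, quiet_recording):
    return extract_features([tremor_recording, quiet_recording])


class TestCatalogArithmetic:

    @pytest.mark.parametrize(
        "set_name,expected",
        [
            ("LF", 186), ("LFHFD", 213), ("LFCFD", 213),
            ("LFE", 198), ("LFHFDE", 225), ("LFCFDE", 225),
        ],
    )
    def test_set_sizes(self, matrix, set_name, expected):
        sets = resolve_feature_sets([set_name], matrix.feature_names)
        assert len(sets[set_name]) == expected

    def test_each_fd_estimator_adds_27_and_entropy_12(self, matrix):
        sets = resolve_feature_sets(
            ["LF", "LFHFD", "LFCFD", "LFE", "LFHFDE", "LFCFDE"],
            matrix.feature_names,
        )
        lf = len(sets["LF"])
        assert len(sets["LFHFD"]) - lf == 27
        assert len(sets["LFCFD"]) - lf == 27
        assert len(sets["LFE"]) - lf == 12
        assert len(sets["LFHFDE"]) - lf == 39
        assert len(sets["LFCFDE"]) - lf == 39

    def test_nonlinear_values_within_estimator_ranges(self, tremor_recording):
        fv = extract_nonlinear(tremor_recording, NonlinearConfig())
        for name, v in fv.values.items():
            if name.startswith("ent."):
                assert 0.0 <= v <= 4.0 + 1e-9  # log2(16)
            else:
                assert v == 0.0 or v >= 1.0 - 0.1
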