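"""Non-linear waveform descriptors: fractal dimensions and Shannon entropy.

Two fractal-dimension estimators are provided.  The Higuchi estimator
fits the scaling of multi-scale curve lengths L(k) ~ k^(-FD); the
Castiglioni estimator applies Katz's ratio formula with ordinate-only
distances (path length L = sum |dX|, extent d = max |X_i - X_1|):

    FD = log(n) / (log(n) + log(d / L)),   n = N - 1 steps.

Shannon entropy is computed from an equal-width amplitude histogram,

    H = -sum p_i log2 p_i   (bits),

and, like the fractal dimensions, is evaluated over short sliding
windows whose per-window values are summarised by min/max/mean/median —
tremor is non-stationary, so the evolution along the drawing carries the
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, ValidationError
from .linear_features import FeatureVector, _channel_sets
from .tablet_io import Recording

AGGREGATES = ("min", "max", "mean", "median")

#: channels the non-linear descriptors are computed on
NL_CHANNELS = ("pressure", "x", "y")

#: saturation value when the Katz-ratio denominator is non-positive
CASTIGLIONI_FD_CAP = 10.0


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout for the per-window complexity profiles."""

    window_len: int = 128  # samples; 0.64 s at 200 Hz
    overlap: float = 0.5  # fraction in [0, 1)
    min_windows: int = 4

    def __post_init__(self) -> None:
        if self.window_len < 16:
            raise ValidationError("window_len must be >= 16 samples")
        if not 0.0 <= self.overlap < 1.0:
            raise ValidationError("overlap must be in [0, 1)")
        if self.min_windows < 1:
            raise ValidationError("min_windows must be >= 1")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.window_len * (1.0 - self.overlap))))

    def required_length(self) -> int:
        return self.window_len + (self.min_windows - 1) * self.hop

    def window_starts(self, n: int) -> np.ndarray:
        if n < self.window_len:
            return np.array([], dtype=int)
        return np.arange(0, n - self.window_len + 1, self.hop)


def higuchi_fd(series: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal-dimension estimate of a 1-D series.

    For each scale k and offset m, the normalised curve length is

        L_m(k) = (N-1) / (floor((N-m)/k) * k^2) * sum |X(m+ik) - X(m+(i-1)k)|

    averaged over offsets; FD is minus the slope of log L(k) vs log k.
    A constant series has zero variation at every scale and returns 1.0
    by convention (the dimension of a smooth line).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if kmax < 2:
        raise ValidationError("kmax must be >= 2")
    if n < 2 * kmax:
        raise InsufficientDataError(
            f"series of length {n} too short for kmax={kmax} (need >= {2 * kmax})"
        )
    if np.ptp(x) == 0.0:
        return 1.0
    ks = np.arange(1, kmax + 1)
    lengths = np.empty(kmax)
    for k in ks:
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            seg = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k * k)
            lm.append(seg * norm)
        lengths[k - 1] = np.mean(lm)
    good = lengths > 0
    if good.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(ks[good]), np.log(lengths[good]), 1)[0]
    return float(-slope)


def castiglioni_fd(series: np.ndarray) -> float:
    """Katz-form fractal dimension with ordinate-only distances.

    Degenerate cases return 1.0: a constant series (no variation) and a
    monotone series (extent equals path length).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 samples")
    steps = np.abs(np.diff(x))
    L = steps.sum()
    if L == 0.0:
        return 1.0
    d = np.max(np.abs(x - x[0]))
    if d == 0.0 or d == L:
        return 1.0
    n = len(x) - 1
    denom = np.log(n) + np.log(d / L)
    if denom <= 0:
        # extent negligible versus path length; saturate instead of blowing up
        return CASTIGLIONI_FD_CAP
    return float(np.log(n) / denom)


def shannon_entropy(series: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram.

    The histogram spans [min, max] with ``bins`` cells; p_i = count_i/N;
    H = -sum p_i log2 p_i with 0 log 0 = 0, so 0 <= H <= log2(bins).
    A constant series has all mass in one cell and returns 0.
    """
    x = np.asarray(series, dtype=float)
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    if len(x) < bins:
        raise InsufficientDataError(f"need at least {bins} samples for {bins} bins")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum())


_ESTIMATORS = {
    "higuchi": higuchi_fd,
    "castiglioni": castiglioni_fd,
    "entropy": shannon_entropy,
}


@dataclass
class ComplexityProfile:
    """Per-window estimator values and their four summary aggregates."""

    per_window_values: np.ndarray
    estimator: str

    @property
    def aggregates(self) -> dict[str, float]:
        v = self.per_window_values
        return {
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
        }


def windowed_profile(
    series: np.ndarray,
    plan: WindowPlan,
    estimator: str,
    **estimator_kwargs,
) -> ComplexityProfile:
    """Apply an estimator to each sliding window of the series."""
    if estimator not in _ESTIMATORS:
        raise ValidationError(f"unknown estimator {estimator!r}")
    x = np.asarray(series, dtype=float)
    starts = plan.window_starts(len(x))
    if len(starts) < plan.min_windows:
        raise InsufficientDataError(
            f"series of length {len(x)} yields {len(starts)} windows; "
            f"plan requires {plan.min_windows} (length >= {plan.required_length()})"
        )
    func = _ESTIMATORS[estimator]
    vals = np.array(
        [func(x[s : s + plan.window_len], **estimator_kwargs) for s in starts]
    )
    return ComplexityProfile(per_window_values=vals, estimator=estimator)


def peak_distortion(
    series: np.ndarray, prominence: float, rate_hz: float = 200.0
) -> float:
    """Local extrema (maxima and minima) above a prominence threshold,
    normalised per second.  An auxiliary distortion score, not part of
    the counted catalogs."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 samples")
    n_peaks = len(find_peaks(x, prominence=prominence)[0])
    n_valleys = len(find_peaks(-x, prominence=prominence)[0])
    duration = len(x) / rate_hz
    return (n_peaks + n_valleys) / duration


@dataclass
class NonlinearConfig:
    """Which estimators to run and with what parameters.

    Per fractal-dimension estimator the extractor emits 27 features:
    3 channels x 2 segments x 4 window aggregates (24) plus the
    whole-recording FD of each channel (3).  Entropy emits 12:
    3 channels x 4 window aggregates over the full signal.
    """

    estimators: tuple[str, ...] = ("higuchi", "castiglioni", "entropy")
    plan: WindowPlan = field(default_factory=WindowPlan)
    kmax: int = 8
    bins: int = 16

    PREFIX = {"higuchi": "hfd", "castiglioni": "cfd", "entropy": "ent"}

    def __post_init__(self) -> None:
        unknown = set(self.estimators) - set(_ESTIMATORS)
        if unknown:
            raise ValidationError(f"unknown estimators: {sorted(unknown)}")

    def kwargs_for(self, estimator: str) -> dict:
        if estimator == "higuchi":
            return {"kmax": self.kmax}
        if estimator == "entropy":
            return {"bins": self.bins}
        return {}

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for est in self.estimators:
            p = self.PREFIX[est]
            if est == "entropy":
                names += [f"{p}.{c}.{agg}" for c in NL_CHANNELS for agg in AGGREGATES]
            else:
                names += [
                    f"{p}.{c}.{seg}.{agg}"
                    for c in NL_CHANNELS
                    for seg in ("down", "up")
                    for agg in AGGREGATES
                ]
                names += [f"{p}.{c}.full" for c in NL_CHANNELS]
        return names


def _profile_or_fallback(
    series: np.ndarray, config: NonlinearConfig, estimator: str
) -> dict[str, float] | None:
    """Windowed aggregates; short segments degrade to a single window
    covering the whole segment, and hopeless ones (< 16 samples) to None."""
    func = _ESTIMATORS[estimator]
    kwargs = config.kwargs_for(estimator)
    n = len(series)
    min_len = max(16, 2 * config.kmax if estimator == "higuchi" else 16,
                  config.bins if estimator == "entropy" else 16)
    if n < min_len:
        return None
    starts = config.plan.window_starts(n)
    if len(starts) >= config.plan.min_windows:
        return windowed_profile(series, config.plan, estimator, **kwargs).aggregates
    v = float(func(np.asarray(series, dtype=float), **kwargs))
    return {agg: v for agg in AGGREGATES}


def extract_nonlinear(rec: Recording, config: NonlinearConfig | None = None,
                      channel_sets=None) -> FeatureVector:
    """Compute the configured non-linear features for one recording.

    Missing or too-short pen-up segments yield zero-valued features with
    a ``missing_up`` flag, mirroring the linear extractor's convention.
    """
    if config is None:
        config = NonlinearConfig()
    sets = channel_sets if channel_sets is not None else _channel_sets(rec)
    values: dict[str, float] = {}
    flags: dict[str, bool] = {}

    def seg_channel(seg: str, ch: str) -> np.ndarray | None:
        cs = sets.get(seg)
        return None if cs is None else cs[ch]

    full = {
        "x": rec.x,
        "y": rec.y,
        "pressure": rec.pressure,
    }
    for est in config.estimators:
        p = config.PREFIX[est]
        if est == "entropy":
            for c in NL_CHANNELS:
                aggs = _profile_or_fallback(full[c], config, est)
                for agg in AGGREGATES:
                    values[f"{p}.{c}.{agg}"] = 0.0 if aggs is None else aggs[agg]
            continue
        for c in NL_CHANNELS:
            for seg in ("down", "up"):
                series = seg_channel(seg, c)
                aggs = (
                    None if series is None else _profile_or_fallback(series, config, est)
                )
                if aggs is None:
                    flags[f"missing_{seg}"] = True
                for agg in AGGREGATES:
                    values[f"{p}.{c}.{seg}.{agg}"] = 0.0 if aggs is None else aggs[agg]
            func = _ESTIMATORS[est]
            values[f"{p}.{c}.full"] = float(
                func(full[c], **config.kwargs_for(est))
            )
    return FeatureVector(values=values, catalog_id="NLF", flags=flags)
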