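"""Stroke segmentation and derived-channel computation.

A recording splits into alternating pen-down (on-surface) and pen-up
(in-air) strokes.  For either surface state, or for the full recording,
:func:`derive_channels` produces the named 1-D signals that feed feature
extraction: the raw tablet channels, polar coordinates about the spiral
centre, and finite-difference kinematics (speed, accelerations,
trajectory angle, displacement, radius of curvature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq

from .errors import InsufficientDataError, ValidationError
from .tablet_io import Recording

#: ceiling for the radius-of-curvature channel, in device units
RHO_CAP = 1.0e6

SEGMENTS = ("down", "up", "full")


@dataclass(frozen=True)
class Stroke:
    """Half-open index range [start, end) of samples sharing a pen state."""

    start: int
    end: int
    pen_down: bool

    def __len__(self) -> int:
        return self.end - self.start


def segment_strokes(rec: Recording) -> list[Stroke]:
    """Partition the recording into maximal runs of constant pen state.

    The returned strokes cover every sample exactly once and alternate
    surface state; an all-down (or all-up) recording yields one stroke.
    """
    state = rec.pen_down
    boundaries = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
    edges = np.concatenate(([0], boundaries, [len(state)]))
    return [
        Stroke(int(a), int(b), bool(state[a])) for a, b in zip(edges[:-1], edges[1:])
    ]


@dataclass
class ChannelSet:
    """Named 1-D signals of equal length sharing one sampling rate."""

    channels: dict[str, np.ndarray]
    rate_hz: float
    segment: str  # down | up | full
    origin: tuple[float, float]
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def names(self) -> list[str]:
        return list(self.channels)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **self.channels})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def spiral_center(rec: Recording) -> tuple[float, float]:
    """Centroid of the pen-down samples, used as origin for polar channels."""
    m = rec.pen_down
    return float(np.mean(rec.x[m])), float(np.mean(rec.y[m]))


def _segment_mask(rec: Recording, segment: str) -> np.ndarray:
    if segment == "down":
        return rec.pen_down
    if segment == "up":
        return ~rec.pen_down
    if segment == "full":
        return np.ones(len(rec), dtype=bool)
    raise ValidationError(f"unknown segment {segment!r}")


def derive_channels(rec: Recording, segment: str = "full") -> ChannelSet:
    """Compute raw, polar and kinematic channels for one surface segment.

    Derivatives use central finite differences on the (possibly
    non-uniform) timestamp grid, one-sided at the endpoints.  The radius
    of curvature rho = v^3 / |v_x a_y - v_y a_x| is floored/capped so all
    channels stay finite.  Requires at least 3 samples in the segment.
    """
    mask = _segment_mask(rec, segment)
    n = int(mask.sum())
    if n == 0:
        raise InsufficientDataError(f"segment {segment!r} has no samples")
    if n < 3:
        raise InsufficientDataError(
            f"segment {segment!r} has {n} samples; need >= 3 for kinematic channels"
        )
    t = rec.t[mask]
    x = rec.x[mask]
    y = rec.y[mask]
    cx, cy = spiral_center(rec)

    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    z = np.unwrap(np.arctan2(dy, dx))

    # velocities / accelerations on the non-uniform grid
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    v = np.hypot(vx, vy)
    ax = np.gradient(vx, t)
    ay = np.gradient(vy, t)
    a = np.hypot(ax, ay)
    a_t = np.gradient(v, t)

    cross = np.abs(vx * ay - vy * ax)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(cross > 0, v**3 / np.maximum(cross, 1e-300), np.inf)
    rho = np.clip(np.nan_to_num(rho, nan=RHO_CAP, posinf=RHO_CAP), 0.0, RHO_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_c = np.where(rho > 0, v**2 / rho, 0.0)

    phi = np.unwrap(np.arctan2(vy, vx))
    d = np.concatenate(([0.0], np.hypot(np.diff(x), np.diff(y))))

    channels = {
        "x": x,
        "y": y,
        "pressure": rec.pressure[mask],
        "azimuth": rec.azimuth[mask],
        "altitude": rec.altitude[mask],
        "Z": z,
        "R": r,
        "Rcos": r * np.cos(z),
        "Rsin": r * np.sin(z),
        "v": v,
        "a": a,
        "at": a_t,
        "ac": a_c,
        "phi": phi,
        "d": d,
        "rho": rho,
    }
    for name, ch in channels.items():
        if not np.all(np.isfinite(ch)):
            raise ValidationError(f"non-finite values in derived channel {name!r}")
    return ChannelSet(
        channels=channels, rate_hz=rec.sampling_rate_hz, segment=segment,
        origin=(cx, cy), t=t,
    )


def spectrum(
    channel: np.ndarray, rate_hz: float, n_fft: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the mean-removed, Hann-windowed signal.

    Zero-pads to the next power of two (or to ``n_fft`` when given, which
    fixes the frequency grid across recordings of different lengths).
    Returns ``(freqs_hz, magnitudes)``; a pure sinusoid of amplitude A
    shows a peak of approximately A.
    """
    channel = np.asarray(channel, dtype=float)
    if len(channel) < 8:
        raise InsufficientDataError(
            f"channel of length {len(channel)} too short for a spectrum (need >= 8)"
        )
    xs = channel - channel.mean()
    w = np.hanning(len(xs))
    if n_fft is None:
        n_fft = 1 << int(np.ceil(np.log2(len(xs))))
    mag = np.abs(rfft(xs * w, n=max(n_fft, len(xs))))
    # amplitude normalisation: coherent gain of the Hann window
    mag *= 2.0 / w.sum()
    freqs = rfftfreq(max(n_fft, len(xs)), d=1.0 / rate_hz)
    return freqs, mag


def band_power_fraction(
    channel: np.ndarray, rate_hz: float, f_lo: float, f_hi: float
) -> float:
    """Fraction of non-DC spectral energy inside [f_lo, f_hi] Hz."""
    freqs, mag = spectrum(channel, rate_hz)
    power = mag**2
    nz = freqs > 0
    total = power[nz].sum()
    if total == 0:
        return 0.0
    band = nz & (freqs >= f_lo) & (freqs <= f_hi)
    return float(power[band].sum() / total)
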