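"""Synthetic Archimedes-spiral drawing cohorts with controllable tremor.

Each simulated drawing follows the ideal spiral r(theta) = a + b*theta at
a constant angular rate, sampled at the tablet's nominal 200 Hz.  Tremor
is injected radially — perpendicular to the drawn path, the direction in
which spiral-drawing tremor is conventionally measured — as a sinusoid
in the 4-12 Hz band with slowly drifting instantaneous frequency and
amplitude.  Pressure is a baseline plus slow AR(1) instability; pen
lifts appear as pen-up intervals with a small outward in-air loop and
zero pressure.  Azimuth and altitude are bounded random walks: they
exist so the full feature catalog is exercised, with no claimed
physiological realism.

All randomness flows from a single integer seed, so a cohort is
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tablet_io import Recording, write_svc

PRESSURE_BASELINE = 512.0  # device units, mid-range of a 10-bit sensor
PRESSURE_MAX = 1023.0


@dataclass(frozen=True)
class TremorParams:
    """Per-drawing tremor and noise parameters (device units / Hz)."""

    amplitude: float = 0.0  # radial tremor amplitude
    frequency_hz: float = 6.0  # must lie in the 4-12 Hz tremor band
    freq_jitter: float = 0.05  # relative std of instantaneous frequency
    amp_modulation: float = 0.2  # relative std of instantaneous amplitude
    pressure_noise: float = 3.0  # std of the AR(1) pressure instability
    pen_lift_rate: float = 1.0  # expected pen lifts per drawing
    lift_duration_s: float = 0.3  # mean in-air duration per lift

    def __post_init__(self) -> None:
        if not 4.0 <= self.frequency_hz <= 12.0:
            raise ValidationError(
                f"tremor frequency {self.frequency_hz} Hz outside the 4-12 Hz band"
            )
        for name in ("amplitude", "freq_jitter", "amp_modulation",
                     "pressure_noise", "pen_lift_rate", "lift_duration_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SpiralGeometry:
    """Ideal-trajectory parameters: r = a + b*theta, drawn over ``turns``
    revolutions at constant angular rate (rad/s)."""

    a: float = 100.0  # inner radius, device units
    b: float = 130.0  # radial growth per radian
    turns: float = 5.0
    angular_rate: float = 2.6  # ~12 s for 5 turns
    center: tuple[float, float] = (2500.0, 2500.0)

    def __post_init__(self) -> None:
        if self.b <= 0 or self.angular_rate <= 0:
            raise ValidationError("spiral pitch b and angular_rate must be positive")
        if self.turns < 2:
            raise ValidationError("need at least 2 turns for a recognisable spiral")


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-variance AR(1) noise (stationary initialisation)."""
    e = rng.standard_normal(n) * np.sqrt(1.0 - rho**2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def generate_spiral(
    params: TremorParams,
    geometry: SpiralGeometry | None = None,
    rate_hz: float = 200.0,
    seed: int = 0,
    subject_id: str = "",
    hand: str = "dominant",
    label: str = "unlabeled",
) -> Recording:
    """Simulate one spiral drawing; deterministic given the seed."""
    if rate_hz <= 0:
        raise ValidationError("sampling rate must be positive")
    geo = geometry or SpiralGeometry()
    rng = np.random.default_rng(seed)

    duration = geo.turns * 2 * np.pi / geo.angular_rate
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz
    theta = geo.angular_rate * t
    r_ideal = geo.a + geo.b * theta

    # tremor: radial sinusoid with drifting frequency and amplitude
    f_inst = params.frequency_hz * (1.0 + params.freq_jitter * _ar1(rng, n, 0.99))
    f_inst = np.clip(f_inst, 0.5, rate_hz / 2 * 0.9)
    phase = 2 * np.pi * np.cumsum(f_inst) / rate_hz + rng.uniform(0, 2 * np.pi)
    amp_t = params.amplitude * np.clip(
        1.0 + params.amp_modulation * _ar1(rng, n, 0.995), 0.0, None
    )
    radial = amp_t * np.sin(phase)

    r = r_ideal + radial
    cx, cy = geo.center
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)

    pressure = PRESSURE_BASELINE + params.pressure_noise * _ar1(rng, n, 0.995)
    pen_down = np.ones(n, dtype=bool)

    # pen lifts: pen-up intervals with a small outward in-air loop
    n_lifts = rng.poisson(params.pen_lift_rate)
    for _ in range(n_lifts):
        dur = max(3, int(round(rng.exponential(params.lift_duration_s) * rate_hz)))
        start = int(rng.uniform(0.05, 0.9) * n)
        end = min(start + dur, n - 2)
        if end <= start or not pen_down[start:end].all():
            continue
        if start == 0:  # keep the first sample on-surface
            start = 1
        pen_down[start:end] = False
        s = np.linspace(0.0, 1.0, end - start)
        bump = np.sin(np.pi * s)
        x[start:end] += bump * 40.0 * np.cos(theta[start:end])
        y[start:end] += bump * 40.0 * np.sin(theta[start:end])

    pressure = np.clip(pressure, 1.0, PRESSURE_MAX)
    pressure[~pen_down] = 0.0

    azimuth = np.clip(200.0 + np.cumsum(rng.normal(0, 0.5, n)), 0.0, 359.9)
    altitude = np.clip(60.0 + np.cumsum(rng.normal(0, 0.2, n)), 0.0, 90.0)

    return Recording(
        t=t, x=x, y=y, pressure=pressure, azimuth=azimuth, altitude=altitude,
        pen_down=pen_down, sampling_rate_hz=rate_hz,
        subject_id=subject_id, hand=hand, label=label,
    )


@dataclass(frozen=True)
class CohortSpec:
    """A two-class cohort specification.

    Defaults mirror the reference cohort layout: 27 control (CR) and 24
    essential-tremor (ET) drawings.  Controls carry only physiological
    micro-tremor (amplitude equal to the pressure-noise scale); the ET
    class defaults to the strong-effect condition with radial tremor
    amplitude 20x the noise scale.  Between-subject variability scales
    each subject's amplitude (relative std) and shifts the tremor
    frequency (absolute std, clipped to the 4-12 Hz band).
    """

    n_control: int = 27
    n_et: int = 24
    control_params: TremorParams = field(
        default_factory=lambda: TremorParams(amplitude=3.0, pen_lift_rate=1.0)
    )
    et_params: TremorParams = field(
        default_factory=lambda: TremorParams(amplitude=60.0, pen_lift_rate=2.0)
    )
    spiral: SpiralGeometry = field(default_factory=SpiralGeometry)
    rate_hz: float = 200.0
    seed: int = 0
    amplitude_rel_std: float = 0.15
    frequency_abs_std: float = 1.0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_et < 1:
            raise ValidationError("both classes need at least one recording")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        for key in ("control_params", "et_params"):
            if key in d:
                d[key] = TremorParams(**d[key])
        if "spiral" in d:
            d["spiral"]["center"] = tuple(d["spiral"]["center"])
            d["spiral"] = SpiralGeometry(**d["spiral"])
        return cls(**d)


def _draw_subject_params(
    base: TremorParams, spec: CohortSpec, rng: np.random.Generator
) -> TremorParams:
    amp = max(0.0, base.amplitude * (1.0 + spec.amplitude_rel_std * rng.standard_normal()))
    freq = float(np.clip(
        base.frequency_hz + spec.frequency_abs_std * rng.standard_normal(), 4.0, 12.0
    ))
    return replace(base, amplitude=amp, frequency_hz=freq)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the labelled cohort and its ground-truth manifest.

    When ``out_dir`` is given, each recording is written as an SVC file
    and the manifest as ``manifest.csv`` alongside them.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[Recording] = []
    manifest_rows = []
    plan = [("CR", spec.control_params, spec.n_control),
            ("ET", spec.et_params, spec.n_et)]
    for label, base, count in plan:
        for i in range(count):
            subject_id = f"{label}{i + 1:02d}"
            params = _draw_subject_params(base, spec, rng)
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_spiral(
                params, geometry=spec.spiral, rate_hz=spec.rate_hz,
                seed=rec_seed, subject_id=subject_id, label=label,
            )
            recordings.append(rec)
            manifest_rows.append(
                {"subject_id": subject_id, "label": label, "seed": rec_seed,
                 **asdict(params)}
            )
    manifest = pd.DataFrame(manifest_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_svc(rec, out_dir / f"{rec.subject_id}.svc")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return recordings, manifest


def strong_effect_cohort_spec(seed: int = 0) -> CohortSpec:
    """The documented strong-effect study condition: 27 CR vs 24 ET with
    ET radial tremor amplitude 20x the pressure-noise scale."""
    return CohortSpec(seed=seed)


def detrended_radius(rec: Recording) -> np.ndarray:
    """Radial signal of the pen-down trace with the spiral growth removed,
    for tremor-band diagnostics.

    The polar origin is the pen-down centroid, which sits about one pitch
    off the true spiral centre; that offset shows up in R as a
    once-per-revolution cosine.  The fit therefore removes an affine term
    in the unwrapped angle plus one cos/sin harmonic, leaving the tremor.
    """
    m = rec.pen_down
    x = rec.x[m] - np.mean(rec.x[m])
    y = rec.y[m] - np.mean(rec.y[m])
    r = np.hypot(x, y)
    z = np.unwrap(np.arctan2(y, x))
    design = np.column_stack([np.ones_like(z), z, np.cos(z), np.sin(z)])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ coef
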