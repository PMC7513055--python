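"""Linear-feature catalog: the declarative grid of per-drawing statistics.

The catalog is configuration, not code: a :class:`CatalogSpec` lists
(channel x segment x statistic) blocks plus scalar time features,
zero-crossing rates and leading spectral magnitudes.  The shipped
default expands to exactly 186 uniquely-named features:

* 3 time features (on-surface, in-air, total drawing time)
* 5 on-surface pressure statistics (min, max, mean, median, std)
* 8 spatial channels x 2 segments x 4 statistics = 64
  (x, y, altitude, azimuth, polar angle Z, modulus R, and the two
  Cartesian projections R cos Z, R sin Z)
* 7 kinematic channels x 2 segments x 4 statistics = 56
  (speed, acceleration, tangential and centripetal acceleration,
  trajectory angle, instantaneous displacement, radius of curvature)
* 6 channels x 2 segments zero-crossing rate = 12
* 23 leading spectral magnitudes of x for each segment = 46

Feature names encode channel, segment and statistic, e.g. ``x.down.mean``,
``zcr.v.up``, ``spec.x.down.07``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .preprocess import ChannelSet, derive_channels, spectrum
from .tablet_io import Recording

logger = logging.getLogger(__name__)

STATS = ("min", "max", "mean", "median")

SPATIAL_CHANNELS = ("x", "y", "altitude", "azimuth", "Z", "R", "Rcos", "Rsin")
KINEMATIC_CHANNELS = ("v", "a", "at", "ac", "phi", "d", "rho")
DEFAULT_ZCR_CHANNELS = ("x", "y", "pressure", "R", "v", "a")
#: fixed FFT length for spectral features so bins are comparable across
#: recordings of different durations (0.39 Hz resolution at 200 Hz)
SPECTRAL_NFFT = 512


@dataclass
class StatGroup:
    """One (channels x segments x statistics) block of the catalog."""

    channels: tuple[str, ...]
    segments: tuple[str, ...]
    stats: tuple[str, ...]

    def names(self) -> list[str]:
        return [
            f"{c}.{seg}.{st}"
            for c in self.channels
            for seg in self.segments
            for st in self.stats
        ]


@dataclass
class CatalogSpec:
    """Declarative description of a linear-feature catalog."""

    time_features: bool = True
    groups: list[StatGroup] = field(default_factory=list)
    zcr_channels: tuple[str, ...] = ()
    zcr_segments: tuple[str, ...] = ("down", "up")
    spectral_channels: tuple[str, ...] = ()
    spectral_segments: tuple[str, ...] = ("down", "up")
    n_spectral: int = 0
    expected_total: int | None = None
    catalog_id: str = "custom"

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.time_features:
            names += ["time.down", "time.up", "time.total"]
        for g in self.groups:
            names += g.names()
        for c in self.zcr_channels:
            for seg in self.zcr_segments:
                names.append(f"zcr.{c}.{seg}")
        for c in self.spectral_channels:
            for seg in self.spectral_segments:
                names += [f"spec.{c}.{seg}.{k:02d}" for k in range(1, self.n_spectral + 1)]
        if len(set(names)) != len(names):
            raise ValidationError("catalog generates duplicate feature names")
        if self.expected_total is not None and len(names) != self.expected_total:
            raise ValidationError(
                f"catalog generates {len(names)} features, expected {self.expected_total}"
            )
        return names

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CatalogSpec":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["groups"] = [
            StatGroup(
                channels=tuple(g["channels"]),
                segments=tuple(g["segments"]),
                stats=tuple(g["stats"]),
            )
            for g in d.get("groups", [])
        ]
        for key in ("zcr_channels", "zcr_segments", "spectral_channels", "spectral_segments"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_linear_catalog() -> CatalogSpec:
    """The shipped 186-feature linear catalog."""
    spec = CatalogSpec(
        time_features=True,
        groups=[
            StatGroup(("pressure",), ("down",), STATS + ("std",)),
            StatGroup(SPATIAL_CHANNELS, ("down", "up"), STATS),
            StatGroup(KINEMATIC_CHANNELS, ("down", "up"), STATS),
        ],
        zcr_channels=DEFAULT_ZCR_CHANNELS,
        spectral_channels=("x",),
        n_spectral=23,
        expected_total=186,
        catalog_id="LF-186",
    )
    return spec


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a feature name into (channel, segment, statistic).

    Time features report channel ``time``; ZCR and spectral features
    report statistic ``zcr`` / ``spec.<bin>``.
    """
    parts = name.split(".")
    if parts[0] == "time":
        return "time", parts[1], "duration"
    if parts[0] == "zcr":
        return parts[1], parts[2], "zcr"
    if parts[0] == "spec":
        return parts[1], parts[2], f"spec.{parts[3]}"
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    raise ValidationError(f"unparseable feature name {name!r}")


_STAT_FUNCS = {
    "min": np.min,
    "max": np.max,
    "mean": np.mean,
    "median": np.median,
    "std": lambda v: float(np.std(v, ddof=0)),
}


def zero_crossing_rate(series: np.ndarray, duration_s: float) -> float:
    """Sign changes of the mean-removed series per second."""
    if duration_s <= 0 or len(series) < 2:
        return 0.0
    zs = np.asarray(series, dtype=float) - np.mean(series)
    signs = np.sign(zs)
    signs = signs[signs != 0]  # exact zeros do not break a run
    if len(signs) < 2:
        return 0.0
    crossings = int(np.count_nonzero(np.diff(signs)))
    return crossings / duration_s


def _segment_durations(rec: Recording) -> tuple[float, float]:
    """(pen-down seconds, pen-up seconds); each inter-sample interval is
    attributed to the state of the sample that opens it."""
    dt = np.diff(rec.t)
    state = rec.pen_down[:-1]
    return float(dt[state].sum()), float(dt[~state].sum())


@dataclass
class FeatureVector:
    """Ordered map feature-name -> finite value for one recording."""

    values: dict[str, float]
    catalog_id: str = "custom"
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


@dataclass
class FeatureMatrix:
    """Recordings x features, with per-row class labels and metadata."""

    X: pd.DataFrame
    labels: pd.Series
    meta: pd.DataFrame  # subject_id, hand per row

    def __post_init__(self) -> None:
        if len(self.X) != len(self.labels) or len(self.X) != len(self.meta):
            raise ValidationError("feature matrix, labels and metadata differ in length")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, columns: list[str]) -> "FeatureMatrix":
        missing = [c for c in columns if c not in self.X.columns]
        if missing:
            raise ValidationError(f"unknown feature columns: {missing[:5]}")
        return FeatureMatrix(self.X[columns].copy(), self.labels.copy(), self.meta.copy())

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat(
            [self.meta.reset_index(drop=True),
             self.labels.rename("label").reset_index(drop=True),
             self.X.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("subject_id", "hand") if c in df.columns]
        feat_cols = [c for c in df.columns if c not in meta_cols + ["label"]]
        return cls(df[feat_cols], df["label"], df[meta_cols])


def _channel_sets(rec: Recording) -> dict[str, ChannelSet | None]:
    sets: dict[str, ChannelSet | None] = {}
    for seg in ("down", "up"):
        try:
            sets[seg] = derive_channels(rec, seg)
        except InsufficientDataError:
            sets[seg] = None
    return sets


def _spectral_block(
    ch: np.ndarray, rate: float, n_keep: int
) -> np.ndarray:
    """Magnitudes at the ``n_keep`` lowest non-DC bins of the fixed grid."""
    freqs, mag = spectrum(ch, rate)
    grid = np.arange(1, n_keep + 1) * rate / SPECTRAL_NFFT
    return np.interp(grid, freqs, mag)


def extract_linear(
    rec: Recording,
    spec: CatalogSpec | None = None,
    channel_sets: dict[str, ChannelSet | None] | None = None,
) -> FeatureVector:
    """Evaluate the catalog on one recording.

    A recording with no usable pen-up segment is not an error: all pen-up
    features are set to 0 and the vector carries a ``missing_up`` flag.
    ``channel_sets`` lets callers share derived channels with the
    non-linear extractor.
    """
    if spec is None:
        spec = default_linear_catalog()
    names = spec.feature_names()
    sets = channel_sets if channel_sets is not None else _channel_sets(rec)
    flags: dict[str, bool] = {}
    if sets.get("up") is None:
        flags["missing_up"] = True
        logger.info("recording %s: no usable pen-up segment; pen-up features set to 0",
                    rec.subject_id or "<unnamed>")

    t_down, t_up = _segment_durations(rec)
    durations = {"down": t_down, "up": t_up}
    values: dict[str, float] = {}
    spectral_cache: dict[tuple[str, str], np.ndarray] = {}
    for name in names:
        parts = name.split(".")
        if parts[0] == "time":
            if parts[1] == "total":
                values[name] = t_down + t_up
            else:
                values[name] = durations[parts[1]]
            continue
        if parts[0] == "zcr":
            _, ch_name, seg = parts
            cs = sets.get(seg)
            if cs is None:
                values[name] = 0.0
                continue
            values[name] = zero_crossing_rate(cs[ch_name], durations[seg] or rec.duration_s)
            continue
        if parts[0] == "spec":
            _, ch_name, seg, k = parts
            cs = sets.get(seg)
            if cs is None or cs.n_samples < 8:
                values[name] = 0.0
                continue
            key = (ch_name, seg)
            if key not in spectral_cache:
                spectral_cache[key] = _spectral_block(
                    cs[ch_name], cs.rate_hz, spec.n_spectral
                )
            values[name] = float(spectral_cache[key][int(k) - 1])
            continue
        ch_name, seg, stat = parts
        cs = sets.get(seg)
        if cs is None:
            values[name] = 0.0
            continue
        values[name] = float(_STAT_FUNCS[stat](cs[ch_name]))
    return FeatureVector(values=values, catalog_id=spec.catalog_id, flags=flags)
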