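"""Reading and writing digitizing-tablet pen recordings in SVC text format.

The SVC dialect used here is the plain-text layout common to online
handwriting corpora: a first line with the sample count, then one pen
sample per line with seven whitespace-separated fields::

    x  y  timestamp  pen_state  azimuth  altitude  pressure

``pen_state`` is 1 while the pen touches the surface (pen-down) and 0
while it travels in the air (pen-up).  Integer timestamps are read as
milliseconds, floats as seconds; both are normalised to float seconds
relative to the first sample.  Lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .errors import IntegrityError, SVCParseError, ValidationError

logger = logging.getLogger(__name__)

PEN_DOWN = 1
PEN_UP = 0


class PenSample(NamedTuple):
    """One tablet sample: position, time, pen orientation and pressure."""

    t: float
    x: float
    y: float
    pressure: float
    azimuth: float
    altitude: float
    pen_down: bool


@dataclass
class Recording:
    """A full pen recording as parallel channel arrays.

    Channels are stored column-wise (one numpy array per channel) because
    every downstream step operates on whole channels; ``samples`` exposes
    the row-wise :class:`PenSample` view when convenient.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    azimuth: np.ndarray
    altitude: np.ndarray
    pen_down: np.ndarray  # boolean mask, True = on-surface
    sampling_rate_hz: float = 200.0
    subject_id: str = ""
    hand: str = "unknown"  # dominant | non_dominant | unknown
    label: str = "unlabeled"  # CR | ET | unlabeled
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.altitude = np.asarray(self.altitude, dtype=float)
        self.pen_down = np.asarray(self.pen_down, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if n == 0:
            raise ValidationError("recording has no samples")
        for name in ("x", "y", "pressure", "azimuth", "altitude", "pen_down"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name!r} length differs from t")
        if np.any(np.diff(self.t) <= 0):
            raise IntegrityError("timestamps are not strictly increasing")
        if not np.any(self.pen_down):
            raise ValidationError("recording contains no pen-down samples")
        if np.any(self.pressure < 0):
            raise ValidationError("negative pressure values")
        if np.any((self.azimuth < 0) | (self.azimuth >= 360)):
            raise ValidationError("azimuth outside [0, 360)")
        if np.any((self.altitude < 0) | (self.altitude > 90)):
            raise ValidationError("altitude outside [0, 90]")
        if np.any(self.pressure[~self.pen_down] != 0):
            raise ValidationError("pen-up sample with non-zero pressure")
        if np.any(self.pressure[self.pen_down] <= 0):
            raise ValidationError("pen-down sample with non-positive pressure")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> Iterator[PenSample]:
        for i in range(len(self)):
            yield PenSample(
                t=float(self.t[i]),
                x=float(self.x[i]),
                y=float(self.y[i]),
                pressure=float(self.pressure[i]),
                azimuth=float(self.azimuth[i]),
                altitude=float(self.altitude[i]),
                pen_down=bool(self.pen_down[i]),
            )


def _parse_number(token: str, line_number: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SVCParseError(f"non-numeric {what}: {token!r}", line_number) from None


def read_svc(
    path: str | Path,
    *,
    subject_id: str = "",
    hand: str = "unknown",
    label: str = "unlabeled",
    sampling_rate_hz: float = 200.0,
) -> Recording:
    """Parse an SVC file into a validated :class:`Recording`.

    Raises :class:`SVCParseError` for malformed lines (with line number),
    :class:`IntegrityError` when the declared count disagrees with the
    number of data lines or timestamps are non-monotone.
    """
    path = Path(path)
    declared: int | None = None
    rows: list[tuple[float, ...]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line_number, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if declared is None:
                try:
                    declared = int(line)
                except ValueError:
                    raise SVCParseError(
                        f"expected integer sample count, got {line!r}", line_number
                    ) from None
                continue
            tokens = line.split()
            if len(tokens) != 7:
                raise SVCParseError(
                    f"expected 7 fields, got {len(tokens)}", line_number
                )
            x = _parse_number(tokens[0], line_number, "x")
            y = _parse_number(tokens[1], line_number, "y")
            ts = tokens[2]
            state = _parse_number(tokens[3], line_number, "pen state")
            azimuth = _parse_number(tokens[4], line_number, "azimuth")
            altitude = _parse_number(tokens[5], line_number, "altitude")
            pressure = _parse_number(tokens[6], line_number, "pressure")
            if state not in (0.0, 1.0):
                raise SVCParseError(
                    f"pen state must be 0 or 1, got {tokens[3]!r}", line_number
                )
            # integer timestamps are milliseconds, floats are seconds
            if any(c in ts for c in ".eE"):
                t = _parse_number(ts, line_number, "timestamp")
            else:
                t = _parse_number(ts, line_number, "timestamp") / 1000.0
            rows.append((t, x, y, pressure, azimuth, altitude, state))
    if declared is None:
        raise IntegrityError(f"{path}: no sample-count header found")
    if declared != len(rows):
        raise IntegrityError(
            f"{path}: header declares {declared} samples but {len(rows)} data lines found"
        )
    if not rows:
        raise IntegrityError(f"{path}: no data lines")
    arr = np.asarray(rows, dtype=float)
    t = arr[:, 0] - arr[0, 0]
    pen_down = arr[:, 6] == 1.0
    pressure = arr[:, 3]
    # pen_state is authoritative when the two channels disagree
    conflict_up = ~pen_down & (pressure > 0)
    if np.any(conflict_up):
        logger.warning(
            "%s: %d pen-up samples with non-zero pressure; zeroed (pen_state wins)",
            path,
            int(conflict_up.sum()),
        )
        pressure = np.where(conflict_up, 0.0, pressure)
    conflict_down = pen_down & (pressure <= 0)
    if np.any(conflict_down):
        logger.warning(
            "%s: %d pen-down samples with zero pressure; set to 1 device unit",
            path,
            int(conflict_down.sum()),
        )
        pressure = np.where(conflict_down, 1.0, pressure)
    return Recording(
        t=t,
        x=arr[:, 1],
        y=arr[:, 2],
        pressure=pressure,
        azimuth=arr[:, 4],
        altitude=arr[:, 5],
        pen_down=pen_down,
        sampling_rate_hz=sampling_rate_hz,
        subject_id=subject_id,
        hand=hand,
        label=label,
    )


def _format_number(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _format_timestamp(t: float) -> str:
    ms = t * 1000.0
    if abs(ms - round(ms)) < 1e-6:
        return str(int(round(ms)))
    return repr(float(t))


def write_svc(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as an SVC file parseable by :func:`read_svc`.

    Timestamps that fall on the millisecond grid are written as integer
    milliseconds (the common SVC convention); others as float seconds.
    Round-tripping through :func:`read_svc` restores every field.
    """
    rec.validate()
    path = Path(path)
    lines = [str(len(rec))]
    for s in rec.samples:
        lines.append(
            " ".join(
                (
                    _format_number(s.x),
                    _format_number(s.y),
                    _format_timestamp(s.t),
                    str(int(s.pen_down)),
                    _format_number(s.azimuth),
                    _format_number(s.altitude),
                    _format_number(s.pressure),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
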