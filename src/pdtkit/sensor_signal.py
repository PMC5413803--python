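"""Raw accelerometer streams and their conversion to drift/pronation angles.

The pronator drift test is recorded by a three-axis accelerometer strapped to
the volar side of each wrist, palms up.  In the device frame the Y axis runs
along the forearm from wrist toward the fingers, X across the wrist toward the
thumb (right arm; left-arm devices are mirrored on load), and Z out of the
device face — pointing at the ceiling in the ideal palm-up posture.  During a
quasi-static hold the accelerometer measures the gravity reaction, so the
orientation of the forearm can be read off the low-frequency part of the
signal:

* drift angle    theta = arcsin(g_y)   — downward deviation of the forearm
  from the horizontal plane (positive = hand dropping);
* pronation angle  phi = atan2(g_x, g_z) — rotation about the forearm axis
  from palm-up (0 deg) toward palm-down (+90 deg and beyond).

All filtering is zero-phase (forward-backward order-2 Butterworth) so angle
series stay time-aligned.  Two bands matter: a narrow gravity-isolation band
(1 Hz default in :func:`estimate_gravity`) captures the purely postural
orientation, while the angle-extraction band (5 Hz default in
:func:`stream_to_angles`) additionally keeps the few-hertz jitter of the
held arm that the OSC features quantify, rejecting only sensor noise above.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ContractError, DataError, FormatError, ParameterError

__all__ = [
    "SIDES",
    "G_MS2",
    "SignalStream",
    "AngleSeries",
    "load_stream",
    "estimate_gravity",
    "drift_angle",
    "pronation_angle",
    "stream_to_angles",
]

log = logging.getLogger(__name__)

SIDES = ("weak", "counter")

#: standard gravity, for m/s^2 -> g conversion
G_MS2 = 9.80665

# filtfilt pad length for an order-2 filter (3 taps): minimum usable stream
_FILTFILT_PADLEN = 9


@dataclass
class SignalStream:
    """Uniformly sampled 3-axis acceleration from one wrist device, in units of g."""

    t: np.ndarray
    acc: np.ndarray  # shape (n, 3): columns ax, ay, az
    rate_hz: float
    side: str
    subject_id: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise ContractError(
                f"stream shape mismatch: t {self.t.shape}, acc {self.acc.shape}"
            )
        if self.t.size == 0:
            raise DataError("empty stream")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.acc)):
            raise DataError("non-finite values in stream")
        if self.t[0] < 0:
            raise DataError("timestamps must be >= 0")
        dt = np.diff(self.t)
        if self.t.size > 1 and np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.rate_hz <= 0:
            raise ParameterError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.t.size > 1:
            nominal = 1.0 / self.rate_hz
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise DataError(
                    "sample spacing inconsistent with rate_hz beyond 1%; "
                    "resample first (load_stream does this automatically)"
                )
        if np.any(np.linalg.norm(self.acc, axis=1) == 0):
            raise DataError("zero-norm acceleration sample")
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class AngleSeries:
    """Per-sample drift and pronation angles (degrees) for one arm."""

    t: np.ndarray
    drift_deg: np.ndarray
    pron_deg: np.ndarray
    side: str
    subject_id: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.drift_deg = np.asarray(self.drift_deg, dtype=float)
        self.pron_deg = np.asarray(self.pron_deg, dtype=float)
        if not (self.t.shape == self.drift_deg.shape == self.pron_deg.shape):
            raise ContractError("t, drift_deg, pron_deg must have equal length")
        if self.t.size == 0:
            raise DataError("empty angle series")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if np.any(np.abs(self.drift_deg) > 90 + 1e-9):
            raise DataError("drift angle outside [-90, 90] degrees")
        if np.any(np.abs(self.pron_deg) > 180 + 1e-9):
            raise DataError("pronation angle outside [-180, 180] degrees")

    @property
    def n_samples(self) -> int:
        return self.t.size


_FILENAME_RE = re.compile(r"^(?P<subject>.+)_(?P<side>weak|counter)$")


def load_stream(
    path: str | Path,
    *,
    units: str = "g",
    side: str | None = None,
    subject_id: str | None = None,
    rate_hz: float | None = None,
    hand: str = "right",
) -> SignalStream:
    """Read one sensor file (CSV with header ``t,ax,ay,az``) into a SignalStream.

    Parameters
    ----------
    units:
        ``"g"`` (default) or ``"ms2"``; m/s^2 inputs are converted to g.
    side, subject_id:
        Taken from the filename ``<subject>_<side>.csv`` when not given.
    rate_hz:
        Target sampling rate.  Defaults to the reciprocal median spacing.
        Irregularly sampled (but monotonic) input is resampled onto a uniform
        grid at this rate by linear interpolation.
    hand:
        ``"left"`` mirrors the X axis so that positive pronation means
        palm-toward-prone on both arms.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sensor file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty sensor file: {path}") from exc
    required = ["t", "ax", "ay", "az"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; header must contain t,ax,ay,az")
    if len(frame) == 0:
        raise DataError(f"{path}: no samples")

    t = frame["t"].to_numpy(dtype=float)
    acc = frame[["ax", "ay", "az"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(acc)):
        raise DataError(f"{path}: non-finite values")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: non-monotonic timestamps")

    if units == "ms2":
        acc = acc / G_MS2
    elif units != "g":
        raise ParameterError(f"units must be 'g' or 'ms2', got {units!r}")

    if hand == "left":
        acc = acc * np.array([-1.0, 1.0, 1.0])
    elif hand != "right":
        raise ParameterError(f"hand must be 'left' or 'right', got {hand!r}")

    if side is None or subject_id is None:
        m = _FILENAME_RE.match(path.stem)
        if m is None and (side is None or subject_id is None):
            raise FormatError(
                f"{path}: cannot resolve side/subject from filename; "
                "expected <subject>_<weak|counter>.csv or explicit arguments"
            )
        side = side or m.group("side")
        subject_id = subject_id or m.group("subject")

    if t.size > 1:
        dt = np.diff(t)
        inferred = 1.0 / float(np.median(dt))
        rate = float(rate_hz) if rate_hz is not None else inferred
        nominal = 1.0 / rate
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            # irregular but monotonic: resample by linear interpolation
            grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * rate)) + 1) / rate
            acc = np.column_stack([np.interp(grid, t, acc[:, k]) for k in range(3)])
            t = grid
            log.info("%s: irregular sampling, resampled to %.6g Hz", path, rate)
    else:
        rate = float(rate_hz) if rate_hz is not None else 50.0

    return SignalStream(t=t, acc=acc, rate_hz=rate, side=side, subject_id=subject_id)


def estimate_gravity(stream: SignalStream, cutoff_hz: float = 1.0) -> np.ndarray:
    """Per-sample unit gravity direction from zero-phase low-pass filtering.

    Returns an (n, 3) array of unit vectors.  Zero-phase (forward-backward)
    filtering keeps the angle series aligned in time with the raw signal.
    """
    if cutoff_hz <= 0:
        raise ParameterError(f"cutoff_hz must be positive, got {cutoff_hz}")
    nyquist = stream.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff_hz={cutoff_hz} must be below the Nyquist frequency {nyquist}"
        )
    if stream.n_samples <= _FILTFILT_PADLEN or stream.duration_s < 1.0 / cutoff_hz:
        raise DataError(
            f"stream too short for gravity estimation: {stream.n_samples} samples "
            f"({stream.duration_s:.3g} s); need > {_FILTFILT_PADLEN} samples and "
            f">= {1.0 / cutoff_hz:.3g} s"
        )
    b, a = butter(2, cutoff_hz, btype="low", fs=stream.rate_hz)
    low = filtfilt(b, a, stream.acc, axis=0)
    norms = np.linalg.norm(low, axis=1)
    if np.any(norms < 1e-12):
        raise DataError("zero-norm filtered acceleration; cannot infer orientation")
    return low / norms[:, None]


def _check_unit(g: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    norms = np.linalg.norm(g, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ContractError("gravity vectors must be unit norm")
    return g


def drift_angle(g: np.ndarray) -> np.ndarray | float:
    """Drift angle in degrees from unit gravity vector(s): arcsin(g_y).

    0 deg for a horizontal forearm, positive when the hand drops below the
    horizontal plane, 90 deg for a vertical (hanging) forearm.
    """
    g = _check_unit(g)
    theta = np.degrees(np.arcsin(np.clip(g[..., 1], -1.0, 1.0)))
    return float(theta) if theta.ndim == 0 else theta


def pronation_angle(g: np.ndarray, *, initial_deg: float = 0.0) -> np.ndarray | float:
    """Pronation angle in degrees from unit gravity vector(s): atan2(g_x, g_z).

    0 deg palm-up, +90 deg quarter pronation (thumb down).  When the forearm
    is exactly vertical (g_x = g_z = 0) pronation is undefined; the previous
    valid value is held (``initial_deg`` if it happens at the start) and a
    warning is logged.
    """
    g = _check_unit(g)
    scalar = g.ndim == 1
    g2 = np.atleast_2d(g)
    phi = np.degrees(np.arctan2(g2[:, 0], g2[:, 2]))
    undef = np.hypot(g2[:, 0], g2[:, 2]) < 1e-9
    if np.any(undef):
        log.warning(
            "pronation undefined at %d sample(s) (vertical forearm); holding last value",
            int(undef.sum()),
        )
        last = float(initial_deg)
        for i in range(phi.size):
            if undef[i]:
                phi[i] = last
            else:
                last = phi[i]
    return float(phi[0]) if scalar else phi


def stream_to_angles(stream: SignalStream, cutoff_hz: float = 5.0) -> AngleSeries:
    """Full raw-signal-to-angles conversion for one device.

    The default band (order-2 zero-phase low-pass at 5 Hz) is deliberately
    wider than the 1 Hz gravity-isolation band: physiological jitter of the
    held arm lives at a few hertz and must survive into the angle series for
    the OSC features to measure it, while sensor noise above the band is
    still suppressed.  Postural statistics (AVG/MAX) are insensitive to the
    choice; pass ``cutoff_hz=1.0`` for a pure postural trace.
    """
    g = estimate_gravity(stream, cutoff_hz=cutoff_hz)
    return AngleSeries(
        t=stream.t.copy(),
        drift_deg=drift_angle(g),
        pron_deg=pronation_angle(g),
        side=stream.side,
        subject_id=stream.subject_id,
    )
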