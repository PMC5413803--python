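"""The 12-feature summary of a pronator drift test recording.

For each arm (WEAK = paretic side, CNT = counter side) and each measure
(DRT = drift, PRN = pronation) three statistics are taken over the analysis
window: AVG (mean angle), MAX (signed maximum — the largest drop / largest
pronation reached), and OSC (root-mean-square of the linearly detrended
series, a jitter magnitude that ignores the slow postural trend).

The test lasts 20 s; analysis covers the second half, [10 s, 20 s), so that
the initial dip — the transient settling under the device's weight right
after arm extension — does not contaminate the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import detrend

from .classifiers import LabeledDataset
from .errors import ContractError, DataError, ParameterError
from .sensor_signal import AngleSeries

__all__ = [
    "FEATURE_NAMES",
    "MRC_GRADES",
    "EXCLUDED_GRADES",
    "WindowConfig",
    "PDTFeatures",
    "SubjectRecord",
    "analysis_window",
    "summarize",
    "extract_features",
    "features_frame",
    "write_feature_matrix",
    "read_feature_matrix",
    "frame_to_dataset",
]

#: fixed feature order used by every writer/reader in the package
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{side}-{meas}-{stat}"
    for side in ("WEAK", "CNT")
    for meas in ("DRT", "PRN")
    for stat in ("AVG", "MAX", "OSC")
)

#: Medical Research Council muscle-power grades
MRC_GRADES = ("0", "1", "2", "3", "4", "4+", "5")

#: grades excluded from analysis: the test requires resisting gravity plus device weight
EXCLUDED_GRADES = frozenset({"0", "1", "2", "3"})


@dataclass(frozen=True)
class WindowConfig:
    """Test duration and analysis window (seconds)."""

    test_duration_s: float = 20.0
    analysis_start_s: float = 10.0
    analysis_end_s: float | None = None

    def __post_init__(self) -> None:
        end = self.end_s
        if not (0 <= self.analysis_start_s < end <= self.test_duration_s):
            raise ParameterError(
                f"require 0 <= start < end <= duration, got start={self.analysis_start_s}, "
                f"end={end}, duration={self.test_duration_s}"
            )

    @property
    def end_s(self) -> float:
        return self.test_duration_s if self.analysis_end_s is None else self.analysis_end_s


@dataclass
class PDTFeatures:
    """The 12 named summary features for one subject."""

    subject_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ContractError(
                f"features must contain exactly the 12 names in canonical order; "
                f"got {list(self.values.keys())}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SubjectRecord:
    """One subject: identity, group label, MRC grade and (optionally) features."""

    subject_id: str
    group: str  # "patient" | "control"
    mrc_grade: str
    features: PDTFeatures | None = None
    weak_label: str = "paretic"  # controls: "nondominant" (no true weak side)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ParameterError(f"group must be patient|control, got {self.group!r}")
        self.mrc_grade = str(self.mrc_grade)
        if self.mrc_grade not in MRC_GRADES:
            raise ParameterError(
                f"mrc_grade must be one of {MRC_GRADES}, got {self.mrc_grade!r}"
            )

    @property
    def eligible(self) -> bool:
        """False for MRC 0-3: too weak to hold the test posture against gravity."""
        return self.mrc_grade not in EXCLUDED_GRADES


def analysis_window(series: AngleSeries, cfg: WindowConfig = WindowConfig()) -> AngleSeries:
    """Restrict an angle series to the half-open analysis window [start, end)."""
    end = cfg.end_s
    dt = float(np.median(np.diff(series.t))) if series.n_samples > 1 else 0.0
    covered = series.t[-1] + dt
    if series.t[0] > cfg.analysis_start_s + 1e-9 or covered < end - 1e-9:
        raise DataError(
            f"series spans [{series.t[0]:.3g}, {covered:.3g}] s but the analysis "
            f"window needs [0, {end:.3g}] s ({end - covered:.3g} s missing)"
        )
    mask = (series.t >= cfg.analysis_start_s - 1e-9) & (series.t < end - 1e-9)
    if not np.any(mask):
        raise DataError("analysis window contains no samples")
    return AngleSeries(
        t=series.t[mask],
        drift_deg=series.drift_deg[mask],
        pron_deg=series.pron_deg[mask],
        side=series.side,
        subject_id=series.subject_id,
    )


def summarize(
    angle_values: Sequence[float] | np.ndarray, *, osc_method: str = "rms_detrend"
) -> tuple[float, float, float]:
    """(AVG, MAX, OSC) for one windowed angle sequence.

    AVG is the arithmetic mean, MAX the signed maximum (greatest downward
    drift / greatest pronation), and OSC the jitter magnitude: RMS of the
    linearly detrended sequence by default, or the direction-reversal count
    with ``osc_method="reversals"``.
    """
    x = np.asarray(angle_values, dtype=float)
    if x.size == 0:
        raise ContractError("cannot summarize an empty sequence")
    avg = float(np.mean(x))
    mx = float(np.max(x))
    if osc_method == "rms_detrend":
        resid = detrend(x) if x.size > 1 else np.zeros(1)
        osc = float(np.sqrt(np.mean(resid**2)))
    elif osc_method == "reversals":
        d = np.diff(x)
        d = d[d != 0]
        osc = float(np.sum(np.sign(d[1:]) != np.sign(d[:-1]))) if d.size > 1 else 0.0
    else:
        raise ParameterError(f"unknown osc_method {osc_method!r}")
    return avg, mx, osc


def extract_features(
    weak: AngleSeries,
    counter: AngleSeries,
    cfg: WindowConfig = WindowConfig(),
    *,
    osc_method: str = "rms_detrend",
) -> PDTFeatures:
    """Extract the 12 PDT features from the two arms' angle series."""
    if weak.subject_id != counter.subject_id:
        raise DataError(
            f"subject mismatch: {weak.subject_id!r} vs {counter.subject_id!r}"
        )
    if weak.side != "weak" or counter.side != "counter":
        raise DataError(
            f"expected sides (weak, counter), got ({weak.side!r}, {counter.side!r})"
        )
    values: dict[str, float] = {}
    for label, series in (("WEAK", weak), ("CNT", counter)):
        win = analysis_window(series, cfg)
        for meas, data in (("DRT", win.drift_deg), ("PRN", win.pron_deg)):
            avg, mx, osc = summarize(data, osc_method=osc_method)
            values[f"{label}-{meas}-AVG"] = avg
            values[f"{label}-{meas}-MAX"] = mx
            values[f"{label}-{meas}-OSC"] = osc
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return PDTFeatures(subject_id=weak.subject_id, values=ordered)


# ---------------------------------------------------------------------------
# feature-matrix I/O

_META_COLUMNS = ["subject_id", "group", "mrc", "weak_label"]


def features_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (with features) into the canonical feature matrix."""
    rows = []
    for rec in records:
        if rec.features is None:
            raise DataError(f"subject {rec.subject_id}: no features extracted")
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "mrc": rec.mrc_grade,
            "weak_label": rec.weak_label,
        }
        row.update(rec.features.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + list(FEATURE_NAMES))


def write_feature_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"mrc": str})
    missing = [c for c in _META_COLUMNS + list(FEATURE_NAMES) if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return frame


def frame_to_dataset(frame: pd.DataFrame, *, enforce_mrc: bool = True) -> LabeledDataset:
    """Feature matrix -> LabeledDataset (+1 patient, -1 control).

    Subjects with MRC grade 0-3 are dropped (the test's eligibility rule)
    unless ``enforce_mrc`` is False.
    """
    if enforce_mrc:
        frame = frame[~frame["mrc"].astype(str).isin(EXCLUDED_GRADES)]
    if len(frame) == 0:
        raise DataError("no eligible subjects in feature matrix")
    y = np.where(frame["group"].to_numpy() == "patient", 1, -1)
    X = frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return LabeledDataset(
        X=X,
        y=y,
        feature_names=list(FEATURE_NAMES),
        subject_ids=list(frame["subject_id"].astype(str)),
    )
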