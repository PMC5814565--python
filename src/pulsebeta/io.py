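"""Waveform and table I/O.

Records are synchronized multichannel time series sampled uniformly:
ECG (arbitrary units), continuous noninvasive blood pressure ``bp``
(mmHg) and a photoplethysmogram ``ppg`` (arbitrary units).  The primary
on-disk format is a single CSV with columns ``time, ecg, bp, ppg``;
human-readable and sufficient for raw 1000 Hz streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

#: Default column names for the four channels of a waveform CSV.
DEFAULT_CHANNELS: Mapping[str, str] = {
    "time": "time",
    "ecg": "ecg",
    "bp": "bp",
    "ppg": "ppg",
}

#: Relative tolerance on the sample interval when checking uniform sampling.
_DT_RTOL = 1e-4


@dataclass
class WaveformRecord:
    """Synchronized ECG / blood-pressure / PPG record.

    Parameters
    ----------
    time : ndarray
        Seconds from record start, uniformly spaced at ``1/fs``.
    ecg : ndarray
        Electrocardiogram, arbitrary units.
    bp : ndarray
        Blood pressure :math:`P_b(t)` in mmHg; must be finite.
    ppg : ndarray
        Photoplethysmogram :math:`P_l(t)`, arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form provenance (subject id, protocol label, units).
    """

    time: np.ndarray
    ecg: np.ndarray
    bp: np.ndarray
    ppg: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        n = self.time.size
        if n < 2:
            raise FormatError("record must contain at least 2 samples")
        for name in ("ecg", "bp", "ppg"):
            if getattr(self, name).size != n:
                raise FormatError(
                    f"channel {name!r} has {getattr(self, name).size} samples, "
                    f"expected {n}"
                )
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise FormatError("time must be strictly increasing (duplicate or "
                              "non-monotonic timestamps)")
        if not np.allclose(dt, 1.0 / self.fs, rtol=_DT_RTOL, atol=1e-9):
            raise FormatError(
                f"non-uniform sampling: sample intervals deviate from 1/fs="
                f"{1.0 / self.fs:g} s beyond tolerance"
            )
        if not np.all(np.isfinite(self.bp)):
            raise DataError("bp contains non-finite samples")
        if not np.all(np.isfinite(self.ppg)):
            raise DataError("ppg contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BaselineWindow:
    """A no-stimulation time window [start, end) in seconds used to
    normalize the stiffness index."""

    start: float
    end: float
    label: str = "baseline"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ConfigError(f"baseline window start ({self.start}) must "
                              f"precede end ({self.end})")

    def contains(self, t: float | np.ndarray):
        return (t >= self.start) & (t < self.end)


def _interpolate_short_gaps(x: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap samples; longer runs error."""
    x = x.copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x
    # locate runs of NaN
    idx = np.flatnonzero(isnan)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    for run in runs:
        if run.size > max_gap:
            raise DataError(
                f"channel {name!r} has a gap of {run.size} samples, longer "
                f"than the configured limit of {max_gap}"
            )
        if run[0] == 0 or run[-1] == x.size - 1:
            raise DataError(f"channel {name!r} has NaN at the record edge")
    good = np.flatnonzero(~isnan)
    x[isnan] = np.interp(np.flatnonzero(isnan), good, x[good])
    logger.warning("channel %s: interpolated %d NaN samples in %d short gaps",
                   name, int(isnan.sum()), len(runs))
    return x


def read_record(
    path,
    channels: Mapping[str, str] | None = None,
    fs: float | None = None,
    gap_limit_ms: float = 20.0,
    meta: dict | None = None,
) -> WaveformRecord:
    """Read a waveform CSV into a validated :class:`WaveformRecord`.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row naming the time column and
        the three channels.
    channels : mapping, optional
        Maps the canonical names ``time/ecg/bp/ppg`` to column names in
        the file.  Defaults to the identity mapping.
    fs : float, optional
        Expected sampling rate in Hz.  If omitted it is inferred from the
        median sample interval.
    gap_limit_ms : float
        NaN runs up to this duration are linearly interpolated with a
        logged warning; longer runs raise :class:`DataError`.

    Raises
    ------
    FormatError
        Missing channel, duplicated timestamps, non-uniform sampling.
    DataError
        NaN gaps beyond the limit, non-finite pressure samples.
    """
    channels = dict(DEFAULT_CHANNELS if channels is None else channels)
    df = pd.read_csv(path)
    cols = {}
    for canon in ("time", "ecg", "bp", "ppg"):
        col = channels.get(canon, canon)
        if col not in df.columns:
            raise FormatError(f"file {path} is missing channel column {col!r} "
                              f"(canonical {canon!r})")
        cols[canon] = df[col].to_numpy(dtype=float)
    t = cols["time"]
    if not np.all(np.isfinite(t)):
        raise FormatError("time column contains non-finite values")
    if t.size < 2:
        raise FormatError("record must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time must be strictly increasing (duplicate or "
                          "non-monotonic timestamps)")
    inferred_fs = 1.0 / float(np.median(dt))
    if fs is None:
        fs = inferred_fs
    elif abs(inferred_fs - fs) / fs > _DT_RTOL:
        raise FormatError(f"sampling rate in file ({inferred_fs:g} Hz) does "
                          f"not match configured fs ({fs:g} Hz)")
    max_gap = max(1, int(round(gap_limit_ms * fs / 1000.0)))
    for name in ("ecg", "bp", "ppg"):
        cols[name] = _interpolate_short_gaps(cols[name], max_gap, name)
    return WaveformRecord(time=t, ecg=cols["ecg"], bp=cols["bp"],
                          ppg=cols["ppg"], fs=float(fs),
                          meta=dict(meta or {}))


def write_record(record: WaveformRecord, path) -> None:
    """Write a record to the canonical 4-column CSV."""
    df = pd.DataFrame({
        "time": record.time,
        "ecg": record.ecg,
        "bp": record.bp,
        "ppg": record.ppg,
    })
    df.to_csv(path, index=False, float_format="%.10g")


#: Columns of the beat-estimate table, in on-disk order.
ESTIMATE_COLUMNS: Sequence[str] = (
    "beat", "t0_s", "mu", "eta", "beta_A", "beta", "intercept", "r2",
    "n_masked", "accepted", "valid", "note",
)


def write_beat_estimates(estimates, path) -> None:
    """Write per-beat estimates to CSV, one row per beat.

    Floats are written at 12 significant digits so that a read/write
    round trip is lossless to that precision.
    """
    rows = list(estimates)
    if not rows:
        raise ValueError("cannot write an empty sequence of beat estimates")
    df = pd.DataFrame([e.as_row() for e in rows], columns=ESTIMATE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_beat_estimates(path) -> pd.DataFrame:
    """Read a beat-estimate CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"beat-estimate table missing columns {sorted(missing)}")
    return df
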