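"""QRS-triggered beat segmentation.

The per-beat estimator needs each cardiac cycle delimited and anchored at
a reference time t0 inside the cycle; the R wave is used as that anchor.
R peaks are detected with a Pan-Tompkins-style energy detector (band-pass,
squared derivative, moving-window integration, adaptive threshold with a
refractory period), which is adequate for clean supine recordings and for
synthetic fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import SegmentationError
from .io import WaveformRecord

logger = logging.getLogger(__name__)

#: Physiologic bounds on the heart period in seconds (30-200 bpm).
DEFAULT_PERIOD_BOUNDS = (0.3, 2.0)


@dataclass(frozen=True)
class BeatWindow:
    """One cardiac cycle: the half-open sample span [start, end) between
    consecutive R waves.

    ``t0_sample`` is the leading R-wave sample, the reference time against
    which the estimator differences all signals.  ``mean_bp`` is the
    arithmetic mean blood pressure over the window; the estimator's
    above-mean mask is taken against it.
    """

    index: int
    start_sample: int
    end_sample: int
    t0_sample: int
    mean_bp: float

    def __post_init__(self) -> None:
        if not (self.start_sample <= self.t0_sample < self.end_sample):
            raise SegmentationError(
                f"beat {self.index}: t0 sample {self.t0_sample} outside "
                f"[{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def slice(self) -> slice:
        return slice(self.start_sample, self.end_sample)


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.25,
    band_hz: tuple[float, float] = (5.0, 25.0),
    threshold_frac: float = 0.25,
) -> np.ndarray:
    """Detect R-peak sample indices in an ECG channel.

    Band-pass 5-25 Hz, squared derivative, 150 ms moving-window
    integration, peak picking at ``threshold_frac`` of the maximum
    integrated energy with a refractory period, then peak refinement on
    the band-passed signal.  Deterministic for fixed input; invariant to
    constant offsets (the band-pass removes DC).

    Returns
    -------
    ndarray of int
        Strictly increasing sample indices.

    Raises
    ------
    SegmentationError
        If the signal is too short or no peak is found.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 * fs:
        raise SegmentationError(
            f"ECG too short for detection: {ecg.size} samples < 2 s at {fs} Hz"
        )
    lo, hi = band_hz
    nyq = fs / 2.0
    sos = sps.butter(2, [lo / nyq, min(hi, 0.95 * nyq) / nyq], btype="band",
                     output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_energy = integ.max()
    if peak_energy <= 0:
        raise SegmentationError("no QRS energy found (flat ECG)")
    distance = max(1, int(round(refractory_s * fs)))
    locs, _ = sps.find_peaks(integ, height=threshold_frac * peak_energy,
                             distance=distance)
    if locs.size == 0:
        raise SegmentationError("no R peaks found above threshold")
    # refine to the local maximum of the band-passed ECG near each
    # energy peak (the integrator delays/widens the response)
    half = max(1, int(round(0.10 * fs)))
    refined = []
    for loc in locs:
        a = max(0, loc - half)
        b = min(ecg.size, loc + half + 1)
        refined.append(a + int(np.argmax(filt[a:b])))
    peaks = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def segment_beats(
    record: WaveformRecord,
    r_peaks: np.ndarray,
    period_bounds: tuple[float, float] = DEFAULT_PERIOD_BOUNDS,
) -> list[BeatWindow]:
    """Partition a record into R-to-R beat windows.

    One window per R-R interval; the leading R is the window start and the
    reference sample t0.  Samples before the first and after the last R
    (partial cycles) are discarded.  Intervals whose implied heart period
    falls outside ``period_bounds`` are dropped with a warning.

    Raises
    ------
    SegmentationError
        Fewer than 2 R peaks.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise SegmentationError(f"need at least 2 R peaks, got {r_peaks.size}")
    if np.any(np.diff(r_peaks) <= 0):
        raise SegmentationError("R peaks must be strictly increasing")
    lo, hi = period_bounds
    beats: list[BeatWindow] = []
    n_dropped = 0
    for a, b in zip(r_peaks[:-1], r_peaks[1:]):
        period = (b - a) / record.fs
        if not (lo <= period <= hi):
            n_dropped += 1
            continue
        beats.append(BeatWindow(
            index=len(beats),
            start_sample=int(a),
            end_sample=int(b),
            t0_sample=int(a),
            mean_bp=float(np.mean(record.bp[a:b])),
        ))
    if n_dropped:
        logger.warning("dropped %d beats with heart period outside %s s",
                       n_dropped, period_bounds)
    return beats
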