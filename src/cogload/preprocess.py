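"""Raw-signal cleaning and windowing.

The physiological pipeline expects photoplethysmogram (PPG) and skin
conductance (GSR) channels sampled uniformly (250 Hz in the reference
protocol).  Cleaning follows the conventional order for pulse signals:
DC-offset removal, Savitzky-Golay detrending of the sub-0.1 Hz drift,
then peak detection to obtain inter-beat (RR) intervals.  All signals
are finally cut into fixed non-overlapping windows (60 s by default) so
that every downstream feature is computed on equal-length support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import iqr


class InsufficientBeatsError(ValueError):
    """Raised when fewer than two pulse peaks can be located."""


@dataclass(frozen=True)
class RawSignal:
    """Uniformly sampled single-channel time series.

    Parameters
    ----------
    samples : ndarray
        Amplitudes (µS for GSR, arbitrary units for PPG).
    fs : float
        Sampling rate in Hz.
    channel : str
        ``"ppg"`` or ``"gsr"``.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = "ppg"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class TriaxialSignal:
    """Uniformly sampled 3-axis accelerometer recording."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("axis arrays must have equal length")
        if self.x.size < 1:
            raise ValueError("axes must be non-empty")

    @property
    def duration(self) -> float:
        return self.x.size / self.fs

    @property
    def resultant(self) -> np.ndarray:
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass(frozen=True)
class RRSeries:
    """Successive inter-beat intervals in milliseconds.

    ``rr[i] = 1000 * (peak_times[i+1] - peak_times[i])``; ``n`` is the
    interval count (one less than the number of peaks).
    """

    rr: np.ndarray
    peak_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rr", np.asarray(self.rr, dtype=float))
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        if self.rr.size != self.peak_times.size - 1:
            raise ValueError("rr length must be len(peak_times) - 1")
        if np.any(self.rr <= 0):
            raise ValueError("all RR intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.rr.size)


@dataclass(frozen=True)
class Segment:
    """One fixed-duration analysis window."""

    window_index: int
    t_start: float
    t_end: float
    payload: object
    session_label: str | None = None


def remove_dc(signal: RawSignal) -> RawSignal:
    """Subtract the mean so the signal oscillates around zero."""
    return replace(signal, samples=signal.samples - signal.samples.mean())


def detrend_savgol(
    signal: RawSignal,
    window_length: int | None = None,
    polyorder: int = 3,
) -> RawSignal:
    """Remove the low-frequency trend with a Savitzky-Golay smoother.

    The smoothed signal (the trend estimate) is subtracted from the
    input.  The default window of ``4*fs + 1`` samples (~4 s) passes
    sub-0.1 Hz drift into the trend while leaving ~1 Hz pulse energy in
    the residual; shorter windows put the pulse band on a negative
    side-lobe of the smoother's frequency response, inflating it and
    wobbling pulse maxima by several milliseconds.
    """
    n = signal.samples.size
    if window_length is None:
        window_length = int(4 * signal.fs) + 1
        window_length = min(window_length, n if n % 2 == 1 else n - 1)
    if window_length % 2 == 0:
        raise ValueError(f"window_length must be odd, got {window_length}")
    if window_length <= polyorder:
        raise ValueError(
            f"window_length ({window_length}) must exceed polyorder ({polyorder})"
        )
    if window_length > n:
        raise ValueError(f"window_length ({window_length}) exceeds signal length ({n})")
    trend = savgol_filter(signal.samples, window_length, polyorder)
    return replace(signal, samples=signal.samples - trend)


def smooth_gaussian(signal: RawSignal, sigma_s: float = 0.2) -> RawSignal:
    """Gaussian smoother used on skin conductance before decomposition."""
    if sigma_s <= 0:
        return signal
    return replace(
        signal, samples=gaussian_filter1d(signal.samples, sigma=sigma_s * signal.fs)
    )


def detect_peaks(
    signal: RawSignal,
    min_distance_s: float = 0.33,
    prominence_frac: float = 0.30,
    smooth_sigma_s: float = 0.02,
) -> np.ndarray:
    """Locate pulse peaks on a detrended, mean-corrected signal.

    Peaks are local maxima separated by at least ``min_distance_s``
    (0.33 s by default, i.e. at most 180 bpm) with prominence of at
    least ``prominence_frac`` times the amplitude inter-quartile range.
    A light Gaussian smoothing (``smooth_sigma_s``, 20 ms by default)
    suppresses broadband noise peaks without shifting ~1 Hz pulse
    maxima.

    Returns
    -------
    ndarray
        Strictly increasing peak times in seconds.

    Raises
    ------
    InsufficientBeatsError
        If fewer than two peaks are found.
    """
    samples = signal.samples
    if smooth_sigma_s > 0:
        samples = gaussian_filter1d(samples, sigma=smooth_sigma_s * signal.fs)
    spread = iqr(samples)
    prominence = prominence_frac * spread if spread > 0 else None
    if prominence is None or prominence <= 0:
        raise InsufficientBeatsError("signal has no amplitude spread; no beats found")
    distance = max(1, int(round(min_distance_s * signal.fs)))
    idx, _ = find_peaks(samples, distance=distance, prominence=prominence)
    if idx.size < 2:
        raise InsufficientBeatsError(f"found {idx.size} peaks; need at least 2")
    # parabolic sub-sample refinement removes the grid-quantization error
    t = idx.astype(float)
    interior = (idx > 0) & (idx < samples.size - 1)
    i = idx[interior]
    num = samples[i - 1] - samples[i + 1]
    den = samples[i - 1] - 2 * samples[i] + samples[i + 1]
    t[interior] = i + 0.5 * np.where(den != 0, num / den, 0.0)
    return signal.start_time + t / signal.fs


def peaks_to_rr(peak_times: np.ndarray) -> RRSeries:
    """Convert peak times (s) to inter-beat intervals (ms)."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise InsufficientBeatsError("need at least 2 peaks to form RR intervals")
    rr = 1000.0 * np.diff(peak_times)
    return RRSeries(rr=rr, peak_times=peak_times)


def segment(
    data: RawSignal | TriaxialSignal | RRSeries,
    window_s: float = 60.0,
    duration: float | None = None,
    session_label: str | None = None,
) -> list[Segment]:
    """Cut a signal or RR series into non-overlapping fixed windows.

    The number of windows is ``floor(duration / window_s)``; a partial
    trailing window is discarded.  RR intervals are assigned to the
    window containing their terminal peak, so each interval is counted
    exactly once.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")

    if isinstance(data, RRSeries):
        if duration is None:
            duration = float(data.peak_times[-1])
        n_windows = int(np.floor(duration / window_s))
        out = []
        terminal = data.peak_times[1:]
        for w in range(n_windows):
            t0, t1 = w * window_s, (w + 1) * window_s
            mask = (terminal >= t0) & (terminal < t1)
            if not mask.any():
                payload = None
            else:
                lo = int(np.argmax(mask))
                hi = lo + int(mask.sum())
                payload = RRSeries(
                    rr=data.rr[lo:hi], peak_times=data.peak_times[lo : hi + 1]
                )
            out.append(Segment(w, t0, t1, payload, session_label))
        return out

    if isinstance(data, TriaxialSignal):
        n_win_samples = int(round(window_s * data.fs))
        n_windows = data.x.size // n_win_samples
        return [
            Segment(
                w,
                data.start_time + w * window_s,
                data.start_time + (w + 1) * window_s,
                TriaxialSignal(
                    x=data.x[w * n_win_samples : (w + 1) * n_win_samples],
                    y=data.y[w * n_win_samples : (w + 1) * n_win_samples],
                    z=data.z[w * n_win_samples : (w + 1) * n_win_samples],
                    fs=data.fs,
                    start_time=data.start_time + w * window_s,
                ),
                session_label,
            )
            for w in range(n_windows)
        ]

    n_win_samples = int(round(window_s * data.fs))
    n_windows = data.samples.size // n_win_samples
    return [
        Segment(
            w,
            data.start_time + w * window_s,
            data.start_time + (w + 1) * window_s,
            replace(
                data,
                samples=data.samples[w * n_win_samples : (w + 1) * n_win_samples],
                start_time=data.start_time + w * window_s,
            ),
            session_label,
        )
        for w in range(n_windows)
    ]
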