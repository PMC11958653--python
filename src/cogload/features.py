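"""Per-window feature extraction.

Three feature families are computed on each 60-s window:

* 19 heart-rate-variability features from the RR series — time-domain
  (RMSSD, MEAN, MEDIAN, SDRR, SDSD, SDRR_RMSSD, HR, PNN25, PNN50),
  Poincaré geometry (SD1, SD2), distribution shape (KURT_RR, SKEW_RR),
  and frequency-domain band powers (VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz,
  HF 0.15-0.4 Hz, TP, LF_HF, HF_LF);
* 9 skin-conductance features from the CDA decomposition (areas under
  the phasic and full SC curves, SCR peak count and mean rise/decay
  times, amplitude-histogram entropy, component standard deviations,
  phasic band power);
* 24 accelerometer features: mean, median, SD, min, max and range for
  each of X, Y, Z and the per-sample resultant.

Note on the spectral features: a 60-s window cannot resolve the VLF
band (lowest resolvable frequency ~0.017 Hz); VLF is computed anyway
for completeness of the feature list but should be treated as
unreliable at this window length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram
from scipy.stats import kurtosis, skew

from . import eda, preprocess
from .preprocess import InsufficientBeatsError, RawSignal, RRSeries, TriaxialSignal

HRV_FEATURE_NAMES = [
    "RMSSD", "MEAN", "MEDIAN", "SDRR", "SDSD", "SDRR_RMSSD", "HR",
    "PNN25", "PNN50", "SD1", "SD2", "KURT_RR", "SKEW_RR",
    "VLF", "LF", "HF", "TP", "LF_HF", "HF_LF",
]
GSR_FEATURE_NAMES = [
    "AreaSCR", "AreaGSR", "No_Peakes", "AvgRiseTime", "AvgDecayTime",
    "Entropy", "STDGSRdata", "STDSCRdata", "BandPower",
]
ACCEL_AXES = ["X", "Y", "Z", "R"]
ACCEL_STATS = ["mean", "median", "std", "min", "max", "range"]
ACCEL_FEATURE_NAMES = [f"{s}{a}" for a in ACCEL_AXES for s in ACCEL_STATS]


@dataclass(frozen=True)
class SpectralBands:
    """HRV frequency-band edges in Hz."""

    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(e <= 0 for e in edges) or sorted(edges) != edges:
            raise ValueError("bands must be ordered, non-overlapping, positive")


DEFAULT_BANDS = SpectralBands()


def hrv_time_features(rr: RRSeries, printed_rmssd: bool = False) -> dict[str, float]:
    """Time-domain and shape HRV features.

    RMSSD uses the standard estimator ``sqrt(sum(d_i^2) / (N-1))`` over
    the ``N-1`` successive differences of ``N`` intervals; set
    ``printed_rmssd=True`` for the variant with the radical restricted
    to the numerator, ``sqrt(sum(d_i^2)) / (N-1)``.
    """
    x = rr.rr
    if x.size < 2:
        raise InsufficientBeatsError("need at least 2 RR intervals")
    d = np.diff(x)
    ssd = float(np.sum(d**2))
    if printed_rmssd:
        rmssd = np.sqrt(ssd) / d.size
    else:
        rmssd = np.sqrt(ssd / d.size)
    mean = float(np.mean(x))
    sdrr = float(np.std(x, ddof=1))
    sdsd = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
    out = {
        "RMSSD": float(rmssd),
        "MEAN": mean,
        "MEDIAN": float(np.median(x)),
        "SDRR": sdrr,
        "SDSD": sdsd,
        "SDRR_RMSSD": sdrr / rmssd if rmssd > 0 else np.nan,
        "HR": 60000.0 / mean,
        "PNN25": 100.0 * np.mean(np.abs(d) > 25.0),
        "PNN50": 100.0 * np.mean(np.abs(d) > 50.0),
        "KURT_RR": float(kurtosis(x, fisher=False, bias=False)) if x.size >= 4 else np.nan,
        "SKEW_RR": float(skew(x, bias=False)) if x.size >= 3 else np.nan,
    }
    return out


def hrv_poincare(rr: RRSeries) -> tuple[float, float]:
    """Poincaré descriptors: SD1 (short-term) and SD2 (long-term).

    SD1^2 = SDSD^2 / 2 and SD2^2 = 2*SDRR^2 - SDSD^2 / 2 (floored at 0).
    """
    x = rr.rr
    if x.size < 3:
        raise InsufficientBeatsError("need at least 3 RR intervals for Poincare")
    sdsd = np.std(np.diff(x), ddof=1)
    sdrr = np.std(x, ddof=1)
    sd1 = np.sqrt(0.5) * sdsd
    sd2 = np.sqrt(max(2.0 * sdrr**2 - 0.5 * sdsd**2, 0.0))
    return float(sd1), float(sd2)


def hrv_spectral(
    rr: RRSeries,
    bands: SpectralBands = DEFAULT_BANDS,
    fs_interp: float = 4.0,
) -> dict[str, float]:
    """Frequency-domain HRV features (band powers in ms²).

    The irregularly sampled RR series is cubic-spline interpolated to a
    uniform ``fs_interp`` grid, linearly detrended, and its Hann-taper
    periodogram integrated over the band edges.  Total power (TP) spans
    0.003-0.4 Hz.  Ratios are NaN when the denominator band is empty.
    """
    if rr.n < 8:
        raise InsufficientBeatsError("need at least 8 RR intervals for spectra")
    t = rr.peak_times[1:]
    span = t[-1] - t[0]
    if span < 30.0:
        raise InsufficientBeatsError("RR span must cover at least 30 s")
    spline = CubicSpline(t, rr.rr)
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
    series = spline(grid)
    series = series - np.polyval(np.polyfit(grid, series, 1), grid)
    freqs, psd = periodogram(series, fs=fs_interp, window="hann", detrend=False)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*bands.vlf)
    lf = band_power(*bands.lf)
    hf = band_power(*bands.hf)
    tp = band_power(bands.vlf[0], bands.hf[1])
    lf_hf = lf / hf if hf > 0 else np.nan
    hf_lf = hf / lf if lf > 0 else np.nan
    return {"VLF": vlf, "LF": lf, "HF": hf, "TP": tp, "LF_HF": lf_hf, "HF_LF": hf_lf}


def hrv_features(rr: RRSeries, bands: SpectralBands = DEFAULT_BANDS, **kw) -> dict[str, float]:
    """All 19 HRV features for one window."""
    out = hrv_time_features(rr, **kw)
    sd1, sd2 = hrv_poincare(rr)
    out["SD1"], out["SD2"] = sd1, sd2
    out.update(hrv_spectral(rr, bands))
    return {name: out[name] for name in HRV_FEATURE_NAMES}


def gsr_features(
    decomp: eda.SCDecomposition,
    events: list[eda.SCREvent],
    entropy_bins: int = 16,
) -> dict[str, float]:
    """The 9 skin-conductance features for one window.

    Entropy is the Shannon entropy (bits) of a 16-bin histogram of the
    SC amplitudes; BandPower integrates the phasic periodogram over
    (0, 1] Hz.  With no detected events the rise/decay means are 0 by
    the sentinel convention.
    """
    if decomp.sc.size == 0:
        raise ValueError("empty segment")
    dt = 1.0 / decomp.fs
    counts, _ = np.histogram(decomp.sc, bins=entropy_bins)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    freqs, psd = periodogram(decomp.sc_phasic, fs=decomp.fs, detrend=False)
    mask = (freqs > 0) & (freqs <= 1.0)
    band_power = float(trapezoid(psd[mask], freqs[mask])) if mask.sum() >= 2 else 0.0
    return {
        "AreaSCR": float(trapezoid(decomp.sc_phasic, dx=dt)),
        "AreaGSR": float(trapezoid(decomp.sc, dx=dt)),
        "No_Peakes": float(len(events)),
        "AvgRiseTime": float(np.mean([e.rise_time for e in events])) if events else 0.0,
        "AvgDecayTime": float(np.mean([e.decay_time for e in events])) if events else 0.0,
        "Entropy": entropy,
        "STDGSRdata": float(np.std(decomp.sc, ddof=1)),
        "STDSCRdata": float(np.std(decomp.sc_phasic, ddof=1)),
        "BandPower": band_power,
    }


def accel_features(sig: TriaxialSignal) -> dict[str, float]:
    """Six summary statistics per axis (X, Y, Z, resultant): 24 values."""
    if sig.x.size == 0:
        raise ValueError("empty accelerometer segment")
    axes = {"X": sig.x, "Y": sig.y, "Z": sig.z, "R": sig.resultant}
    out: dict[str, float] = {}
    for name, arr in axes.items():
        out[f"mean{name}"] = float(np.mean(arr))
        out[f"median{name}"] = float(np.median(arr))
        out[f"std{name}"] = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out[f"min{name}"] = float(np.min(arr))
        out[f"max{name}"] = float(np.max(arr))
        out[f"range{name}"] = out[f"max{name}"] - out[f"min{name}"]
    return {name: out[name] for name in ACCEL_FEATURE_NAMES}


def extract_session_features(
    ppg: RawSignal,
    gsr: RawSignal,
    accel: TriaxialSignal | None = None,
    window_s: float = 60.0,
    bands: SpectralBands = DEFAULT_BANDS,
    tau: tuple[float, float] = eda.DEFAULT_TAU,
    min_scr_amplitude: float = 0.01,
    cda_fs_work: float = 25.0,
) -> pd.DataFrame:
    """Run preprocessing + decomposition + feature extraction on one session.

    Returns one row per valid 60-s window; windows with too few beats
    for the HRV set are dropped.
    """
    cleaned = preprocess.detrend_savgol(preprocess.remove_dc(ppg))
    try:
        peaks = preprocess.detect_peaks(cleaned)
        rr = preprocess.peaks_to_rr(peaks)
    except InsufficientBeatsError:
        return pd.DataFrame()
    duration = min(ppg.duration, gsr.duration)
    rr_segments = preprocess.segment(rr, window_s, duration=duration)
    gsr_segments = preprocess.segment(gsr, window_s)
    accel_segments = (
        preprocess.segment(accel, window_s) if accel is not None else None
    )

    rows = []
    for w, rr_seg in enumerate(rr_segments):
        if w >= len(gsr_segments):
            break
        if rr_seg.payload is None:
            continue
        try:
            row = hrv_features(rr_seg.payload, bands)
        except InsufficientBeatsError:
            continue
        decomp = eda.cda_decompose(gsr_segments[w].payload, tau=tau, fs_work=cda_fs_work)
        events = eda.detect_scrs(decomp, min_amplitude=min_scr_amplitude)
        row.update(gsr_features(decomp, events))
        if accel_segments is not None and w < len(accel_segments):
            row.update(accel_features(accel_segments[w].payload))
        row["window_index"] = w
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(study, include_accel: bool = False, **kw) -> pd.DataFrame:
    """Assemble the labelled segment-level feature table for a whole study.

    One row per valid 60-s window, labelled with participant id and the
    session condition (baseline / visual / code).  Physiology-only
    tables have 28 feature columns (19 HRV + 9 GSR); with the
    accelerometer, 52.  Participants contributing no valid window are
    excluded with a warning.
    """
    frames = []
    for participant in study.participants:
        got_any = False
        for session in participant.sessions:
            if session.ppg is None or session.gsr is None:
                warnings.warn(
                    f"participant {participant.participant_id}: missing signal "
                    f"for session {session.label}; skipped"
                )
                continue
            df = extract_session_features(
                session.ppg,
                session.gsr,
                accel=session.accel if include_accel else None,
                **kw,
            )
            if df.empty:
                continue
            df["participant_id"] = participant.participant_id
            df["label"] = session.label
            frames.append(df)
            got_any = True
        if not got_any:
            warnings.warn(
                f"participant {participant.participant_id} has no valid segment; excluded"
            )
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, ignore_index=True)
    feature_cols = HRV_FEATURE_NAMES + GSR_FEATURE_NAMES + (
        ACCEL_FEATURE_NAMES if include_accel else []
    )
    meta = ["participant_id", "label", "window_index"]
    return table[meta + feature_cols]
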