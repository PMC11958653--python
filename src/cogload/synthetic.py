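"""Synthetic study generator with ground truth.

Emulates a two-session within-subject work-instruction experiment: a
3-minute seated baseline followed by two counterbalanced assembly
sessions (visual-based = low cognitive load, code-based = high load).
Four subgroups counterbalance session order and pattern allocation:

    Sub_G1.1  code (patterns 1,2)  then visual (3,4)
    Sub_G1.2  code (3,4)           then visual (1,2)
    Sub_G2.1  visual (1,2)         then code (3,4)
    Sub_G2.2  visual (3,4)         then code (1,2)

Each session runs at least 5 minutes and until every assigned pattern
has been assembled at least ``min_repetitions`` times, so the task
completion time (TCT) extends past the floor exactly when the
repetition minimum is unmet — the high-load condition, with slower
repetitions, routinely overruns while the low-load condition finishes
near the floor with more repetitions (NTR).

Generated per participant and session: a PPG pulse train with
inter-beat variability, low-frequency trend and DC offset; skin
conductance as a drifting tonic level plus sparse Bateman-kernel SCRs
with condition-dependent event rate; triaxial wrist acceleration with
one movement burst per repetition; NASA-TLX and short-DSSQ item
responses drawn from condition-dependent truncated distributions; and
per-repetition block placements with condition-dependent positional
noise plus a random rigid motion of the whole assembly.  The generating
parameters are retained as ground truth for recovery tests.

A single study seed deterministically spawns per-participant
substreams, so equal (config, seed) yields byte-identical studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eda import bateman_kernel
from .precision import MarkerPattern
from .preprocess import RawSignal, TriaxialSignal
from .questionnaires import (
    DSSQ_ITEMS_PER_STATE,
    DSSQ_STATES,
    DSSQResponse,
    TLX_SUBSCALES,
    TLXResponse,
)

CONDITIONS = ("baseline", "visual", "code")

SUBGROUPS = (
    ("Sub_G1.1", ("code", "visual"), {"code": (1, 2), "visual": (3, 4)}),
    ("Sub_G1.2", ("code", "visual"), {"code": (3, 4), "visual": (1, 2)}),
    ("Sub_G2.1", ("visual", "code"), {"visual": (1, 2), "code": (3, 4)}),
    ("Sub_G2.2", ("visual", "code"), {"visual": (3, 4), "code": (1, 2)}),
)

# Fixed 6-piece reference layouts (plane units ~ pixels), one per pattern.
_PATTERN_OFFSETS = {
    1: [(0, 0), (40, 0), (80, 0), (0, 40), (40, 40), (80, 40)],
    2: [(0, 0), (40, 0), (40, 40), (80, 40), (80, 80), (120, 80)],
    3: [(0, 0), (0, 40), (0, 80), (40, 80), (80, 80), (80, 40)],
    4: [(0, 0), (40, 0), (80, 0), (120, 0), (120, 40), (80, 40)],
}


def reference_patterns() -> dict[int, MarkerPattern]:
    """The four fixed 6-piece reference layouts."""
    return {
        pid: MarkerPattern(
            centers={f"piece{j}": (float(x), float(y)) for j, (x, y) in enumerate(offs)},
            pattern_id=pid,
        )
        for pid, offs in _PATTERN_OFFSETS.items()
    }


@dataclass(frozen=True)
class ConditionEffects:
    """Per-condition generating parameters.

    The questionnaire and performance parameters default to the
    descriptive statistics of the reference protocol (overall cognitive
    load 39.84 +- 13.74 under visual vs 57.24 +- 14.71 under code
    instructions; DSSQ state means/SDs per administration; mean NTR
    9.828 vs 6.379 and TCT 5.342 vs 8.363 min, reached through the
    per-repetition duration distributions; assembly placement noise
    lower under code).  Physiological rates are field-realistic choices
    for seated light assembly work: heart rate rising and variability
    falling with load, SCR rate rising with sympathetic arousal.
    """

    mean_rr_ms: dict = field(
        default_factory=lambda: {"baseline": 850.0, "visual": 800.0, "code": 760.0}
    )
    rr_jitter_ms: dict = field(
        default_factory=lambda: {"baseline": 45.0, "visual": 38.0, "code": 32.0}
    )
    rr_lf_amp_ms: dict = field(
        default_factory=lambda: {"baseline": 25.0, "visual": 20.0, "code": 15.0}
    )
    rr_hf_amp_ms: dict = field(
        default_factory=lambda: {"baseline": 20.0, "visual": 15.0, "code": 10.0}
    )
    scr_rate_per_min: dict = field(
        default_factory=lambda: {"baseline": 4.0, "visual": 8.0, "code": 12.0}
    )
    scr_amp_mean_us: float = 0.3
    scr_amp_sigma: float = 0.4
    tonic_level_us: dict = field(
        default_factory=lambda: {"baseline": 2.0, "visual": 2.5, "code": 3.0}
    )
    tonic_drift_us: float = 0.15
    rep_duration_mean_s: dict = field(
        default_factory=lambda: {"visual": 33.0, "code": 80.0}
    )
    rep_duration_cv: float = 0.25
    tlx_cl_mean: dict = field(
        default_factory=lambda: {"visual": 39.84, "code": 57.24}
    )
    tlx_subscale_offset: dict = field(
        default_factory=lambda: {
            "visual": {"mental": 6.0, "physical": -10.0, "temporal": -2.0,
                       "performance": 2.0, "effort": 6.0, "frustration": -2.0},
            "code": {"mental": 10.0, "physical": -14.0, "temporal": -6.0,
                     "performance": 4.0, "effort": 8.0, "frustration": -2.0},
        }
    )
    tlx_participant_sd: float = 12.0
    tlx_item_sd: float = 8.0
    dssq_mean: dict = field(
        default_factory=lambda: {
            "pre": {"engagement": 25.06, "distress": 9.00, "worry": 15.86},
            "post_visual": {"engagement": 27.43, "distress": 6.56, "worry": 8.60},
            "post_code": {"engagement": 26.83, "distress": 11.83, "worry": 9.23},
        }
    )
    dssq_sd: dict = field(
        default_factory=lambda: {
            "pre": {"engagement": 5.33, "distress": 5.52, "worry": 5.85},
            "post_visual": {"engagement": 5.21, "distress": 4.76, "worry": 4.86},
            "post_code": {"engagement": 4.75, "distress": 6.02, "worry": 6.88},
        }
    )
    dssq_participant_frac: float = 0.6  # share of SD carried by the person
    placement_sd: dict = field(
        default_factory=lambda: {"visual": 4.0, "code": 3.0}
    )
    accel_burst_amp_g: dict = field(
        default_factory=lambda: {"baseline": 0.0, "visual": 0.6, "code": 0.45}
    )
    accel_burst_duration_s: float = 1.5
    accel_noise_g: float = 0.02
    ppg_dc_offset: float = 2.0
    ppg_trend_amplitude: float = 0.5
    ppg_noise_sd: float = 0.05


@dataclass(frozen=True)
class StudyConfig:
    """Design parameters of one synthetic study."""

    n_participants: int = 30
    fs: float = 250.0
    session_length_s: float = 300.0
    baseline_length_s: float = 180.0
    min_repetitions: int = 3
    seed: int = 0
    effects: ConditionEffects = field(default_factory=ConditionEffects)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.session_length_s < 60:
            raise ValueError(
                f"session_length_s must be >= 60, got {self.session_length_s}"
            )
        if self.baseline_length_s < 60:
            raise ValueError(
                f"baseline_length_s must be >= 60, got {self.baseline_length_s}"
            )
        if self.min_repetitions < 1:
            raise ValueError(
                f"min_repetitions must be >= 1, got {self.min_repetitions}"
            )


@dataclass
class SimulatedGSR:
    """Skin-conductance signal with its generating components."""

    signal: RawSignal
    tonic: np.ndarray
    phasic: np.ndarray
    driver_events: list[tuple[float, float]]


@dataclass
class TrialRecord:
    trial_id: str
    pattern_id: int
    observed: MarkerPattern
    t_start: float


@dataclass
class SessionData:
    label: str  # baseline / visual / code
    order_index: int  # 0 = baseline recording, 1 = first task session, 2 = second
    patterns: tuple[int, ...]
    ppg: RawSignal | None
    gsr: RawSignal | None
    accel: TriaxialSignal | None
    rep_times: list[float]
    tct_s: float
    ntr: int
    trials: list[TrialRecord]
    tlx: TLXResponse | None
    dssq: DSSQResponse
    dssq_session: str  # pre / post_visual / post_code
    ground_truth: dict


@dataclass
class ParticipantData:
    participant_id: str
    subgroup: str
    sessions: list[SessionData]


@dataclass
class SyntheticStudy:
    config: StudyConfig
    participants: list[ParticipantData]
    reference_patterns: dict[int, MarkerPattern]

    def sessions(self, label: str | None = None):
        for p in self.participants:
            for s in p.sessions:
                if label is None or s.label == label:
                    yield p, s


def simulate_ppg(
    beat_times: np.ndarray,
    fs: float,
    dc_offset: float = 0.0,
    trend_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
) -> RawSignal:
    """Pulse train with one asymmetric pulse per beat time.

    Additive components: DC offset, a slow trend (sum of up to three
    sinusoids below 0.1 Hz with random phases) and white noise.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    rng = rng or np.random.default_rng(0)
    if duration_s is None:
        duration_s = (beat_times[-1] if beat_times.size else 0.0) + 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    sigma_rise, sigma_fall = 0.06, 0.12
    half = int(round(0.6 * fs))
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half)
        if lo >= hi:
            continue
        tt = t[lo:hi] - tb
        sigma = np.where(tt < 0, sigma_rise, sigma_fall)
        samples[lo:hi] += np.exp(-0.5 * (tt / sigma) ** 2)
    if trend_amplitude > 0:
        freqs = rng.uniform(0.01, 0.09, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = trend_amplitude * np.array([0.5, 0.3, 0.2])
        for a, f, ph in zip(amps, freqs, phases):
            samples += a * np.sin(2 * np.pi * f * t + ph)
    if noise_sd > 0:
        samples += rng.normal(0, noise_sd, size=n)
    samples += dc_offset
    return RawSignal(samples=samples, fs=fs, channel="ppg")


def simulate_gsr(
    driver_events: list[tuple[float, float]],
    tonic_knots: list[tuple[float, float]],
    tau: tuple[float, float] = (1.0, 3.75),
    fs: float = 250.0,
    duration_s: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SimulatedGSR:
    """Tonic drift plus sparse SCRs convolved with the Bateman kernel.

    ``driver_events`` are (time s, amplitude µS) pairs; the kernel has
    unit peak, so each event raises the phasic component by its
    amplitude.  The generating tonic/phasic components are returned as
    ground truth.
    """
    tau1, tau2 = tau
    if not (tau2 > tau1 > 0):
        raise ValueError(f"require tau2 > tau1 > 0, got {tau}")
    for tt, a in driver_events:
        if a < 0:
            raise ValueError(f"negative SCR amplitude {a} at t={tt}")
    if duration_s is None:
        last_event = max((tt for tt, _ in driver_events), default=0.0)
        last_knot = max((tt for tt, _ in tonic_knots), default=0.0)
        duration_s = max(last_event + 10.0, last_knot, 1.0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    knots = sorted(tonic_knots)
    if not knots:
        raise ValueError("need at least one tonic knot")
    if len(knots) == 1:
        tonic = np.full(n, knots[0][1])
    else:
        from scipy.interpolate import PchipInterpolator

        kt = np.array([k[0] for k in knots])
        kv = np.array([k[1] for k in knots])
        tonic = PchipInterpolator(kt, kv, extrapolate=True)(t)
        tonic = np.clip(tonic, 0.0, None)

    train = np.zeros(n)
    for tt, a in driver_events:
        idx = int(round(tt * fs))
        if 0 <= idx < n:
            train[idx] += a
    kernel = bateman_kernel(tau, fs, min(20.0, duration_s))
    phasic = np.convolve(train, kernel)[:n]
    samples = tonic + phasic
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        samples = samples + rng.normal(0, noise_sd, size=n)
    sig = RawSignal(samples=samples, fs=fs, channel="gsr")
    return SimulatedGSR(
        signal=sig, tonic=tonic, phasic=phasic, driver_events=list(driver_events)
    )


def simulate_accel(
    repetition_times: list[float],
    fs: float,
    duration_s: float,
    burst_amp_g: float = 0.5,
    burst_duration_s: float = 1.5,
    burst_freq_hz: float = 4.0,
    noise_sd_g: float = 0.02,
    rng: np.random.Generator | None = None,
) -> TriaxialSignal:
    """Gravity baseline plus one oscillatory movement burst per repetition."""
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = rng.normal(0, noise_sd_g, n)
    y = rng.normal(0, noise_sd_g, n)
    z = 1.0 + rng.normal(0, noise_sd_g, n)
    n_burst = int(round(burst_duration_s * fs))
    window = np.hanning(max(n_burst, 3))
    for t0 in repetition_times:
        if t0 > duration_s:
            raise ValueError(f"repetition time {t0} outside session duration")
        c = int(round(t0 * fs))
        hi = min(n, c + window.size)
        if c >= hi:
            continue
        seg_t = t[c:hi]
        phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
        amp = burst_amp_g * rng.uniform(0.8, 1.2)
        w = window[: hi - c]
        x[c:hi] += amp * w * np.sin(2 * np.pi * burst_freq_hz * seg_t + phase_x)
        y[c:hi] += 0.7 * amp * w * np.sin(2 * np.pi * burst_freq_hz * seg_t + phase_y)
        z[c:hi] += 0.3 * amp * w * np.sin(2 * np.pi * burst_freq_hz * seg_t)
    return TriaxialSignal(x=x, y=y, z=z, fs=fs)


def simulate_trials(
    reference: MarkerPattern,
    n_trials: int,
    placement_sd: float,
    rng: np.random.Generator | None = None,
    translation_box: float = 50.0,
) -> list[MarkerPattern]:
    """Noisy placements of a reference layout under random rigid motion.

    Each trial applies isotropic Gaussian placement noise per piece,
    then a uniform rotation on [0, 2π) about the centroid and a uniform
    translation within ``±translation_box`` — the rigid motion carries
    no information and must leave the precision statistic unchanged.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if placement_sd < 0:
        raise ValueError("placement_sd must be >= 0")
    if len(reference.centers) < 2:
        raise ValueError("reference needs at least 2 pieces")
    rng = rng or np.random.default_rng(0)
    ids = reference.piece_ids
    ref = np.array([reference.centers[i] for i in ids], dtype=float)
    out = []
    for _ in range(n_trials):
        noisy = ref + rng.normal(0, placement_sd, ref.shape)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        centroid = noisy.mean(axis=0)
        moved = (noisy - centroid) @ rot.T + centroid
        moved = moved + rng.uniform(-translation_box, translation_box, size=2)
        out.append(
            MarkerPattern(
                centers={i: tuple(map(float, moved[j])) for j, i in enumerate(ids)},
                pattern_id=reference.pattern_id,
            )
        )
    return out


def _beat_times(
    rng: np.random.Generator,
    duration_s: float,
    mean_rr_ms: float,
    jitter_ms: float,
    lf_amp_ms: float,
    hf_amp_ms: float,
) -> np.ndarray:
    times = []
    t = float(rng.uniform(0, 0.5))
    while t < duration_s:
        times.append(t)
        rr = (
            mean_rr_ms
            + lf_amp_ms * np.sin(2 * np.pi * 0.1 * t)
            + hf_amp_ms * np.sin(2 * np.pi * 0.25 * t)
            + rng.normal(0, jitter_ms)
        )
        t += max(rr, 400.0) / 1000.0
    return np.array(times)


def _repetition_schedule(
    rng: np.random.Generator,
    patterns: tuple[int, ...],
    mean_s: float,
    cv: float,
    session_floor_s: float,
    min_repetitions: int,
) -> tuple[list[tuple[int, float, float]], float]:
    """Alternating repetitions until the time floor AND the minimum count."""
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean_s) - sigma2 / 2.0
    reps: list[tuple[int, float, float]] = []
    counts = {p: 0 for p in patterns}
    t = 0.0
    while t < session_floor_s or any(c < min_repetitions for c in counts.values()):
        if t < session_floor_s:
            pid = min(counts, key=lambda p: (counts[p], patterns.index(p)))
        else:
            pid = next(p for p in patterns if counts[p] < min_repetitions)
        dur = float(rng.lognormal(mu, math.sqrt(sigma2)))
        reps.append((pid, t, t + dur))
        counts[pid] += 1
        t += dur
    return reps, t


def _tlx_response(
    rng: np.random.Generator, eff: ConditionEffects, condition: str, p_effect: float
) -> TLXResponse:
    vals = {}
    for sub in TLX_SUBSCALES:
        m = eff.tlx_cl_mean[condition] + eff.tlx_subscale_offset[condition][sub]
        v = m + p_effect + rng.normal(0, eff.tlx_item_sd)
        vals[sub] = float(np.clip(v, 0, 100))
    return TLXResponse(**vals)


def _dssq_response(
    rng: np.random.Generator,
    eff: ConditionEffects,
    session: str,
    p_effects: dict[str, float],
) -> DSSQResponse:
    items = {}
    for state in DSSQ_STATES:
        sd_total = eff.dssq_sd[session][state]
        sd_noise = math.sqrt(
            max(sd_total**2 - (eff.dssq_participant_frac * sd_total) ** 2, 0.25)
        )
        score = eff.dssq_mean[session][state] + p_effects[state] * sd_total + rng.normal(
            0, sd_noise
        )
        score = int(np.clip(round(score), 0, DSSQ_ITEMS_PER_STATE * 4))
        base, rem = divmod(score, DSSQ_ITEMS_PER_STATE)
        items[state] = tuple(
            base + 1 if j < rem else base for j in range(DSSQ_ITEMS_PER_STATE)
        )
    return DSSQResponse(**items)


def generate_study(config: StudyConfig, include_signals: bool = True) -> SyntheticStudy:
    """Generate one complete counterbalanced synthetic study.

    With ``include_signals=False`` the physiological and accelerometer
    signals are omitted (questionnaires, repetition schedules and trial
    placements are still produced) — used for behavioural Monte-Carlo
    studies where signal synthesis would dominate the runtime.
    """
    eff = config.effects
    refs = reference_patterns()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    participants = []
    for i in range(config.n_participants):
        rng = np.random.default_rng(seeds[i])
        sub_name, order, pattern_map = SUBGROUPS[i % 4]
        pid = f"P{i:02d}"
        # stable person-level latent effects, shared across sessions
        tlx_effect = rng.normal(0, eff.tlx_participant_sd)
        dssq_effects = {s: rng.normal(0, eff.dssq_participant_frac) for s in DSSQ_STATES}
        sessions = []

        def make_session(
            label: str, order_index: int, duration: float,
            reps: list[tuple[int, float, float]], tct: float,
            dssq_session: str, with_tlx: bool,
        ) -> SessionData:
            rep_starts = [r[1] for r in reps]
            truth: dict = {
                "condition": label,
                "mean_rr_ms": eff.mean_rr_ms[label],
                "scr_rate_per_min": eff.scr_rate_per_min[label],
                "placement_sd": eff.placement_sd.get(label),
                "rep_times": rep_starts,
                "tct_s": tct,
                "ntr": len(reps),
            }
            ppg = gsr_sig = accel = None
            if include_signals:
                beats = _beat_times(
                    rng, duration, eff.mean_rr_ms[label], eff.rr_jitter_ms[label],
                    eff.rr_lf_amp_ms[label], eff.rr_hf_amp_ms[label],
                )
                ppg = simulate_ppg(
                    beats, config.fs, dc_offset=eff.ppg_dc_offset,
                    trend_amplitude=eff.ppg_trend_amplitude,
                    noise_sd=eff.ppg_noise_sd, rng=rng, duration_s=duration,
                )
                n_ev = rng.poisson(eff.scr_rate_per_min[label] * duration / 60.0)
                ev_t = np.sort(rng.uniform(0, max(duration - 5.0, 1.0), n_ev))
                amp_mu = math.log(eff.scr_amp_mean_us) - eff.scr_amp_sigma**2 / 2
                ev_a = rng.lognormal(amp_mu, eff.scr_amp_sigma, n_ev)
                events = list(zip(ev_t.tolist(), ev_a.tolist()))
                knot_t = np.arange(0, duration + 30.0, 30.0)
                walk = np.cumsum(rng.normal(0, eff.tonic_drift_us, knot_t.size))
                knots = list(
                    zip(knot_t.tolist(),
                        np.clip(eff.tonic_level_us[label] + walk, 0.3, None).tolist())
                )
                sim_gsr = simulate_gsr(
                    events, knots, fs=config.fs, duration_s=duration
                )
                gsr_sig = sim_gsr.signal
                truth["scr_events"] = events
                truth["tonic_knots"] = knots
                truth["beat_times"] = beats
                accel = simulate_accel(
                    rep_starts, config.fs, duration,
                    burst_amp_g=eff.accel_burst_amp_g[label],
                    burst_duration_s=eff.accel_burst_duration_s,
                    noise_sd_g=eff.accel_noise_g, rng=rng,
                )
            trials = []
            for j, (pat, t0, _) in enumerate(reps):
                observed = simulate_trials(
                    refs[pat], 1, eff.placement_sd[label], rng=rng
                )[0]
                trials.append(
                    TrialRecord(
                        trial_id=f"{pid}_{label}_{j}", pattern_id=pat,
                        observed=observed, t_start=t0,
                    )
                )
            tlx = _tlx_response(rng, eff, label, tlx_effect) if with_tlx else None
            dssq = _dssq_response(rng, eff, dssq_session, dssq_effects)
            return SessionData(
                label=label, order_index=order_index,
                patterns=tuple(pattern_map.get(label, ())),
                ppg=ppg, gsr=gsr_sig, accel=accel,
                rep_times=rep_starts, tct_s=tct, ntr=len(reps),
                trials=trials, tlx=tlx, dssq=dssq,
                dssq_session=dssq_session, ground_truth=truth,
            )

        sessions.append(
            make_session("baseline", 0, config.baseline_length_s, [],
                         config.baseline_length_s, "pre", with_tlx=False)
        )
        for k, label in enumerate(order, start=1):
            reps, tct = _repetition_schedule(
                rng, pattern_map[label], eff.rep_duration_mean_s[label],
                eff.rep_duration_cv, config.session_length_s, config.min_repetitions,
            )
            # recordings cover the whole session, rounded up to the sample grid
            duration = math.ceil(max(config.session_length_s, tct) * config.fs) / config.fs
            sessions.append(
                make_session(label, k, duration, reps, tct,
                             f"post_{label}", with_tlx=True)
            )
        participants.append(
            ParticipantData(participant_id=pid, subgroup=sub_name, sessions=sessions)
        )
    return SyntheticStudy(
        config=config, participants=participants, reference_patterns=refs
    )


# ---------------------------------------------------------------------------
# tidy accessors used by the analysis drivers


def tlx_frame(study: SyntheticStudy) -> pd.DataFrame:
    """Long table of NASA-TLX item responses per participant and session."""
    rows = []
    for p, s in study.sessions():
        if s.tlx is None:
            continue
        for sub in TLX_SUBSCALES:
            rows.append(
                {"participant_id": p.participant_id, "session": s.label,
                 "instrument": "tlx", "item": sub, "value": getattr(s.tlx, sub)}
            )
    return pd.DataFrame(rows)


def dssq_frame(study: SyntheticStudy) -> pd.DataFrame:
    """Long table of DSSQ item responses per participant and administration."""
    rows = []
    for p, s in study.sessions():
        for state in DSSQ_STATES:
            for j, v in enumerate(getattr(s.dssq, state)):
                rows.append(
                    {"participant_id": p.participant_id, "session": s.dssq_session,
                     "instrument": f"dssq_{state}", "item": j, "value": v}
                )
    return pd.DataFrame(rows)


def trials_frame(study: SyntheticStudy) -> pd.DataFrame:
    """Long table of marker-center placements per trial and piece."""
    rows = []
    for p, s in study.sessions():
        for tr in s.trials:
            for piece, (cx, cy) in tr.observed.centers.items():
                rows.append(
                    {"participant_id": p.participant_id, "session": s.label,
                     "trial_id": tr.trial_id, "pattern_id": tr.pattern_id,
                     "piece_id": piece, "cx": cx, "cy": cy}
                )
    return pd.DataFrame(rows)


def performance_frame(study: SyntheticStudy) -> pd.DataFrame:
    """NTR and TCT (minutes) per participant and task session."""
    rows = []
    for p, s in study.sessions():
        if s.label == "baseline":
            continue
        rows.append(
            {"participant_id": p.participant_id, "session": s.label,
             "ntr": s.ntr, "tct_min": s.tct_s / 60.0}
        )
    return pd.DataFrame(rows)
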