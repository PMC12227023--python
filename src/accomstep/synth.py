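"""Synthetic accommodative step-response cohorts.

Generates recordings with the statistical structure the analysis assumes: a
7-condition Maddox-cue design (blur B, disparity D, proximity P, each present
or diminished), 1.5 D demand steps between a 40 cm near target (2.5 D) and a
1 m far target (1.0 D), 5 s movements sampled at 50 Hz with interleaved
far-to-near (focus) and near-to-far (defocus) steps, randomized 0.5-2.0 s
onset delays, per-cue final-amplitude gains, measurement noise, and
blink/dropout gaps.

The per-movement response model is a single first-order exponential
(feedback-dominant): constant baseline before the onset delay, then
``baseline +/- A * (1 - exp(-(t - t0)/tau))``.  Its closed forms anchor the
pipeline tests: the final amplitude of the noiseless response approaches A
and the peak velocity is A/tau at onset.  An optional boxcar velocity pulse
models a distinct preprogrammed component; it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .recordings import RecordingFile, StimulusEvent, write_recording  # noqa: F401

__all__ = [
    "StimulusSpec",
    "CueCondition",
    "ResponseParams",
    "SimConfig",
    "CUE_CONDITIONS",
    "CUE_ORDER",
    "DEFAULT_GAINS",
    "dog_stimulus_profile",
    "demand_from_distance",
    "simulate_movement",
    "inject_artifacts",
    "simulate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# stimulus math
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Difference-of-Gaussians luminance profile of the low-acuity patch.

    ``sigma`` is the space constant (stimulus spatial units) and ``K`` the
    mean luminance (normalized units).
    """

    sigma: float
    K: float = 0.0

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not math.isfinite(self.K):
            raise ValueError("K must be finite")


def dog_stimulus_profile(x, spec: StimulusSpec):
    """Luminance of the difference-of-Gaussians patch at position(s) ``x``.

    ``3 exp(-x^2/sigma^2) - 2 exp(-x^2/(2.25 sigma^2)) + K``; equals 1 + K at
    the center and decays to K in the far surround.
    """
    x = np.asarray(x, dtype=float)
    s2 = spec.sigma**2
    out = 3.0 * np.exp(-(x**2) / s2) - 2.0 * np.exp(-(x**2) / (2.25 * s2)) + spec.K
    return out if out.ndim else float(out)


def demand_from_distance(d) -> float:
    """Accommodative demand (diopters) of a target at ``d`` meters: 1/d."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("viewing distance must be positive")
    out = 1.0 / d
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# design constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueCondition:
    """One Maddox-cue viewing condition of the 7-condition design."""

    code: str
    presentation: str  # "binocular" | "monocular"
    movements_per_session: int

    def __post_init__(self):
        if self.presentation not in ("binocular", "monocular"):
            raise ValueError(f"bad presentation {self.presentation!r}")
        if self.movements_per_session <= 0 or self.movements_per_session % 2:
            raise ValueError("movements_per_session must be a positive even count")


#: canonical cue order, from all cues present to isolated proximity
CUE_ORDER = ("BDP", "BD-p", "BP-d", "B-dp", "DP-b", "D-bp", "P-bd")

CUE_CONDITIONS: dict[str, CueCondition] = {
    "BDP": CueCondition("BDP", "binocular", 30),
    "BD-p": CueCondition("BD-p", "binocular", 30),
    "DP-b": CueCondition("DP-b", "binocular", 30),
    "D-bp": CueCondition("D-bp", "binocular", 30),
    "BP-d": CueCondition("BP-d", "monocular", 60),
    "B-dp": CueCondition("B-dp", "monocular", 60),
    "P-bd": CueCondition("P-bd", "monocular", 60),
}

#: expected final-amplitude gain (FA / demand step) per cue condition
DEFAULT_GAINS: dict[str, float] = {
    "BDP": 0.97,
    "BD-p": 0.97,
    "BP-d": 0.80,
    "B-dp": 0.71,
    "DP-b": 0.60,
    "D-bp": 0.55,
    "P-bd": 0.33,
}


# ---------------------------------------------------------------------------
# single-movement model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseParams:
    """Parameters of one simulated step response.

    amplitude
        Asymptotic response magnitude A in diopters (>= 0).
    tau
        First-order time constant in seconds; peak velocity is A/tau.
    t0
        Onset delay within the movement window, seconds (0.5-2.0 by design).
    baseline
        Absolute refraction before onset, diopters.
    noise_sd
        Per-sample Gaussian measurement noise SD, diopters.
    direction
        "focus" (response rises) or "defocus" (response falls).
    pulse_velocity, pulse_duration
        Optional preprogrammed boxcar velocity addition (D/s for s after
        onset); both zero by default.
    """

    amplitude: float
    tau: float
    t0: float
    baseline: float = 0.0
    noise_sd: float = 0.0
    direction: str = "focus"
    pulse_velocity: float = 0.0
    pulse_duration: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if not (0.5 <= self.t0 <= 2.0):
            raise ValueError(f"onset delay must lie in [0.5, 2.0] s, got {self.t0}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.direction not in ("focus", "defocus"):
            raise ValueError(f"bad direction {self.direction!r}")


def response_waveform(params: ResponseParams, t: np.ndarray) -> np.ndarray:
    """Noiseless response at times ``t`` (seconds from window start)."""
    sign = 1.0 if params.direction == "focus" else -1.0
    dt = t - params.t0
    step = np.where(dt >= 0, params.amplitude * (1.0 - np.exp(-np.maximum(dt, 0.0) / params.tau)), 0.0)
    if params.pulse_velocity and params.pulse_duration:
        step = step + params.pulse_velocity * np.clip(dt, 0.0, params.pulse_duration)
    return params.baseline + sign * step


def simulate_movement(params: ResponseParams, fs: float = 50.0, duration: float = 5.0,
                      seed: int | np.random.Generator | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one movement; returns ``(t, refraction)``.

    Deterministic for a fixed seed.  The noiseless component is the
    first-order exponential of :func:`response_waveform`; Gaussian noise with
    SD ``params.noise_sd`` is added per sample.
    """
    n = int(round(duration * fs))
    if n < 50:
        raise ValueError("duration * fs must be at least 50 samples")
    t = np.arange(n) / fs
    x = response_waveform(params, t)
    if params.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        x = x + rng.normal(0.0, params.noise_sd, size=n)
    return t, x


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(rec: RecordingFile, gap_rate: float, mean_gap_len: float = 8.0,
                     seed: int | np.random.Generator = 0,
                     p_both: float = 0.5) -> tuple[RecordingFile, float]:
    """Insert missing-sample runs (blinks / tracking dropout) into a recording.

    ``gap_rate`` is the expected number of gap onsets per second; gap lengths
    are geometric with the given mean (>= 1 sample).  Each gap hits both eyes
    with probability ``p_both`` (a blink), otherwise a single random eye.
    Returns the modified copy and the resulting combined missing fraction.
    Reproducible for a fixed seed; ``gap_rate=0`` returns an identical copy.
    """
    if gap_rate < 0:
        raise ValueError("gap_rate must be >= 0")
    out = rec.copy()
    n = out.n_samples
    if gap_rate == 0 or n == 0:
        return out, float(np.mean(out.both_missing)) if n else 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_start = gap_rate / rec.fs
    starts = np.flatnonzero(rng.random(n) < p_start)
    for s in starts:
        length = rng.geometric(1.0 / max(mean_gap_len, 1.0))
        u = rng.random()
        sl = slice(s, min(s + length, n))
        if u < p_both:
            out.od[sl] = np.nan
            out.os[sl] = np.nan
        elif u < p_both + (1 - p_both) / 2:
            out.od[sl] = np.nan
        else:
            out.os[sl] = np.nan
    return out, float(np.mean(out.both_missing))


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the experimental design: 50 Hz sampling, 5 s
    movements, a 1.5 D demand step (2.5 D at 40 cm vs 1.0 D at 1 m), 30
    movements per binocular cue and 60 per monocular cue with focus/defocus
    interleaved, onset delays uniform on [0.5, 2.0] s, and the per-cue gain
    table of :data:`DEFAULT_GAINS`.  Movement time constants are drawn
    uniform on [0.20, 0.35] s (a synthetic convention giving peak velocities
    of roughly 4-8 D/s at a 1.5 D amplitude).  Amplitude variability is
    multiplicative: one participant-level factor (SD ``participant_sd``)
    shared across cues and an independent per-movement factor (SD
    ``movement_sd``).
    """

    n_participants: int = 20
    fs: float = 50.0
    movement_duration: float = 5.0
    demand_near: float = 2.5
    demand_far: float = 1.0
    gains: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    defocus_gains: dict[str, float] | None = None
    participant_sd: float = 0.08
    movement_sd: float = 0.10
    noise_sd: float = 0.10
    tau_range: tuple[float, float] = (0.20, 0.35)
    delay_range: tuple[float, float] = (0.5, 2.0)
    gap_rate: float = 0.05
    mean_gap_len: float = 8.0
    baseline_far: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for cue, g in self.gains.items():
            if not (0.0 <= g <= 1.2):
                raise ValueError(f"gain for {cue} outside [0, 1.2]: {g}")
        if not set(self.gains) <= set(CUE_CONDITIONS):
            raise ValueError("gain table contains unknown cue codes")

    @property
    def demand_step(self) -> float:
        return self.demand_near - self.demand_far


def _participant_rngs(config: SimConfig):
    """Master seed -> one child SeedSequence per participant (documented split)."""
    ss = np.random.SeedSequence(config.seed)
    return ss.spawn(config.n_participants)


def simulate_cohort(config: SimConfig | None = None) -> list[RecordingFile]:
    """Generate one recording per participant x cue.

    Recordings are back-to-back movement windows (binocular cues: 30 x 5 s =
    150 s = 7500 samples at 50 Hz; monocular cues: 60 windows), events
    logged at window starts, focus/defocus interleaved starting with focus.
    The population mean movement final amplitude per cue is gain * demand
    step.  Byte-identical output for an identical config (including seed).
    """
    config = config or SimConfig()
    step = config.demand_step
    defocus_gains = config.defocus_gains or config.gains
    recs: list[RecordingFile] = []
    for p_idx, p_ss in enumerate(_participant_rngs(config)):
        pid = f"P{p_idx + 1:02d}"
        cue_seeds = p_ss.spawn(len(config.gains) + 1)
        p_factor = 1.0 + float(np.random.default_rng(cue_seeds[-1]).normal(0.0, config.participant_sd)) \
            if config.participant_sd > 0 else 1.0
        for c_idx, cue in enumerate(k for k in CUE_ORDER if k in config.gains):
            rng = np.random.default_rng(cue_seeds[c_idx])
            cond = CUE_CONDITIONS[cue]
            n_mov = cond.movements_per_session
            n_win = int(round(config.movement_duration * config.fs))
            sig = np.empty(n_mov * n_win)
            events = []
            level = config.baseline_far
            for m in range(n_mov):
                direction = "focus" if m % 2 == 0 else "defocus"
                gain = config.gains[cue] if direction == "focus" else defocus_gains[cue]
                m_factor = 1.0 + rng.normal(0.0, config.movement_sd) if config.movement_sd > 0 else 1.0
                amp = max(gain * step * p_factor * m_factor, 0.0)
                params = ResponseParams(
                    amplitude=amp,
                    tau=rng.uniform(*config.tau_range),
                    t0=rng.uniform(*config.delay_range),
                    baseline=level,
                    noise_sd=0.0,
                    direction=direction,
                )
                t, x = simulate_movement(params, config.fs, config.movement_duration, seed=None)
                sig[m * n_win:(m + 1) * n_win] = x
                level = x[-1]
                onset = m * config.movement_duration
                if direction == "focus":
                    d0, d1 = config.demand_far, config.demand_near
                else:
                    d0, d1 = config.demand_near, config.demand_far
                events.append(StimulusEvent(m, direction, onset, d0, d1))
            if config.noise_sd > 0:
                od = sig + rng.normal(0.0, config.noise_sd, size=sig.size)
                os_ = sig + rng.normal(0.0, config.noise_sd, size=sig.size)
            else:
                od, os_ = sig.copy(), sig.copy()
            rec = RecordingFile(
                participant_id=pid, cue=cue, fs=config.fs,
                time=np.arange(sig.size) / config.fs,
                od=od, os=os_, events=events,
            )
            if config.gap_rate > 0:
                rec, _ = inject_artifacts(rec, config.gap_rate, config.mean_gap_len, seed=rng)
            recs.append(rec)
    return recs


def fa_noise_variance(noise_sd: float, fs: float = 50.0, window_s: float = 5.0,
                      fa_window_s: float = 0.5) -> float:
    """Variance of the final-amplitude estimate's measurement-noise component.

    The pipeline computes FA as (mean of the last half-second of the
    zero-phase-filtered binocular-average signal) minus (its window-start
    sample).  For white per-eye noise of SD ``noise_sd`` this is a fixed
    linear functional of the noise; its variance is evaluated exactly from
    the filter's combined (forward-backward) impulse response.
    """
    if noise_sd == 0:
        return 0.0
    from scipy.signal import butter, filtfilt

    from .preprocess import FILTER_CUTOFF_HZ, FILTER_ORDER

    b, a = butter(FILTER_ORDER, FILTER_CUTOFF_HZ, fs=fs)
    n, c = 1024, 512
    imp = np.zeros(n)
    imp[c] = 1.0
    h = filtfilt(b, a, imp)  # h[c + k] is the response at offset k

    n_win = int(round(window_s * fs))
    n_fa = int(round(fa_window_s * fs))
    window_idx = np.arange(n_win - n_fa, n_win)
    # weight of noise sample t in the FA functional: mean_j h[j - t] - h[0 - t]
    t = np.arange(-c // 2, n_win + c // 2)
    w = -h[np.clip(c - t, 0, n - 1)] * ((c - t >= 0) & (c - t < n))
    for j in window_idx:
        k = c + j - t
        valid = (k >= 0) & (k < n)
        w = w + np.where(valid, h[np.clip(k, 0, n - 1)], 0.0) / n_fa
    per_sample_var = noise_sd**2 / 2.0  # binocular average of two eyes
    return float(per_sample_var * np.sum(w**2))


def expected_fa_se(config: SimConfig, cue: str, direction: str = "focus") -> float:
    """Theoretical SE of a cohort's per-cue mean |FA| estimate.

    Combines the participant-level amplitude variance, the per-movement
    amplitude variance averaged over the movements of one direction, and the
    FA measurement-noise variance of :func:`fa_noise_variance`.
    """
    gains = (config.defocus_gains or config.gains) if direction == "defocus" else config.gains
    A = gains[cue] * config.demand_step
    m = CUE_CONDITIONS[cue].movements_per_session // 2
    var_participant = (A * config.participant_sd) ** 2
    var_movement = (A * config.movement_sd) ** 2 + fa_noise_variance(
        config.noise_sd, config.fs, config.movement_duration)
    return float(np.sqrt((var_participant + var_movement / m) / config.n_participants))


def write_cohort(recs: list[RecordingFile], out_dir) -> list:
    """Write each recording as ``<participant>_<cue>.csv`` under ``out_dir``."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        safe_cue = rec.cue.replace("-", "m")
        paths.append(write_recording(rec, out_dir / f"{rec.participant_id}_{safe_cue}.csv"))
    return paths
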