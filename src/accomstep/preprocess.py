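"""Signal conditioning and movement segmentation.

Pipeline order is fixed: interpolate (qc) -> low-pass filter -> calibrate ->
baseline-align -> segment into per-movement windows -> differentiate.  The
low-pass is a fifth-order Butterworth with a 20 Hz cut-off applied zero-phase
(forward-backward) so it adds no group delay that would bias peak-velocity
timing; the zero-phase pass squares the magnitude response, so attenuation
at the cut-off is -6 dB rather than -3 dB.  Filtering is applied to the
whole recording before segmentation to keep edge transients out of the
5 s windows.  Velocity is the central difference of the filtered position
(one-sided at the window edges), which is exact for quadratics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .recordings import RecordingFile

__all__ = [
    "MovementTrace",
    "AlignedAverage",
    "lowpass_filter",
    "apply_calibration",
    "align_baseline",
    "compute_velocity",
    "segment_movements",
    "align_at_peak_velocity",
    "binocular_average",
]

FILTER_ORDER = 5
FILTER_CUTOFF_HZ = 20.0


@dataclass
class MovementTrace:
    """One aligned 5 s step-response segment.

    ``refraction`` is the baseline-aligned change in refraction (first sample
    0 by construction); ``velocity`` its central-difference derivative.
    ``interpolated_fraction`` records how much of the window was gap-filled.
    """

    participant_id: str
    cue: str
    direction: str  # "focus" | "defocus"
    t: np.ndarray
    refraction: np.ndarray
    velocity: np.ndarray
    fs: float
    demand_step: float = 1.5
    movement_index: int = 0
    interpolated_fraction: float = 0.0

    def __post_init__(self):
        if self.refraction.size != self.t.size or self.velocity.size != self.t.size:
            raise ValueError("t, refraction and velocity must have equal length")


def lowpass_filter(signal, fs: float = 50.0, order: int = FILTER_ORDER,
                   fc: float = FILTER_CUTOFF_HZ):
    """Zero-phase Butterworth low-pass; DC gain exactly 1.

    Requires a gap-free signal and ``fc < fs/2``.
    """
    signal = np.asarray(signal, dtype=float)
    if not (0 < fc < fs / 2):
        raise ValueError(f"cut-off must satisfy 0 < fc < fs/2, got fc={fc}, fs={fs}")
    if np.isnan(signal).any():
        raise ValueError("signal contains missing samples; interpolate gaps first")
    b, a = butter(order, fc, fs=fs)
    return filtfilt(b, a, signal)


def apply_calibration(signal, factor: float):
    """Scale refraction by the instrument calibration factor (> 0)."""
    if not (factor > 0):
        raise ValueError(f"calibration factor must be positive, got {factor}")
    return np.asarray(signal, dtype=float) * factor


def align_baseline(signal):
    """Subtract the first sample so the trace plots change in refraction."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    return signal - signal[0]


def compute_velocity(refraction, fs: float):
    """Central-difference velocity, one-sided at the edges (D/s)."""
    refraction = np.asarray(refraction, dtype=float)
    if refraction.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(refraction, 1.0 / fs)


def binocular_average(rec: RecordingFile) -> np.ndarray:
    """Mean of the two eyes' refraction (the consensual response analyzed)."""
    return (rec.od + rec.os) / 2.0


def segment_movements(rec: RecordingFile, window_s: float = 5.0,
                      calibration_factor: float | None = None,
                      ) -> tuple[list[MovementTrace], int]:
    """Filter, calibrate and cut a recording into per-movement traces.

    The recording must be gap-free (post interpolation).  One window of
    ``window_s`` seconds starts at each event onset; windows running past
    the end of file are dropped (their count is returned and warned about).
    Each window is baseline-aligned to its first sample and differentiated.
    """
    if not rec.events:
        raise ValueError("recording has no stimulus events")
    sig = binocular_average(rec)
    if np.isnan(sig).any():
        raise ValueError("recording contains missing samples; run QC interpolation first")
    factor = rec.calibration_factor if calibration_factor is None else calibration_factor
    sig = apply_calibration(lowpass_filter(sig, fs=rec.fs), factor)

    interp = None
    if rec.od_interpolated is not None and rec.os_interpolated is not None:
        interp = rec.od_interpolated | rec.os_interpolated

    n_win = int(round(window_s * rec.fs))
    t_rel = np.arange(n_win) / rec.fs
    starts = np.array([int(round((ev.onset_s - rec.time[0]) * rec.fs)) for ev in rec.events])
    in_range = (starts >= 0) & (starts + n_win <= sig.size)
    n_dropped = int((~in_range).sum())

    # all windows at once: rows are baseline-aligned segments, velocity is the
    # central difference along each row (one-sided at row edges)
    kept = starts[in_range]
    windows = sig[kept[:, None] + np.arange(n_win)]
    windows = windows - windows[:, :1]
    velocity = np.gradient(windows, 1.0 / rec.fs, axis=1) if kept.size else np.empty((0, n_win))
    interp_frac = (interp[kept[:, None] + np.arange(n_win)].mean(axis=1)
                   if interp is not None and kept.size else np.zeros(kept.size))

    traces: list[MovementTrace] = []
    for row, ev in enumerate(ev for ev, ok in zip(rec.events, in_range) if ok):
        traces.append(MovementTrace(
            participant_id=rec.participant_id,
            cue=rec.cue,
            direction=ev.direction,
            t=t_rel,
            refraction=windows[row],
            velocity=velocity[row],
            fs=rec.fs,
            demand_step=abs(ev.demand_end_d - ev.demand_start_d),
            movement_index=ev.movement_index,
            interpolated_fraction=float(interp_frac[row]),
        ))
    if n_dropped:
        warnings.warn(f"{rec.participant_id}/{rec.cue}: dropped {n_dropped} window(s) "
                      "extending past end of recording", stacklevel=2)
    return traces, n_dropped


@dataclass
class AlignedAverage:
    """Peak-velocity-aligned group average with SD bands.

    ``t`` is time relative to the common peak-velocity sample (0 at peak).
    """

    t: np.ndarray
    mean_position: np.ndarray
    sd_position: np.ndarray
    mean_velocity: np.ndarray
    sd_velocity: np.ndarray
    n_traces: int


def _peak_index(trace: MovementTrace) -> int:
    v = trace.velocity
    return int(np.argmax(v)) if trace.direction == "focus" else int(np.argmin(v))


def align_at_peak_velocity(traces: list[MovementTrace]) -> AlignedAverage:
    """Average traces after shifting each so its peak velocity coincides.

    Each trace is time-shifted so its peak-velocity sample maps to a common
    index; the pointwise mean and SD are computed over the region covered by
    every trace (sample SD, 0 for a single trace).
    """
    if not traces:
        raise ValueError("need at least one trace to average")
    fs = traces[0].fs
    if any(tr.fs != fs for tr in traces):
        raise ValueError("traces must share a sampling rate")
    peaks = [_peak_index(tr) for tr in traces]
    lo = -min(peaks)
    hi = min(tr.t.size - 1 - pk for tr, pk in zip(traces, peaks))
    if hi < lo:
        raise ValueError("traces have no common aligned window")
    offsets = np.arange(lo, hi + 1)
    pos = np.stack([tr.refraction[pk + lo: pk + hi + 1] for tr, pk in zip(traces, peaks)])
    vel = np.stack([tr.velocity[pk + lo: pk + hi + 1] for tr, pk in zip(traces, peaks)])
    ddof = 1 if len(traces) > 1 else 0
    return AlignedAverage(
        t=offsets / fs,
        mean_position=pos.mean(axis=0),
        sd_position=pos.std(axis=0, ddof=ddof),
        mean_velocity=vel.mean(axis=0),
        sd_velocity=vel.std(axis=0, ddof=ddof),
        n_traces=len(traces),
    )
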