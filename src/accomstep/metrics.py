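"""Per-movement response metrics and participant-level summaries.

Two metrics characterize each step response: peak velocity (PV), the maximum
observed rate of change, indexing the preprogrammed (open-loop) component;
and final amplitude (FA), the mean of the last half-second (25 samples at
50 Hz) of the baseline-aligned position, indexing the feedback (closed-loop)
component.  Gain is FA divided by the stimulated demand step; 1.0 is a
perfect response.

Movements are screened for non-response, noise and recording artifacts, and
an intra-participant 2-SD rule removes outlying movements before averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import MovementTrace

__all__ = [
    "FA_WINDOW_S",
    "ValidityThresholds",
    "MovementMetrics",
    "ParticipantSummary",
    "peak_velocity",
    "final_amplitude",
    "fa_window_samples",
    "movement_validity",
    "compute_movement_metrics",
    "remove_intra_outliers",
    "summarize_participant",
    "ca_c_ratio",
]

#: length of the final-amplitude window in seconds (25 samples at 50 Hz)
FA_WINDOW_S = 0.5

NON_RESPONSE = "NON_RESPONSE"
NOISE = "NOISE"
ARTIFACT = "ARTIFACT"


def fa_window_samples(fs: float) -> int:
    """Number of samples in the final-amplitude window at rate ``fs``."""
    return int(round(FA_WINDOW_S * fs))


def peak_velocity(trace: MovementTrace) -> float:
    """Signed peak velocity (D/s): max for focus, min for defocus.

    The sign convention makes increasing accommodation positive, so a focus
    response has positive PV and a defocus response negative; use ``abs``
    for the magnitude analyzed within each direction stratum.
    """
    v = trace.velocity
    if v.size == 0 or np.isnan(v).all():
        raise ValueError("velocity is empty or all-missing")
    return float(np.nanmax(v)) if trace.direction == "focus" else float(np.nanmin(v))


def final_amplitude(trace: MovementTrace) -> float:
    """Mean of the last half-second of the baseline-aligned position (D)."""
    n = fa_window_samples(trace.fs)
    if trace.refraction.size < n:
        raise ValueError(f"trace shorter than the {n}-sample final-amplitude window")
    return float(trace.refraction[-n:].mean())


@dataclass(frozen=True)
class ValidityThresholds:
    """Screening thresholds for individual movements (configurable defaults).

    ``min_response_d``: |FA| below this on a step is a non-response.
    ``max_velocity_dps``: any |velocity| sample above this is noise.
    ``max_interpolated_fraction``: more gap-filled samples than this is an
    artifact.
    """

    min_response_d: float = 0.2
    max_velocity_dps: float = 25.0
    max_interpolated_fraction: float = 0.10


@dataclass
class MovementMetrics:
    participant_id: str
    cue: str
    direction: str
    movement_index: int
    pv: float  # signed, D/s
    fa: float  # D
    invalid_reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.invalid_reason is None


def movement_validity(trace: MovementTrace, pv: float, fa: float,
                      thresholds: ValidityThresholds | None = None) -> str | None:
    """Return a reason code (NON_RESPONSE | NOISE | ARTIFACT) or None if valid."""
    thr = thresholds or ValidityThresholds()
    if abs(fa) < thr.min_response_d:
        return NON_RESPONSE
    if abs(pv) > thr.max_velocity_dps or np.nanmax(np.abs(trace.velocity)) > thr.max_velocity_dps:
        return NOISE
    if trace.interpolated_fraction > thr.max_interpolated_fraction:
        return ARTIFACT
    return None


def compute_movement_metrics(trace: MovementTrace,
                             thresholds: ValidityThresholds | None = None) -> MovementMetrics:
    pv = peak_velocity(trace)
    fa = final_amplitude(trace)
    return MovementMetrics(
        participant_id=trace.participant_id, cue=trace.cue,
        direction=trace.direction, movement_index=trace.movement_index,
        pv=pv, fa=fa,
        invalid_reason=movement_validity(trace, pv, fa, thresholds),
    )


def compute_movement_metrics_batch(traces: list[MovementTrace],
                                   thresholds: ValidityThresholds | None = None,
                                   ) -> list[MovementMetrics]:
    """Vectorized equivalent of :func:`compute_movement_metrics` over a batch.

    Requires all traces to share a window length; produces identical results
    to the per-trace path.
    """
    if not traces:
        return []
    thr = thresholds or ValidityThresholds()
    n = fa_window_samples(traces[0].fs)
    ref = np.stack([t.refraction for t in traces])
    vel = np.stack([t.velocity for t in traces])
    if ref.shape[1] < n:
        raise ValueError(f"traces shorter than the {n}-sample final-amplitude window")
    focus = np.array([t.direction == "focus" for t in traces])
    pv = np.where(focus, vel.max(axis=1), vel.min(axis=1))
    fa = ref[:, -n:].mean(axis=1)
    vmax = np.abs(vel).max(axis=1)
    interp = np.array([t.interpolated_fraction for t in traces])
    out = []
    for i, t in enumerate(traces):
        if abs(fa[i]) < thr.min_response_d:
            reason = NON_RESPONSE
        elif abs(pv[i]) > thr.max_velocity_dps or vmax[i] > thr.max_velocity_dps:
            reason = NOISE
        elif interp[i] > thr.max_interpolated_fraction:
            reason = ARTIFACT
        else:
            reason = None
        out.append(MovementMetrics(
            participant_id=t.participant_id, cue=t.cue, direction=t.direction,
            movement_index=t.movement_index, pv=float(pv[i]), fa=float(fa[i]),
            invalid_reason=reason,
        ))
    return out


def remove_intra_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass intra-participant 2-SD rule.

    A movement is removed iff its value lies 2 sample standard deviations
    (n-1 denominator) or more from the mean, both computed once over all
    input values.  With fewer than 3 values, or zero SD, nothing is removed.
    Returns (kept_indices, removed_indices) into the input order.
    """
    values = np.asarray(values, dtype=float)
    idx = np.arange(values.size)
    if values.size < 3:
        warnings.warn("fewer than 3 movements; 2-SD outlier rule not applied", stacklevel=2)
        return idx, np.array([], dtype=int)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return idx, np.array([], dtype=int)
    removed = np.abs(values - mean) >= 2.0 * sd
    return idx[~removed], idx[removed]


@dataclass
class ParticipantSummary:
    """Per participant x cue x direction averages over surviving movements."""

    participant_id: str
    cue: str
    direction: str
    n_movements: int          # valid movements entering the outlier rule
    n_used_pv: int
    n_used_fa: int
    mean_pv: float            # signed D/s
    sd_pv: float
    mean_fa: float            # D
    sd_fa: float
    demand_step: float
    single_movement: bool = False

    @property
    def gain(self) -> float:
        """|mean FA| / demand step; 1.0 is a perfect response."""
        return abs(self.mean_fa) / self.demand_step


def summarize_participant(metrics: list[MovementMetrics], demand_step: float = 1.5,
                          ) -> ParticipantSummary | None:
    """Average valid movements after applying the 2-SD rule per metric.

    The outlier rule is applied independently to PV and FA (a movement may
    be excluded from one metric's mean and kept in the other's).  Returns
    None when no valid movements survive; a single surviving movement yields
    SD 0 with ``single_movement`` flagged.
    """
    valid = [m for m in metrics if m.valid]
    if not valid:
        return None
    pv = np.array([m.pv for m in valid])
    fa = np.array([m.fa for m in valid])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        keep_pv, _ = remove_intra_outliers(pv)
        keep_fa, _ = remove_intra_outliers(fa)
    m0 = valid[0]
    return ParticipantSummary(
        participant_id=m0.participant_id, cue=m0.cue, direction=m0.direction,
        n_movements=len(valid), n_used_pv=keep_pv.size, n_used_fa=keep_fa.size,
        mean_pv=float(pv[keep_pv].mean()),
        sd_pv=float(pv[keep_pv].std(ddof=1)) if keep_pv.size > 1 else 0.0,
        mean_fa=float(fa[keep_fa].mean()),
        sd_fa=float(fa[keep_fa].std(ddof=1)) if keep_fa.size > 1 else 0.0,
        demand_step=demand_step,
        single_movement=(len(valid) == 1),
    )


def ca_c_ratio(accom_fa: float, vergence_fa: float) -> float:
    """Convergence-accommodation per unit convergence (D per prism diopter).

    The disparity-isolated response final amplitude (D) divided by the gaze
    final amplitude (prism diopters).
    """
    if vergence_fa == 0 or not math.isfinite(vergence_fa):
        raise ValueError("vergence final amplitude must be nonzero and finite")
    return accom_fa / vergence_fa
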