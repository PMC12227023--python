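"""File-level integrity rules for refraction recordings.

The repair/rejection sequence mirrors the acquisition software's conventions:
single-eye dropout is repaired by substituting the fellow eye's signal, then
files are rejected when (a) 25% or more of samples are missing, (b) fewer
than 750 valid samples (15 s at 50 Hz) remain where a 150 s session (7500
samples) was expected, or (c) any 225-sample (4.5 s) consecutive gap exists.
Gaps below the rejection threshold are linearly interpolated so the
downstream filter sees a gap-free signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recordings import RecordingFile

__all__ = [
    "QCThresholds",
    "QCReport",
    "substitute_eye",
    "missing_fraction",
    "longest_missing_run",
    "apply_rejection",
    "interpolate_short_gaps",
    "EXPECTED_SAMPLES",
]

#: nominal full-session length used for completeness reporting (150 s at 50 Hz)
EXPECTED_SAMPLES = 7500

# rejection reason codes
DATA_LOSS_25PCT = "DATA_LOSS_25PCT"
TOO_SHORT_750 = "TOO_SHORT_750"
GAP_225 = "GAP_225"


@dataclass(frozen=True)
class QCThresholds:
    """Rejection thresholds; inclusivity follows the stated rules literally:

    missing fraction >= ``max_missing_fraction`` rejects; valid-sample count
    < ``min_valid_samples`` rejects; longest gap >= ``max_gap_samples``
    rejects.
    """

    max_missing_fraction: float = 0.25
    min_valid_samples: int = 750
    max_gap_samples: int = 225


@dataclass
class QCReport:
    participant_id: str
    cue: str
    n_samples: int
    missing_fraction_od: float
    missing_fraction_os: float
    missing_fraction_combined: float
    longest_missing_run: int
    n_valid_samples: int
    completeness: float  # n_valid / EXPECTED_SAMPLES, reporting only
    reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.reasons

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["accepted"] = self.accepted
        return d


def substitute_eye(rec: RecordingFile) -> tuple[RecordingFile, dict]:
    """Repair single-eye dropout by copying the fellow eye's sample.

    Where exactly one eye is missing, the other eye's value is substituted;
    samples missing in both eyes stay missing.  Valid samples are never
    changed.  Returns the repaired copy and per-eye substitution counts.
    """
    out = rec.copy()
    od_fix = out.od_missing & ~out.os_missing
    os_fix = out.os_missing & ~out.od_missing
    out.od[od_fix] = out.os[od_fix]
    out.os[os_fix] = out.od[os_fix]
    return out, {"od": int(od_fix.sum()), "os": int(os_fix.sum())}


def missing_fraction(rec: RecordingFile, per_eye: bool = False):
    """Fraction of missing samples (combined both-eye mask by default)."""
    if rec.n_samples == 0:
        raise ValueError("zero-length recording")
    if per_eye:
        return float(np.mean(rec.od_missing)), float(np.mean(rec.os_missing))
    return float(np.mean(rec.both_missing))


def longest_missing_run(mask) -> int:
    """Length of the longest consecutive True run in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def apply_rejection(rec: RecordingFile, thresholds: QCThresholds | None = None,
                    substitute: bool = True) -> QCReport:
    """Evaluate the file rejection rules and return a :class:`QCReport`.

    By default the fellow-eye substitution is applied first, so the rules
    judge the post-substitution combined signal; ``substitute=False``
    evaluates the raw per-file masks instead.
    """
    thr = thresholds or QCThresholds()
    judged = substitute_eye(rec)[0] if substitute else rec
    n = judged.n_samples
    if n == 0:
        raise ValueError("zero-length recording")
    od_mf, os_mf = missing_fraction(judged, per_eye=True)
    mf = missing_fraction(judged)
    run = longest_missing_run(judged.both_missing)
    n_valid = n - int(judged.both_missing.sum())
    reasons = []
    if mf >= thr.max_missing_fraction:
        reasons.append(DATA_LOSS_25PCT)
    if n_valid < thr.min_valid_samples:
        reasons.append(TOO_SHORT_750)
    if run >= thr.max_gap_samples:
        reasons.append(GAP_225)
    return QCReport(
        participant_id=rec.participant_id, cue=rec.cue, n_samples=n,
        missing_fraction_od=od_mf, missing_fraction_os=os_mf,
        missing_fraction_combined=mf, longest_missing_run=run,
        n_valid_samples=n_valid, completeness=n_valid / EXPECTED_SAMPLES,
        reasons=sorted(reasons),
    )


def _fill_gaps(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation over NaN runs; edge gaps take the nearest value."""
    mask = np.isnan(x)
    if not mask.any():
        return x.copy(), mask
    if mask.all():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(x.size)
    filled = x.copy()
    filled[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return filled, mask


def interpolate_short_gaps(rec: RecordingFile, max_gap: int = 225) -> RecordingFile:
    """Fill sub-threshold gaps linearly so filtering sees a gap-free signal.

    Interior gaps shorter than ``max_gap`` are linearly interpolated between
    flanking valid samples; leading/trailing gaps take the nearest valid
    value.  The pre-fill masks are retained on ``od_interpolated`` /
    ``os_interpolated`` for provenance.  Recordings containing a gap of
    ``max_gap`` or longer should have been rejected beforehand.
    """
    if longest_missing_run(np.isnan(rec.od)) >= max_gap or \
            longest_missing_run(np.isnan(rec.os)) >= max_gap:
        raise ValueError(f"recording contains a gap of {max_gap}+ samples; reject it instead")
    out = rec.copy()
    out.od, out.od_interpolated = _fill_gaps(out.od)
    out.os, out.os_interpolated = _fill_gaps(out.os)
    return out
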