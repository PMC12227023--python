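"""End-to-end orchestration: simulate/load -> QC -> preprocess -> metrics -> stats.

`run_pipeline` executes the whole analysis on either a synthetic cohort or a
directory of recording CSVs, writes every intermediate table, and returns a
manifest whose per-stage counts account for every movement exactly once
(segmented = used + invalid + outlier-removed + dropped).  All randomness
flows from the config's master seed, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .groupstats import GroupInference, GroupSample, main_effect_workflow
from .metrics import (MovementMetrics, ValidityThresholds,
                      compute_movement_metrics_batch, summarize_participant)
from .preprocess import MovementTrace, align_at_peak_velocity, segment_movements
from .recordings import RecordingFile, read_recording
from .synth import SimConfig, simulate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_recordings",
    "group_average_report",
    "violin_summary",
    "metrics_table",
    "summaries_table",
]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Exactly one input source: a synthetic cohort spec (``sim``) or a
    directory of recording CSVs (``input_dir``).
    """

    sim: SimConfig | None = None
    input_dir: str | None = None
    out_dir: str | None = None
    qc_thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    validity: ValidityThresholds = field(default_factory=ValidityThresholds)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one input source (sim or input_dir) must be set")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# analysis core (shared by pipeline, tests and the acceptance script)
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    qc_reports: list
    traces: list[MovementTrace]
    movement_metrics: list[MovementMetrics]
    summaries: list
    counts: dict


def analyze_recordings(recs: list[RecordingFile],
                       qc_thresholds: qc_mod.QCThresholds | None = None,
                       validity: ValidityThresholds | None = None,
                       ) -> AnalysisResult:
    """QC, segment and score a set of recordings; returns every intermediate.

    Movement disposition is tracked so that
    ``segmented == used + invalid + outlier_removed`` per metric.
    """
    thr = qc_thresholds or qc_mod.QCThresholds()
    reports = []
    traces: list[MovementTrace] = []
    n_dropped = 0
    n_rejected = 0
    for rec in recs:
        repaired, _ = qc_mod.substitute_eye(rec)
        report = qc_mod.apply_rejection(repaired, thr, substitute=False)
        reports.append(report)
        if not report.accepted:
            n_rejected += 1
            continue
        filled = qc_mod.interpolate_short_gaps(repaired, thr.max_gap_samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr, dropped = segment_movements(filled)
        traces.extend(tr)
        n_dropped += dropped

    movement_metrics = compute_movement_metrics_batch(traces, validity)

    # group by participant x cue x direction, 2-SD rule inside the summary
    grouped: dict[tuple, list[MovementMetrics]] = {}
    demands: dict[tuple, float] = {}
    for m, t in zip(movement_metrics, traces):
        key = (m.participant_id, m.cue, m.direction)
        grouped.setdefault(key, []).append(m)
        demands.setdefault(key, t.demand_step)
    summaries = []
    n_outlier_pv = n_outlier_fa = 0
    for key in sorted(grouped):
        s = summarize_participant(grouped[key], demand_step=demands[key])
        if s is not None:
            summaries.append(s)
            n_outlier_pv += s.n_movements - s.n_used_pv
            n_outlier_fa += s.n_movements - s.n_used_fa
    counts = {
        "files_in": len(recs),
        "files_rejected": n_rejected,
        "movements_segmented": len(traces),
        "movements_dropped_at_eof": n_dropped,
        "movements_invalid": sum(not m.valid for m in movement_metrics),
        "movements_valid": sum(m.valid for m in movement_metrics),
        "intra_outliers_pv": n_outlier_pv,
        "intra_outliers_fa": n_outlier_fa,
    }
    return AnalysisResult(reports, traces, movement_metrics, summaries, counts)


def metrics_table(movement_metrics: list[MovementMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": m.participant_id, "cue": m.cue, "direction": m.direction,
        "movement_index": m.movement_index, "pv_dps": m.pv, "fa_d": m.fa,
        "valid": m.valid, "invalid_reason": m.invalid_reason or "",
    } for m in movement_metrics])


def summaries_table(summaries) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": s.participant_id, "cue": s.cue, "direction": s.direction,
        "n_movements": s.n_movements, "n_used_pv": s.n_used_pv, "n_used_fa": s.n_used_fa,
        "mean_pv_dps": s.mean_pv, "sd_pv_dps": s.sd_pv,
        "mean_fa_d": s.mean_fa, "sd_fa_d": s.sd_fa, "gain": s.gain,
    } for s in summaries])


def groups_from_summaries(summaries, metric: str, direction: str) -> list[GroupSample]:
    """Participant-level group samples per cue (PV as magnitudes)."""
    df = summaries_table(summaries)
    df = df[df.direction == direction]
    col = "mean_fa_d" if metric == "fa" else "mean_pv_dps"
    groups = []
    for cue, sub in df.groupby("cue", sort=True):
        vals = np.abs(sub[col].to_numpy())
        if vals.size >= 2:
            groups.append(GroupSample(str(cue), vals))
    return groups


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def group_average_report(traces_by_cue: dict[str, list[MovementTrace]]) -> pd.DataFrame:
    """Peak-velocity-aligned per-cue average curves (position and velocity).

    Emits a tidy frame of (cue, t, mean_pos, sd_pos, mean_vel, sd_vel);
    cues with zero traces are omitted with a warning.
    """
    frames = []
    for cue, traces in traces_by_cue.items():
        if not traces:
            warnings.warn(f"cue {cue}: no traces to average, omitted", stacklevel=2)
            continue
        avg = align_at_peak_velocity(traces)
        frames.append(pd.DataFrame({
            "cue": cue, "t_s": avg.t,
            "mean_pos_d": avg.mean_position, "sd_pos_d": avg.sd_position,
            "mean_vel_dps": avg.mean_velocity, "sd_vel_dps": avg.sd_velocity,
            "n_traces": avg.n_traces,
        }))
    if not frames:
        raise ValueError("no cue had any traces")
    return pd.concat(frames, ignore_index=True)


def violin_summary(values_by_cue: dict[str, np.ndarray]) -> pd.DataFrame:
    """Distribution summary per cue: median, mean, quartiles, whisker bounds.

    Whiskers are Q1 - 1.5 IQR and Q3 + 1.5 IQR under the linear-interpolation
    quartile convention; the outlier count applies the same fence.
    """
    rows = []
    for cue, vals in values_by_cue.items():
        vals = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows.append({
            "cue": cue, "n": vals.size, "median": med, "mean": vals.mean(),
            "q1": q1, "q3": q3, "iqr": iqr,
            "whisker_lo": lo, "whisker_hi": hi,
            "n_outliers": int(((vals < lo) | (vals > hi)).sum()),
        })
    return pd.DataFrame(rows).sort_values("cue").reset_index(drop=True)


def _config_hash(config: RunConfig) -> str:
    """Hash of the analytic configuration (output location excluded)."""
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    fields = asdict(config)
    fields.pop("out_dir", None)
    blob = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables + a manifest under ``out_dir``.

    Returns the manifest dict.  Identical config (including seed) yields
    byte-identical outputs.
    """
    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
        paths = sorted(in_dir.glob("*.csv"))
        paths = [p for p in paths if not p.name.endswith(".events.csv")]
        if not in_dir.is_dir() or not paths:
            raise FileNotFoundError(f"no recording CSVs found in {config.input_dir}")
        recs = [read_recording(p) for p in paths]
    else:
        sim = config.sim
        if sim.seed != config.seed:
            sim = SimConfig(**{**sim.__dict__, "seed": config.seed})
        recs = simulate_cohort(sim)

    result = analyze_recordings(recs, config.qc_thresholds, config.validity)

    inference: dict[str, GroupInference] = {}
    for metric in ("pv", "fa"):
        for direction in ("focus", "defocus"):
            groups = groups_from_summaries(result.summaries, metric, direction)
            if len(groups) >= 2:
                inference[f"{metric}_{direction}"] = main_effect_workflow(
                    groups, metric, direction, config.alpha)

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "counts": result.counts,
        "kw": {key: {"H": inf.kw.H, "df": inf.kw.df, "p": inf.kw.p}
               for key, inf in inference.items()},
        "n_pairwise": {key: len(inf.pairwise) for key, inf in inference.items()},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([r.to_dict() for r in result.qc_reports]).to_csv(out / "qc_report.csv", index=False)
        metrics_table(result.movement_metrics).to_csv(out / "movement_metrics.csv", index=False)
        summaries_table(result.summaries).to_csv(out / "participant_summaries.csv", index=False)
        by_cue: dict[str, list[MovementTrace]] = {}
        for t in result.traces:
            by_cue.setdefault(t.cue, []).append(t)
        group_average_report(by_cue).to_csv(out / "group_averages.csv", index=False)
        fa_by_cue = {}
        for s in result.summaries:
            fa_by_cue.setdefault(s.cue, []).append(abs(s.mean_fa))
        violin_summary({k: np.array(v) for k, v in fa_by_cue.items()}).to_csv(
            out / "violin_fa.csv", index=False)
        pairwise_rows = []
        for key, inf in inference.items():
            for pr in inf.pairwise:
                pairwise_rows.append({"contrast": key, "cue_i": pr.pair[0],
                                      "cue_j": pr.pair[1], "W": pr.W, "p": pr.p})
        pd.DataFrame(pairwise_rows).to_csv(out / "dscf_pairwise.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    manifest["inference"] = inference
    return manifest
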