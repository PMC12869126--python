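"""CSV / JSON readers and writers and visualization payload exporters.

The canonical on-disk form of a cohort is a wide CSV: one row per sample
with ``subject_id``, ``group`` and ``time`` columns plus one column per
channel.  Long or renamed layouts are accepted through a column-name
mapping.  Visualization exports are plain JSON payloads (3D surface
frames, chord diagrams, bubble charts) so that any front end can render
them; no plotting is done here.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import (
    ChannelKind,
    GroupLabel,
    RecordingSession,
    TimeSeriesChannel,
    validate_session,
)
from .coherence import CorrelationReport
from .metrics import oxygen_summary, session_indices, summarize_speed_bands
from .normalize import DegenerateInputError, NormalizationMethod, normalize

__all__ = [
    "SchemaError",
    "read_sessions_csv",
    "write_sessions_csv",
    "sessions_to_frame",
    "export_surface_json",
    "export_bubble_payload",
    "metrics_table",
    "group_metrics_table",
    "write_correlation_csv",
    "dump_json",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "group", "time")


class SchemaError(ValueError):
    """The CSV layout does not match the expected session schema."""


def dump_json(obj, path: str | Path) -> None:
    """Write JSON deterministically (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False) + "\n"
    )


def sessions_to_frame(sessions: list[RecordingSession]) -> pd.DataFrame:
    """Stack sessions into one wide DataFrame (one row per sample)."""
    frames = []
    for s in sessions:
        data = {
            "subject_id": s.subject_id,
            "group": s.group.value,
            "time": np.arange(s.n_samples) * s.sampling_interval,
        }
        for kind, chan in s.channels.items():
            data[kind.value] = chan.values
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def write_sessions_csv(sessions: list[RecordingSession], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    tolerance: float = 1e-6,
) -> list[RecordingSession]:
    """Read a wide cohort CSV back into validated sessions.

    ``schema`` maps file column names onto the canonical ones (meta columns
    and channel names); identity by default.  Sessions are validated in lax
    mode and violations logged with their location; structural problems
    (missing meta columns, unknown channel columns, unparseable numbers)
    raise instead.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns=schema)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    channel_names = {k.value for k in ChannelKind}
    data_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = sorted(set(data_cols) - channel_names)
    if unknown:
        raise SchemaError(f"unknown channel columns: {unknown}")
    if not data_cols:
        raise SchemaError("no channel columns present")

    numeric = {}
    for col in ("time", *data_cols):
        # astype(float) is correctly rounded (exact round-trip of written
        # values); on failure, scan per cell to report the location.
        try:
            numeric[col] = df[col].astype(float).to_numpy()
        except (TypeError, ValueError):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            row = int(bad.idxmax())
            raise SchemaError(
                f"unparseable numeric value {df[col][row]!r} "
                f"in column {col!r}, row {row + 2}"  # 1-based + header line
            ) from None
    df = df.assign(**numeric)

    sessions = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"subject {subject_id!r} carries multiple group labels")
        times = sub["time"].to_numpy(dtype=float)
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        channels = {
            ChannelKind(col): TimeSeriesChannel(
                kind=ChannelKind(col),
                sampling_interval=dt,
                values=sub[col].to_numpy(dtype=float),
            )
            for col in data_cols
        }
        session = RecordingSession(
            subject_id=str(subject_id),
            group=GroupLabel(groups[0]),
            channels=channels,
            tolerance=tolerance,
        )
        report = validate_session(session)
        for v in report.violations:
            logger.warning(
                "subject %s: %s on %s at index %s (%s)",
                subject_id, v.rule, v.channel, v.index, v.detail,
            )
        sessions.append(session)
    return sessions


def export_surface_json(
    sessions: list[RecordingSession],
    method: NormalizationMethod | str,
    out_dir: str | Path,
) -> list[Path]:
    """One 3D surface frame per group: time on X, channels on Y, values on Z.

    Subjects of a group are concatenated along the time axis and each
    channel is normalized by the chosen method over that concatenated
    timeline.  Channels degenerate under the method are dropped with a
    warning rather than failing the export.
    """
    method = NormalizationMethod(method)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for group in GroupLabel:
        members = [s for s in sessions if s.group == group]
        if not members:
            continue
        labels, rows = [], []
        for kind in ChannelKind:
            if not all(kind in s for s in members):
                continue
            pooled = np.concatenate([s.values(kind) for s in members])
            try:
                result = normalize(pooled, method)
            except DegenerateInputError as exc:
                logger.warning("group %s: dropping %s from surface (%s)",
                               group.value, kind.value, exc)
                continue
            labels.append(kind.value)
            rows.append([float(v) for v in result.transformed])
        frame = {
            "group": group.value,
            "normalization": method.value,
            "axis_time": list(range(len(rows[0]) if rows else 0)),
            "axis_variable": labels,
            "z_values": rows,
        }
        path = out_dir / f"surface_{group.value}.json"
        dump_json(frame, path)
        written.append(path)
    return written


def metrics_table(
    sessions: list[RecordingSession],
    s_constant: float = 0.15,
    s_unit: str = "mm",
) -> pd.DataFrame:
    """Per-subject metric table: one row per session, all summary metrics."""
    rows = []
    for s in sessions:
        speed = summarize_speed_bands(s)
        oxy = oxygen_summary(s)
        idx = session_indices(s, s_constant=s_constant, s_unit=s_unit)
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group.value,
            "mean_total_bp": speed.mean_total,
            "mean_low_bp": speed.mean_low,
            "mean_mid_bp": speed.mean_mid,
            "mean_high_bp": speed.mean_high,
            "rel_low": speed.rel_low,
            "rel_mid": speed.rel_mid,
            "rel_high": speed.rel_high,
            "mean_crbc": oxy.mean_crbc,
            "mean_so2": oxy.mean_so2,
            "mean_hb_total": oxy.mean_hb_total,
            "mean_hb_oxy": oxy.mean_hb_oxy,
            "mean_hb_red": oxy.mean_hb_red,
            "rel_oxy": oxy.rel_oxy,
            "rel_red": oxy.rel_red,
            "oxy_red_ratio": oxy.oxy_red_ratio,
            "mbp": idx.mbp,
            "mvel": idx.mvel,
            "mfre": idx.mfre,
            "imr": idx.imr,
        })
    return pd.DataFrame(rows)


def group_metrics_table(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Descriptive group summaries: mean and standard error per metric."""
    value_cols = [c for c in per_subject.columns if c not in ("subject_id", "group")]
    grouped = per_subject.groupby("group", sort=False)[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return pd.concat([mean, sem], axis=1).reset_index()


def export_bubble_payload(
    metric_table: pd.DataFrame,
    size_range: tuple[float, float] = (10.0, 60.0),
) -> list[dict]:
    """Bubble-chart records from a long table of (group, metric, value).

    Bubble sizes are scaled linearly within each metric onto
    ``size_range``; when all values of a metric coincide every bubble gets
    the midpoint size.  Colors are left to the consumer, keyed by group.
    """
    required = {"group", "metric", "value"}
    if metric_table.empty:
        raise ValueError("empty metric table")
    if not required <= set(metric_table.columns):
        raise SchemaError(f"bubble table needs columns {sorted(required)}")
    lo, hi = size_range
    records = []
    for metric, sub in metric_table.groupby("metric", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        vmin, vmax = float(vals.min()), float(vals.max())
        if vmax > vmin:
            sizes = lo + (vals - vmin) / (vmax - vmin) * (hi - lo)
        else:
            sizes = np.full_like(vals, (lo + hi) / 2.0)
        for (_, row), size in zip(sub.iterrows(), sizes):
            records.append({
                "group": str(row["group"]),
                "metric": str(metric),
                "value": float(row["value"]),
                "size": float(size),
            })
    return records


def write_correlation_csv(report: CorrelationReport, r_path: str | Path, flags_path: str | Path) -> None:
    """Correlation matrix and relevance-flag matrix as CSV."""
    r_df = pd.DataFrame(report.r, index=report.channels, columns=report.channels)
    r_df.to_csv(r_path)
    flag_df = pd.DataFrame(
        report.relevant.astype(int), index=report.channels, columns=report.channels
    )
    flag_df.to_csv(flags_path)
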