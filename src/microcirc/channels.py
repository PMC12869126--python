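"""Core data types for synchronized microcirculatory recordings.

A recording session bundles the ten channels acquired simultaneously by a
combined laser-Doppler-flowmetry / diffuse-reflectance-spectroscopy probe:
red-blood-cell tissue fraction (C_RBC, %), oxygen saturation (SO2, %), the
three hemoglobin concentrations (total / oxygenized / reduced, µM),
speed-resolved blood perfusion in three red-cell-speed bands plus the band
total (%RBC·mm/s), and conventional laser-Doppler perfusion (PU).

All channels of a session share one implicit time grid: sample ``i`` of
every channel was acquired at ``i * sampling_interval`` seconds.  Physical
coupling between channels (hemoglobin conservation, SO2 consistency, band
additivity) is validated rather than assumed, because instrument glitches
break it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ChannelKind",
    "GroupLabel",
    "TimeSeriesChannel",
    "RecordingSession",
    "Violation",
    "ValidationReport",
    "ValidationError",
    "validate_session",
]

#: Absolute tolerance floor for conservation checks so that zero-valued
#: samples do not trip the relative criterion.
ABSOLUTE_TOLERANCE_FLOOR = 1e-9


class ChannelKind(str, Enum):
    """The ten channels of a synchronized microcirculatory recording."""

    CRBC = "CRBC"            # red blood cell tissue fraction, %
    SO2 = "SO2"              # oxygen saturation, %
    HB_TOTAL = "HB_TOTAL"    # total hemoglobin, µM
    HB_OXY = "HB_OXY"        # oxygenized hemoglobin, µM
    HB_RED = "HB_RED"        # reduced hemoglobin, µM
    BP_LOW = "BP_LOW"        # perfusion, red-cell speed < 1 mm/s, %RBC·mm/s
    BP_MID = "BP_MID"        # perfusion, 1-10 mm/s, %RBC·mm/s
    BP_HIGH = "BP_HIGH"      # perfusion, > 10 mm/s, %RBC·mm/s
    BP_TOTAL = "BP_TOTAL"    # total speed-resolved perfusion, %RBC·mm/s
    BP_CONV = "BP_CONV"      # conventional laser-Doppler perfusion, PU

    @property
    def units(self) -> str:
        return _UNITS[self]


_UNITS = {
    ChannelKind.CRBC: "%",
    ChannelKind.SO2: "%",
    ChannelKind.HB_TOTAL: "µM",
    ChannelKind.HB_OXY: "µM",
    ChannelKind.HB_RED: "µM",
    ChannelKind.BP_LOW: "%RBC·mm/s",
    ChannelKind.BP_MID: "%RBC·mm/s",
    ChannelKind.BP_HIGH: "%RBC·mm/s",
    ChannelKind.BP_TOTAL: "%RBC·mm/s",
    ChannelKind.BP_CONV: "PU",
}

#: Channels whose values are percentages and must lie in [0, 100].
PERCENT_CHANNELS = (ChannelKind.CRBC, ChannelKind.SO2)

#: The three speed bands summing to BP_TOTAL.
BAND_CHANNELS = (ChannelKind.BP_LOW, ChannelKind.BP_MID, ChannelKind.BP_HIGH)


class GroupLabel(str, Enum):
    """Experimental groups of the diabetes / incretin-therapy design."""

    CONTROL = "control"
    T2DM = "t2dm"
    INSULIN_1W = "insulin_1w"
    INSULIN_2W = "insulin_2w"
    LIRAGLUTIDE_1W = "liraglutide_1w"
    LIRAGLUTIDE_2W = "liraglutide_2w"


@dataclass(frozen=True)
class TimeSeriesChannel:
    """One channel's evenly sampled values.

    Parameters
    ----------
    kind
        Which physiological quantity the channel carries.
    sampling_interval
        Seconds between consecutive samples; must be positive.
    values
        Finite real samples, stored as a read-only float array.
    """

    kind: ChannelKind
    sampling_interval: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("channel values must be one-dimensional")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Total recording span in seconds."""
        return len(self) * self.sampling_interval


@dataclass(frozen=True)
class Violation:
    """One validation failure: which channel, which sample, which rule."""

    channel: str
    index: int | None
    rule: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class ValidationError(ValueError):
    """Raised in strict mode on the first invariant violation."""

    def __init__(self, violation: Violation):
        self.violation = violation
        super().__init__(
            f"{violation.rule} on {violation.channel}"
            + (f" at index {violation.index}" if violation.index is not None else "")
            + f": {violation.detail}"
        )


@dataclass(frozen=True)
class RecordingSession:
    """One subject's synchronized multichannel recording.

    ``tolerance`` is the relative tolerance used by the conservation checks
    (hemoglobin additivity, perfusion-band additivity, SO2 consistency); the
    generator produces exactly consistent channels so the default is tight,
    and noisy instrument data can loosen it.
    """

    subject_id: str
    group: GroupLabel
    channels: dict[ChannelKind, TimeSeriesChannel]
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("session must contain at least one channel")

    def __getitem__(self, kind: ChannelKind) -> TimeSeriesChannel:
        return self.channels[kind]

    def __contains__(self, kind: ChannelKind) -> bool:
        return kind in self.channels

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def sampling_interval(self) -> float:
        return next(iter(self.channels.values())).sampling_interval

    def values(self, kind: ChannelKind) -> np.ndarray:
        return self.channels[kind].values

    def with_channels(self, channels: dict[ChannelKind, TimeSeriesChannel]) -> "RecordingSession":
        return replace(self, channels=channels)


#: Channels that must be present for the session to be structurally complete.
MANDATORY_CHANNELS = tuple(ChannelKind)


def _conservation_mask(total: np.ndarray, parts_sum: np.ndarray, rel_tol: float) -> np.ndarray:
    """True where |total - parts_sum| exceeds rel_tol*|total| with an absolute floor."""
    bound = np.maximum(rel_tol * np.abs(total), ABSOLUTE_TOLERANCE_FLOOR)
    return np.abs(total - parts_sum) > bound


def validate_session(session: RecordingSession, strict: bool = False) -> ValidationReport:
    """Check a session against the channel invariants.

    Rules checked, in order:

    - ``missing_channel`` — every mandatory channel is present (structural).
    - ``synchrony`` — all channels share one length and sampling interval.
    - ``range`` — C_RBC and SO2 in [0, 100]; perfusion and hemoglobin >= 0;
      all values finite.
    - ``hb_conservation`` — HB_TOTAL = HB_OXY + HB_RED elementwise within
      the session tolerance.
    - ``bp_conservation`` — BP_TOTAL = BP_LOW + BP_MID + BP_HIGH likewise.
    - ``so2_consistency`` — SO2 = 100·HB_OXY/HB_TOTAL where HB_TOTAL > 0.

    In strict mode the first violation raises :class:`ValidationError`;
    otherwise the full report is returned.  The check is pure: it never
    mutates the session, and repeated calls return identical reports.
    """
    report = ValidationReport()

    def add(channel: str, index: int | None, rule: str, detail: str) -> None:
        v = Violation(channel=channel, index=index, rule=rule, detail=detail)
        if strict:
            raise ValidationError(v)
        report.violations.append(v)

    for kind in MANDATORY_CHANNELS:
        if kind not in session.channels:
            add(kind.value, None, "missing_channel", "mandatory channel absent")
    present = {k: c for k, c in session.channels.items()}

    lengths = {len(c) for c in present.values()}
    intervals = {c.sampling_interval for c in present.values()}
    if len(lengths) > 1:
        add("*", None, "synchrony", f"channel lengths differ: {sorted(lengths)}")
    if len(intervals) > 1:
        add("*", None, "synchrony", f"sampling intervals differ: {sorted(intervals)}")

    for kind, chan in present.items():
        vals = chan.values
        bad = np.flatnonzero(~np.isfinite(vals))
        for i in bad:
            add(kind.value, int(i), "range", "non-finite value")
        if kind in PERCENT_CHANNELS:
            out = np.flatnonzero((vals < 0) | (vals > 100))
            for i in out:
                add(kind.value, int(i), "range", f"value {vals[i]:g} outside [0, 100]")
        else:
            neg = np.flatnonzero(vals < 0)
            for i in neg:
                add(kind.value, int(i), "range", f"negative value {vals[i]:g}")

    if len(lengths) == 1:
        tol = session.tolerance
        if all(k in present for k in (ChannelKind.HB_TOTAL, ChannelKind.HB_OXY, ChannelKind.HB_RED)):
            total = present[ChannelKind.HB_TOTAL].values
            parts = present[ChannelKind.HB_OXY].values + present[ChannelKind.HB_RED].values
            for i in np.flatnonzero(_conservation_mask(total, parts, tol)):
                add(ChannelKind.HB_TOTAL.value, int(i), "hb_conservation",
                    f"total {total[i]:g} != oxy+red {parts[i]:g}")
        if all(k in present for k in (ChannelKind.BP_TOTAL, *BAND_CHANNELS)):
            total = present[ChannelKind.BP_TOTAL].values
            parts = sum(present[k].values for k in BAND_CHANNELS)
            for i in np.flatnonzero(_conservation_mask(total, parts, tol)):
                add(ChannelKind.BP_TOTAL.value, int(i), "bp_conservation",
                    f"total {total[i]:g} != band sum {parts[i]:g}")
        if all(k in present for k in (ChannelKind.SO2, ChannelKind.HB_OXY, ChannelKind.HB_TOTAL)):
            so2 = present[ChannelKind.SO2].values
            hb_total = present[ChannelKind.HB_TOTAL].values
            hb_oxy = present[ChannelKind.HB_OXY].values
            pos = hb_total > 0
            expected = np.zeros_like(so2)
            expected[pos] = 100.0 * hb_oxy[pos] / hb_total[pos]
            abs_tol = max(100.0 * tol, ABSOLUTE_TOLERANCE_FLOOR)
            mismatch = pos & (np.abs(so2 - expected) > abs_tol)
            for i in np.flatnonzero(mismatch):
                add(ChannelKind.SO2.value, int(i), "so2_consistency",
                    f"SO2 {so2[i]:g} != 100·oxy/total {expected[i]:g}")

    return report
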