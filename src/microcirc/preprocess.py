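"""Signal refinement: boxplot-fence winsorization and length uniformization.

Artifacts in optically acquired microcirculatory signals appear as isolated
samples of exceptional magnitude.  They are handled with the classic
boxplot rule: values outside ``[Q1 - 1.5·IQR, Q3 + 1.5·IQR]`` are adjusted
to the nearest fence (winsorized), never deleted, so the sample count and
the time grid are preserved.  Quartiles use linear interpolation between
order statistics (the "type 7" convention of numpy's default percentile);
the convention matters because the fences differ across conventions.

Fences are computed once from the raw values — a single automated pass, no
iterative re-fencing.

Channels recorded at different lengths are brought to a common length by
repeating every sample an integer number of times, the only scheme
consistent with a least-common-multiple target length.  The LCM can blow up
for coprime lengths, so a cap guards against pathological expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelKind, RecordingSession, TimeSeriesChannel

__all__ = [
    "FenceReport",
    "InsufficientDataError",
    "LengthBlowupError",
    "compute_fences",
    "winsorize_outliers",
    "uniformize_lengths",
    "preprocess_session",
]

FENCE_FACTOR = 1.5
MIN_FENCE_SAMPLES = 4
DEFAULT_LENGTH_CAP = 10**6


class InsufficientDataError(ValueError):
    """Fewer samples than the quartile computation needs."""


class LengthBlowupError(ValueError):
    """The least common multiple of channel lengths exceeds the cap."""


@dataclass(frozen=True)
class FenceReport:
    """Quartiles, fences, and which indices were adjusted."""

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    adjusted_indices: tuple[int, ...] = ()
    original_values_at_adjusted: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "lower_fence": self.lower_fence,
            "upper_fence": self.upper_fence,
            "adjusted_indices": list(self.adjusted_indices),
            "original_values_at_adjusted": list(self.original_values_at_adjusted),
        }


def compute_fences(values) -> FenceReport:
    """Quartiles by linear interpolation and the 1.5·IQR fences.

    Requires at least four samples; with fewer, the interpolated quartiles
    are dominated by single observations and fencing is meaningless.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < MIN_FENCE_SAMPLES:
        raise InsufficientDataError(
            f"need at least {MIN_FENCE_SAMPLES} samples, got {arr.size}"
        )
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear ("type 7") interpolation
    iqr = q3 - q1
    return FenceReport(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(q1 - FENCE_FACTOR * iqr),
        upper_fence=float(q3 + FENCE_FACTOR * iqr),
    )


def winsorize_outliers(values) -> tuple[np.ndarray, FenceReport]:
    """Adjust values strictly outside the fences to the nearer fence.

    The fences come from the original values in a single pass; the output
    is bit-identical to the input everywhere inside them.
    """
    arr = np.asarray(values, dtype=float)
    report = compute_fences(arr)
    outside = (arr < report.lower_fence) | (arr > report.upper_fence)
    adjusted = np.clip(arr, report.lower_fence, report.upper_fence)
    idx = np.flatnonzero(outside)
    report = FenceReport(
        q1=report.q1,
        q3=report.q3,
        iqr=report.iqr,
        lower_fence=report.lower_fence,
        upper_fence=report.upper_fence,
        adjusted_indices=tuple(int(i) for i in idx),
        original_values_at_adjusted=tuple(float(arr[i]) for i in idx),
    )
    return adjusted, report


def uniformize_lengths(
    channel_lengths: list[int], max_common_length: int = DEFAULT_LENGTH_CAP
) -> tuple[int, list[int]]:
    """Common target length (the LCM) and per-channel integer repeat factors.

    Raises :class:`LengthBlowupError` when the LCM exceeds the cap — with
    near-coprime lengths the LCM explodes and resampling onto a shared grid
    is the sane alternative.
    """
    if not channel_lengths:
        raise ValueError("channel_lengths must be non-empty")
    if any(n < 1 for n in channel_lengths):
        raise ValueError("all lengths must be >= 1")
    common = math.lcm(*channel_lengths)
    if common > max_common_length:
        raise LengthBlowupError(
            f"least common multiple {common} exceeds cap {max_common_length}; "
            "resample channels onto a shared grid instead"
        )
    return common, [common // n for n in channel_lengths]


def preprocess_session(
    session: RecordingSession, max_common_length: int = DEFAULT_LENGTH_CAP
) -> tuple[RecordingSession, dict[ChannelKind, FenceReport]]:
    """Winsorize each channel independently, then uniformize lengths.

    Fences are data-local: computed per channel per session, never pooled
    across subjects.  When channels differ in length, every sample of
    channel ``i`` is repeated ``LCM/len_i`` times in order, so all channels
    end at the LCM length.  Equal-length sessions pass through unrepeated.
    """
    reports: dict[ChannelKind, FenceReport] = {}
    winsorized: dict[ChannelKind, np.ndarray] = {}
    for kind, chan in session.channels.items():
        adjusted, report = winsorize_outliers(chan.values)
        winsorized[kind] = adjusted
        reports[kind] = report

    lengths = [len(v) for v in winsorized.values()]
    if len(set(lengths)) > 1:
        _, factors = uniformize_lengths(lengths, max_common_length)
        winsorized = {
            kind: np.repeat(vals, factor)
            for (kind, vals), factor in zip(winsorized.items(), factors)
        }

    new_channels = {
        kind: TimeSeriesChannel(
            kind=kind,
            sampling_interval=session.channels[kind].sampling_interval,
            values=vals,
        )
        for kind, vals in winsorized.items()
    }
    return session.with_channels(new_channels), reports
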