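"""Four dimensionless transforms and the cross-method comparison.

Microcirculatory channels span wildly different numeric ranges (red-cell
fraction of a few percent against conventional perfusion in hundreds of
PU), so joint visualization and comparison require a dimensionless scale.
Four standard transforms are provided:

- z-score: ``x' = (x - mean) / sd`` with population sd (divisor n),
- min-max: ``x' = (x - min) / (max - min)``, mapping onto [0, 1],
- L2: ``x' = x / ||x||`` with the Euclidean norm,
- median scaling: ``x' = x / median``.

``compare_methods`` applies all four per channel and summarizes the
transformed distributions as boxplot five-number summaries.  Min-max is
recommended whenever every channel admits it, because it is the only
method that lands every channel on one fixed bounded interval, making
heterogeneous units directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NormalizationMethod",
    "NormalizationResult",
    "BoxplotSummary",
    "MethodComparison",
    "DegenerateInputError",
    "normalize_zscore",
    "normalize_minmax",
    "normalize_l2",
    "normalize_median",
    "normalize",
    "compare_methods",
]


class NormalizationMethod(str, Enum):
    ZSCORE = "zscore"
    MINMAX = "minmax"
    L2 = "l2"
    MEDIAN = "median"


class DegenerateInputError(ValueError):
    """The input admits no well-defined transform (zero spread, norm, or median)."""


@dataclass(frozen=True)
class NormalizationResult:
    method: NormalizationMethod
    transformed: np.ndarray
    parameters: dict[str, float]


def _as_array(values, min_len: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {arr.size}")
    return arr


def normalize_zscore(values) -> NormalizationResult:
    """Center on the mean and scale by the population standard deviation."""
    arr = _as_array(values, 2)
    mean = float(np.mean(arr))
    sd = float(np.std(arr))  # population sd, divisor n
    if sd == 0.0:
        raise DegenerateInputError("constant input has zero standard deviation")
    return NormalizationResult(
        method=NormalizationMethod.ZSCORE,
        transformed=(arr - mean) / sd,
        parameters={"mean": mean, "sd": sd},
    )


def normalize_minmax(values) -> NormalizationResult:
    """Map the range onto [0, 1]; extremes land exactly on the endpoints."""
    arr = _as_array(values, 2)
    lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi == lo:
        raise DegenerateInputError("constant input has zero range")
    return NormalizationResult(
        method=NormalizationMethod.MINMAX,
        transformed=(arr - lo) / (hi - lo),
        parameters={"min": lo, "max": hi},
    )


def normalize_l2(values) -> NormalizationResult:
    """Scale by the Euclidean norm so the output vector has unit length."""
    arr = _as_array(values, 1)
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        raise DegenerateInputError("all-zero vector has no direction")
    return NormalizationResult(
        method=NormalizationMethod.L2,
        transformed=arr / norm,
        parameters={"norm": norm},
    )


def normalize_median(values) -> NormalizationResult:
    """Divide by the median (midpoint of central order statistics for even n)."""
    arr = _as_array(values, 1)
    med = float(np.median(arr))
    if med == 0.0:
        raise DegenerateInputError("zero median")
    return NormalizationResult(
        method=NormalizationMethod.MEDIAN,
        transformed=arr / med,
        parameters={"median": med},
    )


_DISPATCH = {
    NormalizationMethod.ZSCORE: normalize_zscore,
    NormalizationMethod.MINMAX: normalize_minmax,
    NormalizationMethod.L2: normalize_l2,
    NormalizationMethod.MEDIAN: normalize_median,
}


def normalize(values, method: NormalizationMethod | str) -> NormalizationResult:
    """Apply the named transform."""
    return _DISPATCH[NormalizationMethod(method)](values)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary of one transformed channel."""

    q1: float
    median: float
    q3: float
    whisker_min: float
    whisker_max: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "BoxplotSummary":
        q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
        return cls(
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            whisker_min=float(np.min(values)),
            whisker_max=float(np.max(values)),
        )


@dataclass(frozen=True)
class MethodComparison:
    """Per-method, per-channel distribution summaries of transformed data.

    ``summaries[method][channel]`` is ``None`` where the channel was
    degenerate under that method (e.g. a constant channel under z-score).
    """

    summaries: dict[NormalizationMethod, dict[str, BoxplotSummary | None]]
    recommended_method: NormalizationMethod


def compare_methods(channels: Mapping[str, Sequence[float]]) -> MethodComparison:
    """Apply all four transforms to every channel and summarize.

    A channel degenerate under a method marks that method inapplicable for
    the channel without failing the comparison.  Min-max is recommended
    whenever it applies to all channels — it alone pins every channel to a
    common fixed interval regardless of original units.
    """
    if len(channels) < 2:
        raise ValueError("need at least 2 channels to compare")
    if any(len(v) < 4 for v in channels.values()):
        raise ValueError("every channel needs at least 4 samples")

    summaries: dict[NormalizationMethod, dict[str, BoxplotSummary | None]] = {}
    applicable: dict[NormalizationMethod, bool] = {}
    for method in NormalizationMethod:
        per_channel: dict[str, BoxplotSummary | None] = {}
        all_ok = True
        for name, values in channels.items():
            try:
                result = normalize(values, method)
            except DegenerateInputError:
                per_channel[name] = None
                all_ok = False
            else:
                per_channel[name] = BoxplotSummary.from_values(result.transformed)
        summaries[method] = per_channel
        applicable[method] = all_ok

    if applicable[NormalizationMethod.MINMAX]:
        recommended = NormalizationMethod.MINMAX
    else:
        # fall back to the first universally applicable method
        recommended = next(
            (m for m in NormalizationMethod if applicable[m]),
            NormalizationMethod.MEDIAN,
        )
    return MethodComparison(summaries=summaries, recommended_method=recommended)
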