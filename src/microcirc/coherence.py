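"""Hemodynamic-oxygen coherence: joint binning and correlation clustering.

Because perfusion and oxygen saturation are acquired synchronously, their
sample-by-sample pairing is meaningful.  Two views are computed:

- a joint heat matrix: both variables binned into 10 equal-width intervals
  and the 10x10 co-occurrence counts collected — the engine behind both
  heat maps and chord diagrams (arcs = marginals, chords = joint cells);
- relevance-thresholded correlation clustering: Pearson r between every
  channel pair on samples pooled within a group, with a pair flagged
  relevant when ``p < 0.05`` and ``|r| > 0.4``, and channels ordered by
  average-linkage hierarchical clustering on distance ``1 - |r|``.

No multiple-testing correction is applied to the pairwise p-values; the
relevance rule is a plain per-pair threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .channels import ChannelKind, GroupLabel, RecordingSession, TimeSeriesChannel

__all__ = [
    "CoherenceMatrix",
    "ChordPayload",
    "CorrelationReport",
    "make_bins",
    "joint_histogram",
    "chord_payload",
    "filter_chords",
    "correlate_channels",
    "RELEVANCE_R_THRESHOLD",
    "RELEVANCE_P_THRESHOLD",
]

RELEVANCE_R_THRESHOLD = 0.4
RELEVANCE_P_THRESHOLD = 0.05
DEFAULT_N_BINS = 10


def make_bins(values, k: int = DEFAULT_N_BINS, range_override: tuple[float, float] | None = None) -> np.ndarray:
    """``k + 1`` equal-width edges spanning the data (or an override range).

    Intervals are half-open ``[a, b)`` except the last, which is closed so
    the maximum is never lost.
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    if range_override is not None:
        lo, hi = map(float, range_override)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot bin an empty sequence")
        lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi <= lo:
        raise ValueError("degenerate range: max must exceed min (or pass range_override)")
    return np.linspace(lo, hi, k + 1)


@dataclass(frozen=True)
class CoherenceMatrix:
    """Joint counts of binned perfusion (rows) x binned SO2 (columns)."""

    bp_edges: np.ndarray
    so2_edges: np.ndarray
    counts: np.ndarray  # (k_bp, k_so2) integer counts
    group: GroupLabel | None
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "bp_edges": [float(e) for e in self.bp_edges],
            "so2_edges": [float(e) for e in self.so2_edges],
            "counts": self.counts.astype(int).tolist(),
            "group": self.group.value if self.group else None,
            "n_pairs": int(self.n_pairs),
        }


def joint_histogram(
    bp: TimeSeriesChannel | np.ndarray,
    so2: TimeSeriesChannel | np.ndarray,
    bp_edges: np.ndarray,
    so2_edges: np.ndarray,
    group: GroupLabel | None = None,
) -> CoherenceMatrix:
    """Count synchronous (perfusion, SO2) pairs per joint bin.

    The channels must be equally long (synchrony is what licenses the
    pairing).  Pairs outside the edge span are dropped; with edges from
    :func:`make_bins` on the same data the counts conserve the series
    length exactly.
    """
    bp_vals = bp.values if isinstance(bp, TimeSeriesChannel) else np.asarray(bp, dtype=float)
    so2_vals = so2.values if isinstance(so2, TimeSeriesChannel) else np.asarray(so2, dtype=float)
    if bp_vals.shape[0] != so2_vals.shape[0]:
        raise ValueError(
            f"length mismatch: bp has {bp_vals.shape[0]} samples, so2 has {so2_vals.shape[0]}"
        )
    counts, _, _ = np.histogram2d(bp_vals, so2_vals, bins=[bp_edges, so2_edges])
    counts = counts.astype(int)
    return CoherenceMatrix(
        bp_edges=np.asarray(bp_edges, dtype=float),
        so2_edges=np.asarray(so2_edges, dtype=float),
        counts=counts,
        group=group,
        n_pairs=int(counts.sum()),
    )


@dataclass(frozen=True)
class ChordPayload:
    """Renderer-agnostic chord-diagram payload.

    ``arcs`` carries one record per interval per side (20 for 10 bins);
    arc width is the marginal proportion, so each side sums to 1.  Chords
    carry the joint proportions (zero-count cells omitted) plus the raw
    counts for consumers that prefer absolute numbers.
    """

    arcs: list[dict]
    chords: list[dict]

    def to_dict(self) -> dict:
        return {"arcs": self.arcs, "chords": self.chords}


def _interval_label(side: str, edges: np.ndarray, i: int) -> str:
    close = "]" if i == len(edges) - 2 else ")"
    return f"{side}[{edges[i]:g},{edges[i + 1]:g}{close}"


def chord_payload(matrix: CoherenceMatrix) -> ChordPayload:
    """Marginal arcs and joint chords, as proportions of all pairs."""
    if matrix.n_pairs <= 0:
        raise ValueError("empty matrix: no pairs to normalize")
    n = matrix.n_pairs
    bp_marginal = matrix.counts.sum(axis=1)
    so2_marginal = matrix.counts.sum(axis=0)
    arcs = [
        {
            "side": "BP",
            "interval": i,
            "label": _interval_label("BP", matrix.bp_edges, i),
            "width": float(c) / n,
            "count": int(c),
        }
        for i, c in enumerate(bp_marginal)
    ] + [
        {
            "side": "SO2",
            "interval": j,
            "label": _interval_label("SO2", matrix.so2_edges, j),
            "width": float(c) / n,
            "count": int(c),
        }
        for j, c in enumerate(so2_marginal)
    ]
    chords = [
        {
            "bp_interval": int(i),
            "so2_interval": int(j),
            "width": float(matrix.counts[i, j]) / n,
            "count": int(matrix.counts[i, j]),
        }
        for i, j in zip(*np.nonzero(matrix.counts))
    ]
    return ChordPayload(arcs=arcs, chords=chords)


def filter_chords(payload: ChordPayload, side: str, interval: int) -> ChordPayload:
    """Sub-diagram restricted to one interval of one side.

    Conditioning a chord diagram on, say, one SO2 interval yields the
    interval-specific view (which perfusion levels sustain that
    saturation); widths are kept on the full-diagram scale so filtered
    views remain comparable.
    """
    key = {"BP": "bp_interval", "SO2": "so2_interval"}[side.upper()]
    chords = [c for c in payload.chords if c[key] == interval]
    kept_bp = {c["bp_interval"] for c in chords}
    kept_so2 = {c["so2_interval"] for c in chords}
    arcs = [
        a for a in payload.arcs
        if (a["side"] == "BP" and a["interval"] in kept_bp)
        or (a["side"] == "SO2" and a["interval"] in kept_so2)
    ]
    return ChordPayload(arcs=arcs, chords=chords)


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations with relevance flags and cluster order.

    ``r`` and ``p`` are symmetric matrices over ``channels``; entries are
    NaN where a channel is constant (correlation undefined).  ``relevant``
    is True where ``p < 0.05`` and ``|r| > 0.4``.  ``dendrogram_order`` is
    the leaf order of average-linkage clustering on ``1 - |r|``.
    """

    channels: list[str]
    r: np.ndarray
    p: np.ndarray
    relevant: np.ndarray
    dendrogram_order: list[int]
    n: int
    group: GroupLabel | None = None

    def pair(self, a: ChannelKind | str, b: ChannelKind | str) -> tuple[float, float, bool]:
        names = [str(getattr(c, "value", c)) for c in (a, b)]
        i, j = (self.channels.index(name) for name in names)
        return float(self.r[i, j]), float(self.p[i, j]), bool(self.relevant[i, j])


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p from the t statistic ``t = r sqrt((n-2)/(1-r^2))``."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_channels(
    sessions: list[RecordingSession],
    group: GroupLabel | None = None,
) -> CorrelationReport:
    """Pairwise Pearson correlations on samples pooled across subjects.

    When ``group`` is given only that group's sessions are pooled;
    otherwise all sessions are.  Pooling concatenates each channel's
    synchronized samples across subjects, matching a per-group analysis
    with large n.  Constant channels yield NaN correlations for their
    pairs, flagged not-relevant rather than failing.
    """
    pool = [s for s in sessions if group is None or s.group == group]
    if not pool:
        raise ValueError("no sessions to correlate")
    kinds = [k for k in ChannelKind if all(k in s for s in pool)]
    if len(kinds) < 2:
        raise ValueError("need at least 2 channels present in every session")
    data = np.vstack([
        np.concatenate([s.values(k) for s in pool]) for k in kinds
    ])
    n = data.shape[1]
    if n < 3:
        raise ValueError("need at least 3 pooled samples")

    m = len(kinds)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    sds = data.std(axis=1)
    for i in range(m):
        if sds[i] == 0:
            continue
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, m):
            if sds[j] == 0:
                continue
            rij = float(np.corrcoef(data[i], data[j])[0, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = _pearson_p(rij, n)

    with np.errstate(invalid="ignore"):
        relevant = (p < RELEVANCE_P_THRESHOLD) & (np.abs(r) > RELEVANCE_R_THRESHOLD)
    relevant = np.where(np.isnan(r), False, relevant)
    np.fill_diagonal(relevant, False)  # self-pairs are trivially r=1

    dist = 1.0 - np.abs(np.where(np.isnan(r), 0.0, r))
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return CorrelationReport(
        channels=[k.value for k in kinds],
        r=r,
        p=p,
        relevant=relevant.astype(bool),
        dendrogram_order=[int(i) for i in order],
        n=n,
        group=group,
    )
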