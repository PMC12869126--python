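"""Joint binning, chord payloads, and correlation relevance."""

import numpy as np
import pytest

from microcirc.channels import ChannelKind, GroupLabel
from microcirc.coherence import (
    CoherenceMatrix,
    chord_payload,
    correlate_channels,
    filter_chords,
    joint_histogram,
    make_bins,
)
from microcirc.synth import generate_cohort


def test_make_bins_equal_width_edges():
    edges = make_bins([0.0, 100.0], k=10)
    np.testing.assert_allclose(edges, np.arange(0.0, 101.0, 10.0))
    assert len(edges) == 11


def test_max_value_lands_in_last_interval():
    values = np.array([0.0, 5.0, 10.0])
    edges = make_bins(values, k=10)
    matrix = joint_histogram(values, values, edges, edges)
    assert matrix.counts[-1, -1] == 1  # the maximum, via the closed last bin
    assert matrix.n_pairs == 3


def test_degenerate_range_needs_override():
    with pytest.raises(ValueError):
        make_bins([4.0, 4.0, 4.0])
    edges = make_bins([4.0, 4.0, 4.0], range_override=(0.0, 10.0))
    assert edges[0] == 0.0 and edges[-1] == 10.0


def test_single_cell_histogram():
    bp = np.array([1.2, 1.5, 1.8])
    so2 = np.array([52.0, 55.0, 58.0])
    matrix = joint_histogram(bp, so2, make_bins([0, 10]), make_bins([0, 100]))
    assert matrix.counts.sum() == 3
    assert matrix.counts.max() == 3


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        joint_histogram(np.zeros(5), np.zeros(6), make_bins([0, 1]), make_bins([0, 1]))


def test_count_conservation_on_random_inputs():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(10, 400))
        bp = rng.uniform(0, 60, n)
        so2 = rng.uniform(30, 90, n)
        matrix = joint_histogram(bp, so2, make_bins(bp), make_bins(so2))
        assert matrix.counts.sum() == n == matrix.n_pairs


def test_uniform_pairs_fill_cells_multinomially():
    rng = np.random.default_rng(31)
    n = 10_000
    bp = rng.uniform(0, 1, n)
    so2 = rng.uniform(0, 1, n)
    edges = np.linspace(0, 1, 11)
    matrix = joint_histogram(bp, so2, edges, edges)
    expected = n / 100.0
    sd = np.sqrt(n * 0.01 * 0.99)
    assert np.all(np.abs(matrix.counts - expected) < 4 * sd)


def test_joint_permutation_invariance():
    rng = np.random.default_rng(5)
    bp = rng.uniform(0, 10, 500)
    so2 = rng.uniform(0, 100, 500)
    perm = rng.permutation(500)
    edges_bp, edges_so2 = make_bins(bp), make_bins(so2)
    a = joint_histogram(bp, so2, edges_bp, edges_so2)
    b = joint_histogram(bp[perm], so2[perm], edges_bp, edges_so2)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_chord_payload_single_cell():
    counts = np.zeros((10, 10), dtype=int)
    counts[2, 3] = 7
    matrix = CoherenceMatrix(
        bp_edges=np.linspace(0, 10, 11), so2_edges=np.linspace(0, 100, 11),
        counts=counts, group=None, n_pairs=7,
    )
    payload = chord_payload(matrix)
    assert len(payload.chords) == 1
    assert payload.chords[0]["width"] == pytest.approx(1.0)
    widths = [a["width"] for a in payload.arcs if a["width"] > 0]
    assert widths == [1.0, 1.0]


def test_chord_payload_toy_2x2_normalization():
    counts = np.array([[2, 0], [1, 1]])
    matrix = CoherenceMatrix(
        bp_edges=np.array([0.0, 1.0, 2.0]), so2_edges=np.array([0.0, 50.0, 100.0]),
        counts=counts, group=None, n_pairs=4,
    )
    payload = chord_payload(matrix)
    widths = sorted(c["width"] for c in payload.chords)
    assert widths == pytest.approx([0.25, 0.25, 0.5])
    bp_widths = [a["width"] for a in payload.arcs if a["side"] == "BP"]
    so2_widths = [a["width"] for a in payload.arcs if a["side"] == "SO2"]
    assert bp_widths == pytest.approx([0.5, 0.5])
    assert so2_widths == pytest.approx([0.75, 0.25])
    assert sum(c["width"] for c in payload.chords) == pytest.approx(1.0)


def test_arc_widths_sum_to_one_per_side(control_session):
    bp = control_session.values(ChannelKind.BP_TOTAL)
    so2 = control_session.values(ChannelKind.SO2)
    matrix = joint_histogram(bp, so2, make_bins(bp), make_bins(so2))
    payload = chord_payload(matrix)
    for side in ("BP", "SO2"):
        total = sum(a["width"] for a in payload.arcs if a["side"] == side)
        assert total == pytest.approx(1.0)


def test_filter_chords_restricts_to_one_interval():
    counts = np.array([[2, 0], [1, 1]])
    matrix = CoherenceMatrix(
        bp_edges=np.array([0.0, 1.0, 2.0]), so2_edges=np.array([0.0, 50.0, 100.0]),
        counts=counts, group=None, n_pairs=4,
    )
    filtered = filter_chords(chord_payload(matrix), "SO2", 0)
    assert all(c["so2_interval"] == 0 for c in filtered.chords)
    assert sum(c["count"] for c in filtered.chords) == 3


def test_empty_matrix_rejected():
    matrix = CoherenceMatrix(
        bp_edges=np.array([0.0, 1.0]), so2_edges=np.array([0.0, 1.0]),
        counts=np.zeros((1, 1), dtype=int), group=None, n_pairs=0,
    )
    with pytest.raises(ValueError):
        chord_payload(matrix)


def test_self_pair_correlation_is_unit(config):
    cohort = generate_cohort(config, 1)
    report = correlate_channels(cohort, GroupLabel.CONTROL)
    i = report.channels.index("SO2")
    assert report.r[i, i] == pytest.approx(1.0)
    assert report.p[i, i] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(report.r, report.r.T, equal_nan=True)


def test_relevance_rule_threshold_cases():
    # r = 0.45 at n = 200 clears both the p and |r| thresholds;
    # r = 0.39 fails the |r| threshold however small p is.
    from microcirc.coherence import _pearson_p

    assert _pearson_p(0.45, 200) < 0.05
    assert abs(0.45) > 0.4 and not abs(0.39) > 0.4


def test_generator_correlation_recovered_and_flagged(config):
    cohort = generate_cohort(config, 3)
    report = correlate_channels(cohort, GroupLabel.CONTROL)
    r, p, relevant = report.pair(ChannelKind.HB_OXY, ChannelKind.BP_LOW)
    assert report.n >= 1500
    assert r == pytest.approx(config.target_correlation, abs=0.1)
    assert p < 0.05
    assert relevant


def test_constant_channel_flagged_not_fatal(config):
    from microcirc.channels import TimeSeriesChannel
    from microcirc.synth import generate_session

    session = generate_session(config, GroupLabel.CONTROL, "c", seed=55)
    channels = dict(session.channels)
    channels[ChannelKind.BP_CONV] = TimeSeriesChannel(
        kind=ChannelKind.BP_CONV,
        sampling_interval=session.sampling_interval,
        values=np.full(session.n_samples, 42.0),
    )
    report = correlate_channels([session.with_channels(channels)])
    i = report.channels.index("BP_CONV")
    assert np.isnan(report.r[i, :]).all()
    assert not report.relevant[i, :].any()


def test_dendrogram_order_is_permutation(config):
    cohort = generate_cohort(config, 1)
    report = correlate_channels(cohort, GroupLabel.T2DM)
    assert sorted(report.dendrogram_order) == list(range(len(report.channels)))
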