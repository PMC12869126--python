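"""Speed-band, oxygenation, and resistance-index metrics."""

import math

import numpy as np
import pytest
from scipy.signal import periodogram

from microcirc.channels import ChannelKind, GroupLabel, TimeSeriesChannel
from microcirc.metrics import (
    InsufficientDurationError,
    compute_imr,
    compute_mvel,
    estimate_mfre,
    oxygen_summary,
    session_indices,
    summarize_speed_bands,
)
from microcirc.synth import GroupEffectProfile, SyntheticConfig, generate_session


def _constant_session(bands=(2.0, 5.0, 3.0), oxy=6.0, red=4.0, n=100, crbc=2.0):
    dt = 0.1
    low, mid, high = (np.full(n, b) for b in bands)
    oxy_arr, red_arr = np.full(n, oxy), np.full(n, red)
    total_hb = oxy_arr + red_arr
    so2 = np.where(total_hb > 0, 100.0 * oxy_arr / np.maximum(total_hb, 1e-30), 0.0)
    arrays = {
        ChannelKind.CRBC: np.full(n, crbc),
        ChannelKind.SO2: so2,
        ChannelKind.HB_TOTAL: total_hb,
        ChannelKind.HB_OXY: oxy_arr,
        ChannelKind.HB_RED: red_arr,
        ChannelKind.BP_LOW: low,
        ChannelKind.BP_MID: mid,
        ChannelKind.BP_HIGH: high,
        ChannelKind.BP_TOTAL: low + mid + high,
        ChannelKind.BP_CONV: np.full(n, 100.0),
    }
    from microcirc.channels import RecordingSession

    return RecordingSession(
        subject_id="const",
        group=GroupLabel.CONTROL,
        channels={
            k: TimeSeriesChannel(kind=k, sampling_interval=dt, values=v)
            for k, v in arrays.items()
        },
    )


@pytest.mark.parametrize(
    "bands, expected",
    [((2.0, 5.0, 3.0), (20.0, 50.0, 30.0)), ((0.0, 5.0, 5.0), (0.0, 50.0, 50.0))],
)
def test_band_shares_arithmetic(bands, expected):
    summary = summarize_speed_bands(_constant_session(bands=bands))
    assert (summary.rel_low, summary.rel_mid, summary.rel_high) == pytest.approx(expected)
    assert summary.rel_low + summary.rel_mid + summary.rel_high == pytest.approx(100.0, abs=1e-6)


def test_all_zero_bands_flagged_undefined():
    summary = summarize_speed_bands(_constant_session(bands=(0.0, 0.0, 0.0)))
    assert not summary.shares_defined
    assert math.isnan(summary.rel_low)


def test_oxygen_split_and_ratio():
    summary = oxygen_summary(_constant_session(oxy=6.0, red=4.0))
    assert summary.rel_oxy == pytest.approx(60.0)
    assert summary.rel_red == pytest.approx(40.0)
    assert summary.oxy_red_ratio == pytest.approx(1.5)
    assert summary.rel_oxy + summary.rel_red == pytest.approx(100.0, abs=1e-6)


def test_equal_oxy_red_gives_unit_ratio():
    summary = oxygen_summary(_constant_session(oxy=5.0, red=5.0))
    assert summary.oxy_red_ratio == pytest.approx(1.0)


def test_mvel_arithmetic_and_homogeneity():
    assert compute_mvel(10.0, 2.0) == pytest.approx(5.0)
    assert compute_mvel(0.0, 3.0) == 0.0
    assert compute_mvel(20.0, 4.0) == pytest.approx(compute_mvel(10.0, 2.0))
    with pytest.raises(ZeroDivisionError):
        compute_mvel(10.0, 0.0)


def test_imr_arithmetic():
    assert compute_imr(10.0, 5.0, 10.0, 0.15) == pytest.approx(10.0 / (5.0 * 10.0 * 0.15))
    with pytest.raises(ZeroDivisionError):
        compute_imr(10.0, 5.0, 0.0, 0.15)


def test_imr_invariant_under_joint_perfusion_rescaling():
    # Mvel = Mbp / C_RBC couples the two: doubling Mbp doubles Mvel and
    # leaves the resistance index unchanged.
    base = compute_imr(10.0, compute_mvel(10.0, 2.0), 12.0)
    doubled = compute_imr(20.0, compute_mvel(20.0, 2.0), 12.0)
    assert doubled == pytest.approx(base)


def test_s_constant_unit_scales_imr_by_1000():
    in_mm = compute_imr(10.0, 5.0, 10.0, 0.15)
    in_um = compute_imr(10.0, 5.0, 10.0, 150.0)
    assert in_mm == pytest.approx(1000.0 * in_um)


def test_mfre_clean_sine_counts_cycles():
    t = np.arange(int(60.0 * 20.0)) / 20.0  # 60 s at 20 Hz
    rate = estimate_mfre(np.sin(2 * np.pi * 0.5 * t), sampling_interval=0.05)
    assert rate == pytest.approx(30.0, abs=1.0)


def test_mfre_noisy_sine_within_5_percent():
    rng = np.random.default_rng(42)
    t = np.arange(int(60.0 * 20.0)) / 20.0
    signal = np.sin(2 * np.pi * 0.5 * t) + 0.05 * rng.standard_normal(t.size)
    rate = estimate_mfre(signal, sampling_interval=0.05)
    assert rate == pytest.approx(30.0, rel=0.05)


def test_mfre_constant_series_is_zero():
    assert estimate_mfre(np.full(100, 7.0), sampling_interval=0.1) == 0.0


def test_mfre_too_short_series_rejected():
    with pytest.raises(InsufficientDurationError):
        estimate_mfre(np.array([1.0, 2.0]), sampling_interval=0.1)


def test_mfre_agrees_with_spectral_peak_on_generated_sessions(config):
    # Independent oracle: dominant periodogram frequency of the detrended
    # perfusion trace, converted to cycles per minute.
    for group in (GroupLabel.CONTROL, GroupLabel.T2DM):
        session = generate_session(config, group, "spectral", seed=11)
        chan = session.channels[ChannelKind.BP_TOTAL]
        freqs, power = periodogram(
            chan.values - chan.values.mean(), fs=1.0 / chan.sampling_interval
        )
        spectral = 60.0 * freqs[np.argmax(power)]
        assert estimate_mfre(chan) == pytest.approx(spectral, rel=0.05)


def test_session_indices_match_hand_chained_formulas():
    profiles = {g: GroupEffectProfile(vasomotion_freq=12.0) for g in GroupLabel}
    cfg = SyntheticConfig(
        n_samples=1200,
        noise_sd={k: 0.0 for k in SyntheticConfig().noise_sd},
        group_profiles=profiles,
        seed=3,
    )
    session = generate_session(cfg, GroupLabel.CONTROL, "clean")
    indices = session_indices(session)

    mbp = float(np.mean(session.values(ChannelKind.BP_TOTAL)))
    crbc = float(np.mean(session.values(ChannelKind.CRBC)))
    assert indices.mbp == pytest.approx(mbp)
    assert indices.mvel == pytest.approx(mbp / crbc)
    # noiseless 12 cycles/min over 120 s
    assert indices.mfre == pytest.approx(12.0, abs=0.5)
    assert indices.imr == pytest.approx(
        mbp / (indices.mvel * indices.mfre * 0.15)
    )


def test_t2dm_has_lower_mfre_and_higher_imr_than_control(config):
    rows = {}
    for group in (GroupLabel.CONTROL, GroupLabel.T2DM):
        values = [
            session_indices(generate_session(config, group, f"s{i}", seed=100 + i))
            for i in range(6)
        ]
        rows[group] = (
            np.mean([v.mfre for v in values]),
            np.mean([v.imr for v in values]),
        )
    assert rows[GroupLabel.T2DM][0] < rows[GroupLabel.CONTROL][0]
    assert rows[GroupLabel.T2DM][1] > rows[GroupLabel.CONTROL][1]
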