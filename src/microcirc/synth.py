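"""Seeded generator of synthetic microcirculatory cohorts.

The generator emulates the statistical structure the downstream analysis
assumes rather than the optics of the instrument: each channel fluctuates
around a group-adjusted baseline with Gaussian noise, total perfusion
carries a sinusoidal vasomotion component, hemoglobin channels are built so
that conservation (HB_TOTAL = HB_OXY + HB_RED) and SO2 consistency hold
exactly, and a shared latent Gaussian driver induces a configurable Pearson
correlation between oxygenized hemoglobin and low-speed perfusion.

The latent-driver construction is closed-form: with the low-speed perfusion
noise equal to the driver ``L`` and the oxygenized-Hb noise equal to
``(w·L + e)/sqrt(1 + w²)`` for independent standard normals ``L, e``, the
population correlation is ``w/sqrt(1 + w²)``; solving for ``w`` at the
target correlation ``r`` gives ``w = r/sqrt(1 - r²)``.

Group effects are multiplicative on perfusion, red-cell fraction and
hemoglobin, additive (percentage points) on oxygen saturation, and
multiplicative on vasomotion frequency.  The disease profile lowers
high-speed perfusion most strongly, shifts saturation down, and slows
vasomotion; the treated groups recover partially, the longer liraglutide
course most completely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    BAND_CHANNELS,
    ChannelKind,
    GroupLabel,
    RecordingSession,
    TimeSeriesChannel,
)

__all__ = [
    "GroupEffectProfile",
    "SyntheticConfig",
    "default_group_profiles",
    "generate_session",
    "generate_cohort",
    "inject_artifacts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupEffectProfile:
    """Multiplicative / additive effects of one experimental group.

    Parameters
    ----------
    perfusion_multipliers
        (low, mid, high) band multipliers, each > 0.
    so2_shift
        Additive shift of the oxygen-saturation baseline, percentage points.
    crbc_multiplier, hb_multiplier
        Multipliers on red-cell tissue fraction and total hemoglobin.
    vasomotion_freq
        Vasomotion rate in oscillations (cycles) per minute, >= 0.
    """

    perfusion_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    so2_shift: float = 0.0
    crbc_multiplier: float = 1.0
    hb_multiplier: float = 1.0
    vasomotion_freq: float = 12.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.perfusion_multipliers):
            raise ValueError("perfusion multipliers must be positive")
        if self.crbc_multiplier <= 0 or self.hb_multiplier <= 0:
            raise ValueError("channel multipliers must be positive")
        if self.vasomotion_freq < 0:
            raise ValueError("vasomotion_freq must be >= 0")


def default_group_profiles() -> dict[GroupLabel, GroupEffectProfile]:
    """Default group effects.

    The control profile is identity.  The diabetic profile reduces
    high-speed perfusion to 60%, shifts SO2 down by 10 points, lowers
    red-cell fraction and hemoglobin to 80%, and slows vasomotion to 0.7x
    of the control rate.  Treatment profiles interpolate back toward
    control, with the two-week liraglutide course closest to it.
    """
    ctrl_freq = 12.0
    return {
        GroupLabel.CONTROL: GroupEffectProfile(vasomotion_freq=ctrl_freq),
        GroupLabel.T2DM: GroupEffectProfile(
            perfusion_multipliers=(0.85, 0.80, 0.60),
            so2_shift=-10.0,
            crbc_multiplier=0.80,
            hb_multiplier=0.80,
            vasomotion_freq=0.7 * ctrl_freq,
        ),
        GroupLabel.INSULIN_1W: GroupEffectProfile(
            perfusion_multipliers=(0.92, 0.88, 0.78),
            so2_shift=-5.0,
            crbc_multiplier=0.90,
            hb_multiplier=0.90,
            vasomotion_freq=10.0,
        ),
        GroupLabel.INSULIN_2W: GroupEffectProfile(
            perfusion_multipliers=(0.94, 0.90, 0.82),
            so2_shift=-4.0,
            crbc_multiplier=0.92,
            hb_multiplier=0.92,
            vasomotion_freq=10.4,
        ),
        GroupLabel.LIRAGLUTIDE_1W: GroupEffectProfile(
            perfusion_multipliers=(0.95, 0.92, 0.85),
            so2_shift=-3.5,
            crbc_multiplier=0.92,
            hb_multiplier=0.93,
            vasomotion_freq=10.8,
        ),
        GroupLabel.LIRAGLUTIDE_2W: GroupEffectProfile(
            perfusion_multipliers=(0.98, 0.97, 0.95),
            so2_shift=-1.5,
            crbc_multiplier=0.97,
            hb_multiplier=0.97,
            vasomotion_freq=11.5,
        ),
    }


def _default_baselines() -> dict[str, float]:
    # Control-group channel means: red-cell fraction and saturation in
    # percent, hemoglobin in µM, perfusion bands in %RBC·mm/s, conventional
    # perfusion in PU.
    return {
        "crbc": 2.0,
        "so2": 65.0,
        "hb_total": 60.0,
        "bp_low": 10.0,
        "bp_mid": 25.0,
        "bp_high": 15.0,
        "bp_conv": 120.0,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "crbc": 0.10,
        "hb_oxy": 1.5,
        "hb_red": 1.5,
        "bp_low": 0.5,
        "bp_mid": 1.0,
        "bp_high": 0.8,
        "bp_conv": 5.0,
    }


@dataclass
class SyntheticConfig:
    """Everything the generator needs, including the master seed.

    ``vasomotion_amplitude_frac`` scales the vasomotion sinusoid as a
    fraction of the group-adjusted mid+high perfusion baseline, so that
    oscillation amplitude shrinks with perfusion in impaired groups.
    """

    n_samples: int = 2000
    sampling_interval: float = 0.1  # seconds; 10 Hz default acquisition rate
    baselines: dict[str, float] = field(default_factory=_default_baselines)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    target_correlation: float = 0.5
    vasomotion_amplitude_frac: float = 0.15
    group_profiles: dict[GroupLabel, GroupEffectProfile] = field(
        default_factory=default_group_profiles
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not -1.0 < self.target_correlation < 1.0:
            raise ValueError("target_correlation must lie in (-1, 1)")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")

    # -- serialization used by the CLI config file ------------------------

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "sampling_interval": self.sampling_interval,
            "baselines": dict(self.baselines),
            "noise_sd": dict(self.noise_sd),
            "target_correlation": self.target_correlation,
            "vasomotion_amplitude_frac": self.vasomotion_amplitude_frac,
            "group_profiles": {
                g.value: {
                    "perfusion_multipliers": list(p.perfusion_multipliers),
                    "so2_shift": p.so2_shift,
                    "crbc_multiplier": p.crbc_multiplier,
                    "hb_multiplier": p.hb_multiplier,
                    "vasomotion_freq": p.vasomotion_freq,
                }
                for g, p in self.group_profiles.items()
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        profiles_raw = data.pop("group_profiles", None)
        cfg = cls(**data) if profiles_raw is None else cls(
            **data,
            group_profiles={
                GroupLabel(g): GroupEffectProfile(
                    perfusion_multipliers=tuple(p["perfusion_multipliers"]),
                    so2_shift=p["so2_shift"],
                    crbc_multiplier=p["crbc_multiplier"],
                    hb_multiplier=p["hb_multiplier"],
                    vasomotion_freq=p["vasomotion_freq"],
                )
                for g, p in profiles_raw.items()
            },
        )
        return cfg


def correlation_mixing_weight(r: float) -> float:
    """Mixing weight ``w`` such that corr(L, (wL+e)/sqrt(1+w²)) = r."""
    return r / math.sqrt(1.0 - r * r)


def _clip_logged(values: np.ndarray, lo: float, hi: float, label: str) -> np.ndarray:
    clipped = np.clip(values, lo, hi)
    n_clipped = int(np.count_nonzero(clipped != values))
    if n_clipped:
        logger.debug("clipped %d samples of %s into [%g, %g]", n_clipped, label, lo, hi)
    return clipped


def generate_session(
    config: SyntheticConfig,
    group: GroupLabel,
    subject_id: str,
    seed: int | None = None,
) -> RecordingSession:
    """Generate one subject's fully consistent synchronized session.

    Derived channels are constructed, not sampled: HB_TOTAL is the exact sum
    of the oxygenized and reduced channels, SO2 is exactly
    ``100·HB_OXY/HB_TOTAL``, and BP_TOTAL is the exact band sum.  The
    vasomotion sinusoid (random phase per subject) is carried by the mid-
    and high-speed bands in proportion to their adjusted baselines; the
    low-speed band instead carries the latent driver shared with
    oxygenized hemoglobin, which leaves the target correlation unattenuated.
    """
    if not isinstance(group, GroupLabel):
        group = GroupLabel(group)
    profile = config.group_profiles.get(group)
    if profile is None:
        raise ValueError(f"no effect profile configured for group {group.value!r}")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    dt = config.sampling_interval
    base = config.baselines
    sd = config.noise_sd
    m_low, m_mid, m_high = profile.perfusion_multipliers

    t = np.arange(n) * dt
    phase = rng.uniform(0.0, 2.0 * math.pi)
    freq_hz = profile.vasomotion_freq / 60.0
    osc = np.sin(2.0 * math.pi * freq_hz * t + phase) if freq_hz > 0 else np.zeros(n)

    # Shared latent driver and the mixing weight hitting target_correlation.
    latent = rng.standard_normal(n)
    e_oxy = rng.standard_normal(n)
    w = correlation_mixing_weight(config.target_correlation)
    oxy_noise = (w * latent + e_oxy) / math.sqrt(1.0 + w * w)

    # Perfusion bands.
    adj_mid = base["bp_mid"] * m_mid
    adj_high = base["bp_high"] * m_high
    amp = config.vasomotion_amplitude_frac * (adj_mid + adj_high)
    share = adj_mid / (adj_mid + adj_high) if (adj_mid + adj_high) > 0 else 0.5
    bp_low = base["bp_low"] * m_low + sd["bp_low"] * latent
    bp_mid = adj_mid + amp * share * osc + sd["bp_mid"] * rng.standard_normal(n)
    bp_high = adj_high + amp * (1.0 - share) * osc + sd["bp_high"] * rng.standard_normal(n)
    bp_low = _clip_logged(bp_low, 0.0, np.inf, "BP_LOW")
    bp_mid = _clip_logged(bp_mid, 0.0, np.inf, "BP_MID")
    bp_high = _clip_logged(bp_high, 0.0, np.inf, "BP_HIGH")
    bp_total = bp_low + bp_mid + bp_high

    mean_mult = (m_low + m_mid + m_high) / 3.0
    bp_conv = base["bp_conv"] * mean_mult + sd["bp_conv"] * rng.standard_normal(n)
    bp_conv = _clip_logged(bp_conv, 0.0, np.inf, "BP_CONV")

    # Hemoglobin: oxy and red sampled, total and SO2 derived exactly.
    hb_total_base = base["hb_total"] * profile.hb_multiplier
    so2_target = base["so2"] + profile.so2_shift
    hb_oxy_base = hb_total_base * so2_target / 100.0
    hb_red_base = hb_total_base - hb_oxy_base
    hb_oxy = _clip_logged(hb_oxy_base + sd["hb_oxy"] * oxy_noise, 0.0, np.inf, "HB_OXY")
    hb_red = _clip_logged(
        hb_red_base + sd["hb_red"] * rng.standard_normal(n), 0.0, np.inf, "HB_RED"
    )
    hb_total = hb_oxy + hb_red
    so2 = np.zeros(n)
    pos = hb_total > 0
    so2[pos] = 100.0 * hb_oxy[pos] / hb_total[pos]

    crbc = _clip_logged(
        base["crbc"] * profile.crbc_multiplier + sd["crbc"] * rng.standard_normal(n),
        0.0, 100.0, "CRBC",
    )

    arrays = {
        ChannelKind.CRBC: crbc,
        ChannelKind.SO2: so2,
        ChannelKind.HB_TOTAL: hb_total,
        ChannelKind.HB_OXY: hb_oxy,
        ChannelKind.HB_RED: hb_red,
        ChannelKind.BP_LOW: bp_low,
        ChannelKind.BP_MID: bp_mid,
        ChannelKind.BP_HIGH: bp_high,
        ChannelKind.BP_TOTAL: bp_total,
        ChannelKind.BP_CONV: bp_conv,
    }
    channels = {
        kind: TimeSeriesChannel(kind=kind, sampling_interval=dt, values=vals)
        for kind, vals in arrays.items()
    }
    return RecordingSession(subject_id=subject_id, group=group, channels=channels)


def generate_cohort(config: SyntheticConfig, n_per_group: int) -> list[RecordingSession]:
    """Generate ``n_per_group`` subjects for each of the six groups.

    Per-subject seeds are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence``, so the cohort is a pure function of the
    configuration.  Subject ids are ``<group>_<k>``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = list(GroupLabel)
    children = np.random.SeedSequence(config.seed).spawn(len(groups) * n_per_group)
    sessions: list[RecordingSession] = []
    idx = 0
    for group in groups:
        for k in range(n_per_group):
            subject_seed = int(children[idx].generate_state(1)[0] % (2**31))
            sessions.append(
                generate_session(config, group, f"{group.value}_{k + 1}", seed=subject_seed)
            )
            idx += 1
    return sessions


def inject_artifacts(
    session: RecordingSession,
    rate: float,
    magnitude_sd_units: float,
    seed: int,
    channels: tuple[ChannelKind, ...] | None = None,
) -> tuple[RecordingSession, dict[ChannelKind, np.ndarray]]:
    """Displace ``floor(rate·n)`` random samples per targeted channel.

    Each chosen sample is moved by ``±magnitude_sd_units`` channel standard
    deviations (sign random).  Derived-channel consistency is deliberately
    not repaired: real instrument glitches hit channels independently, and
    leaving the conservation violations in place makes them detectable by
    validation.  Returns the corrupted session and the injected indices per
    channel (sorted), for recovery studies.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("artifact rate must lie in [0, 1]")
    if magnitude_sd_units <= 0:
        raise ValueError("magnitude_sd_units must be positive")
    targeted = tuple(session.channels) if channels is None else channels
    rng = np.random.default_rng(seed)
    n = session.n_samples
    n_inject = int(math.floor(rate * n))

    new_channels = dict(session.channels)
    injected: dict[ChannelKind, np.ndarray] = {}
    for kind in targeted:
        chan = session.channels[kind]
        if n_inject == 0:
            injected[kind] = np.array([], dtype=int)
            continue
        idx = np.sort(rng.choice(n, size=n_inject, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_inject)
        scale = float(np.std(chan.values))
        vals = chan.values.copy()
        vals[idx] = vals[idx] + signs * magnitude_sd_units * scale
        new_channels[kind] = TimeSeriesChannel(
            kind=kind, sampling_interval=chan.sampling_interval, values=vals
        )
        injected[kind] = idx
    return session.with_channels(new_channels), injected
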