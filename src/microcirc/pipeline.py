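"""End-to-end pipeline: simulate/load -> validate -> preprocess ->
normalize -> metrics -> coherence -> export.

The whole run is a pure function of the configuration document: the
synthetic cohort is seeded, every stage is deterministic, and each output
directory carries a manifest (configuration hash, seed, package version)
sufficient to reproduce the artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .channels import ChannelKind, GroupLabel, validate_session
from .coherence import chord_payload, correlate_channels, joint_histogram, make_bins
from .io import (
    dump_json,
    export_bubble_payload,
    export_surface_json,
    group_metrics_table,
    metrics_table,
    read_sessions_csv,
    sessions_to_frame,
    write_correlation_csv,
    write_sessions_csv,
)
from .normalize import NormalizationMethod
from .preprocess import preprocess_session
from .synth import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfigError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """The configuration document is invalid; nothing has run."""


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineConfigError("config document must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _validate_config(config: dict) -> None:
    if ("simulate" in config) == ("input_csv" in config):
        raise PipelineConfigError("config needs exactly one of 'simulate' or 'input_csv'")
    method = config.get("normalization", "minmax")
    try:
        NormalizationMethod(method)
    except ValueError:
        valid = [m.value for m in NormalizationMethod]
        raise PipelineConfigError(
            f"unknown normalization {method!r}; choose one of {valid}"
        ) from None
    if config.get("bin_range", "pooled") not in ("pooled", "per_group"):
        raise PipelineConfigError("bin_range must be 'pooled' or 'per_group'")


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute every stage in order and write the artifact tree.

    Returns the artifact directory.  Raises :class:`PipelineConfigError`
    before any stage runs when the configuration is malformed; stage
    failures propagate with the failing stage in the log.
    """
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: simulate / load ------------------------------------------
    if "simulate" in config:
        sim = dict(config["simulate"])
        n_per_group = int(sim.pop("n_per_group", 3))
        synth_config = SyntheticConfig.from_dict(sim)
        sessions = generate_cohort(synth_config, n_per_group)
        write_sessions_csv(sessions, out / "sessions.csv")
        logger.info("simulate: %d sessions (%d per group)", len(sessions), n_per_group)
        seed = synth_config.seed
    else:
        sessions = read_sessions_csv(config["input_csv"])
        logger.info("load: %d sessions from %s", len(sessions), config["input_csv"])
        seed = None

    # -- stage: validate --------------------------------------------------
    n_violations = 0
    for s in sessions:
        report = validate_session(s)
        n_violations += len(report.violations)
    logger.info("validate: %d sessions, %d violations", len(sessions), n_violations)

    # -- stage: preprocess ------------------------------------------------
    processed, all_reports = [], {}
    n_adjusted = 0
    for s in sessions:
        clean, reports = preprocess_session(s)
        processed.append(clean)
        all_reports[s.subject_id] = {
            kind.value: rep.to_dict() for kind, rep in reports.items()
        }
        n_adjusted += sum(len(rep.adjusted_indices) for rep in reports.values())
    dump_json(all_reports, out / "fence_reports.json")
    write_sessions_csv(processed, out / "sessions_processed.csv")
    logger.info("preprocess: %d samples winsorized", n_adjusted)

    # -- stage: normalize (surface export carries the normalized view) ----
    method = NormalizationMethod(config.get("normalization", "minmax"))
    export_surface_json(processed, method, out)
    logger.info("normalize: %s surfaces exported", method.value)

    # -- stage: metrics ----------------------------------------------------
    s_constant = float(config.get("s_constant", 0.15))
    s_unit = str(config.get("s_unit", "mm"))
    table = metrics_table(processed, s_constant=s_constant, s_unit=s_unit)
    table.to_csv(out / "metrics.csv", index=False)
    group_metrics_table(table).to_csv(out / "metrics_groups.csv", index=False)
    long = table.melt(
        id_vars=["subject_id", "group"], var_name="metric", value_name="value"
    )
    bubbles = export_bubble_payload(
        long.groupby(["group", "metric"], sort=False, as_index=False)["value"].mean()
    )
    dump_json(bubbles, out / "bubbles.json")
    logger.info("metrics: %d subjects summarized", len(table))

    # -- stage: coherence --------------------------------------------------
    n_bins = int(config.get("bins", 10))
    pooled_range = config.get("bin_range", "pooled") == "pooled"
    if pooled_range:
        bp_all = np.concatenate([s.values(ChannelKind.BP_TOTAL) for s in processed])
        so2_all = np.concatenate([s.values(ChannelKind.SO2) for s in processed])
        bp_edges = make_bins(bp_all, n_bins)
        so2_edges = make_bins(so2_all, n_bins)
    for group in GroupLabel:
        members = [s for s in processed if s.group == group]
        if not members:
            continue
        bp = np.concatenate([s.values(ChannelKind.BP_TOTAL) for s in members])
        so2 = np.concatenate([s.values(ChannelKind.SO2) for s in members])
        if not pooled_range:
            bp_edges = make_bins(bp, n_bins)
            so2_edges = make_bins(so2, n_bins)
        matrix = joint_histogram(bp, so2, bp_edges, so2_edges, group)
        dump_json(
            {"matrix": matrix.to_dict(), "chords": chord_payload(matrix).to_dict()},
            out / f"coherence_{group.value}.json",
        )
        corr = correlate_channels(members, group)
        write_correlation_csv(
            corr,
            out / f"correlations_{group.value}.csv",
            out / f"correlations_{group.value}_flags.csv",
        )
    logger.info("coherence: %d-bin joint histograms and correlations written", n_bins)

    # -- stage: export manifest -------------------------------------------
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    dump_json(manifest, out / "manifest.json")
    return out
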