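"""Run configuration and end-to-end pipeline orchestration.

A run is a pure function of (inputs, config, seed): stages execute in
order, every artifact lands in the run directory, and a manifest records
the package version, parameters, per-stage seeds, and SHA-256 digests of
all outputs so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as mio
from .errors import ConfigError
from .fret import analyze_fret_trace
from .segmentation import SegmentationParams, extract_dwells, segment_trajectory
from .synthetic import (
    FretSimParams,
    SchemeParams,
    TwoStateTrajParams,
    simulate_fret_trace,
    simulate_two_state_trajectory,
)

log = logging.getLogger("motorkin")

_KNOWN_KEYS = {"seed", "out_dir", "stages", "simulate", "segment", "fret", "log_level"}
_KNOWN_STAGES = {"simulate", "segment", "fret", "report"}


@dataclass
class RunConfig:
    out_dir: str
    stages: list[str]
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    fret: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = sorted(set(raw) - _KNOWN_KEYS)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        for req in ("out_dir", "stages"):
            if req not in raw:
                raise ConfigError(f"missing required config key: '{req}'")
        bad = sorted(set(raw["stages"]) - _KNOWN_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {bad} (known: {sorted(_KNOWN_STAGES)})")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A single root seed spawns one independent RNG stream per stage, so
    stage order and stage-internal draws never interfere.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            sorted(_KNOWN_STAGES), np.random.SeedSequence(config.seed).spawn(4)
        )
    }
    artifacts: dict[str, str] = {}
    truth_params: dict | None = None

    if "simulate" in config.stages:
        sim = dict(config.simulate)
        kind = sim.pop("kind", "trajectory")
        seed = sim.pop("seed", stage_seeds["simulate"])
        if kind == "trajectory":
            params = TwoStateTrajParams(seed=seed, **sim)
            traj, truth = simulate_two_state_trajectory(params)
            mio.write_trajectory_csv(traj, out / "trajectory.csv")
            mio.write_ground_truth_json(
                out / "trajectory_truth.json",
                parameters=dataclasses.asdict(params), seed=seed,
                events=[[s, d] for s, d in truth.source_events],
                labels=truth.labels,
            )
            artifacts["trajectory"] = "trajectory.csv"
            artifacts["trajectory_truth"] = "trajectory_truth.json"
            truth_params = dataclasses.asdict(params)
        elif kind == "fret":
            scheme = SchemeParams(**sim.pop("scheme"))
            params = FretSimParams(scheme=scheme, seed=seed, **sim)
            trace, events = simulate_fret_trace(params)
            mio.write_fret_csv(trace, out / "fret.csv")
            mio.write_ground_truth_json(
                out / "fret_truth.json",
                parameters={**dataclasses.asdict(params)}, seed=seed,
                events=[dataclasses.asdict(e) for e in events],
            )
            artifacts["fret"] = "fret.csv"
            artifacts["fret_truth"] = "fret_truth.json"
        else:
            raise ConfigError(f"unknown simulate kind {kind!r}")
        log.info("simulate: wrote %s", sorted(artifacts))

    if "segment" in config.stages:
        seg_cfg = dict(config.segment)
        traj_path = seg_cfg.pop("traj", out / "trajectory.csv")
        frame_rate = seg_cfg.pop("frame_rate", None)
        params = SegmentationParams(**seg_cfg)
        traj = mio.read_trajectory_csv(traj_path, frame_rate)
        seg = segment_trajectory(traj, params)
        mio.write_segmentation_json(seg, out / "segmentation.json")
        mio.write_dwell_csv(extract_dwells(seg), out / "dwells.csv")
        artifacts["segmentation"] = "segmentation.json"
        artifacts["dwells"] = "dwells.csv"
        log.info("segment: %d dwells", len(seg.dwells))

    if "fret" in config.stages:
        fr = dict(config.fret)
        trace_path = fr.pop("trace", out / "fret.csv")
        trace = mio.read_fret_csv(trace_path)
        events, summary = analyze_fret_trace(trace, **fr)
        events.to_csv(out / "fret_events.csv", index=False)
        (out / "fret_summary.json").write_text(json.dumps(summary, indent=1))
        artifacts["fret_events"] = "fret_events.csv"
        artifacts["fret_summary"] = "fret_summary.json"

    if "report" in config.stages:
        report: dict = {}
        dwell_path = out / "dwells.csv"
        if dwell_path.exists():
            dwells = mio.read_dwell_csv(dwell_path)
            for state in ("bound", "unbound"):
                sub = dwells[(dwells.state == state) & ~dwells.censored]
                if len(sub):
                    report[f"mean_{state}_dwell_s"] = float(sub.duration_s.mean())
                    report[f"n_{state}"] = int(len(sub))
        if truth_params is not None:
            report["truth"] = {
                "mean_bound_dwell_s": truth_params.get("mean_bound_dwell"),
                "mean_unbound_dwell_s": truth_params.get("mean_unbound_dwell"),
            }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        artifacts["report"] = "report.json"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": dataclasses.asdict(config),
        "artifacts": {k: {"file": v, "sha256": _sha256(out / v)}
                      for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
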