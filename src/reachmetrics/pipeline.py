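"""End-to-end orchestration: simulate -> read -> segment -> features/latency -> stats.

One :func:`run` call executes the requested stages with a single seed,
writes all result tables as delimited text, and records a manifest
(config echo, versions, seed, per-stage record counts) sufficient to
reproduce every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .emg import FilterSpec, peak_latency
from .kinematics import analysis_cell, extract_features, summaries_to_frame, summarize
from .segmentation import segment_session
from .session_io import EventLog, read_emg, read_events, read_trajectory
from .simulate import SimulationConfig, simulate_session
from .stats import RmDataset, posthoc_bonferroni, rm_anova2, rm_dataset_from_summaries

__all__ = ["RunConfig", "run", "analyze_session", "stats_tables"]

log = logging.getLogger("reachmetrics")

FEATURES = ("movement_time", "v_avg", "v_peak", "time_to_peak", "n_peak")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "full"  # simulate | analyze | full
    out_dir: str = "reachmetrics_out"
    session_dir: str | None = None  # input sessions (analyze mode)
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    smoothing_cutoff: float | None = 10.0
    amplitude_cutoff: float = 0.020
    min_separation: float = 0.150
    sphericity_policy: str = "auto"
    all_pairs_posthoc: bool = False
    write_sessions: bool = False  # full mode: also persist raw session files
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze" and self.session_dir is None:
            raise ValueError("analyze mode requires session_dir")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "simulation" in raw and not isinstance(raw["simulation"], SimulationConfig):
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if "filter_spec" in raw and not isinstance(raw["filter_spec"], FilterSpec):
            raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
        return cls(**raw)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def analyze_session(
    traj, events: EventLog, participant: str, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment one session and compute per-segment features + cell summaries."""
    segments = segment_session(traj, events)
    rows = []
    pairs = []
    for seg in segments:
        feats = extract_features(
            seg,
            smoothing_cutoff=cfg.smoothing_cutoff,
            amplitude_cutoff=cfg.amplitude_cutoff,
            min_separation=cfg.min_separation,
        )
        pairs.append((seg.trial, feats))
        rows.append(
            {
                "participant": participant,
                "trial": seg.trial.index,
                "ball_mode": seg.trial.ball_mode,
                "phase": seg.trial.phase,
                "feedback": seg.trial.feedback,
                "cell": analysis_cell(seg.trial) or "",
                **{f: getattr(feats, f) for f in FEATURES},
            }
        )
    features_df = pd.DataFrame(rows)
    summary_df = summaries_to_frame(summarize(pairs, participant))
    return features_df, summary_df


def _session_latencies(emg_rec, events: EventLog, participant: str, cfg: RunConfig) -> pd.DataFrame:
    """Peak latency per (ball mode, analysis cell, muscle), first segments."""
    cells = [("baseline", "none"), ("retention", "TV"), ("retention", "TH"), ("retention", "TM")]
    rows = []
    for mode in sorted({t.ball_mode for t in events}):
        for phase, feedback in cells:
            try:
                results = peak_latency(
                    emg_rec, events, cfg.filter_spec, ball_mode=mode,
                    phase=phase, feedback=feedback,
                )
            except LookupError:
                continue
            cell = "baseline" if phase == "baseline" else feedback
            for r in results:
                rows.append(
                    {
                        "participant": participant,
                        "ball_mode": mode,
                        "cell": cell,
                        "muscle": r.muscle,
                        "latency": r.latency,
                        "trial": r.segment.index,
                    }
                )
    return pd.DataFrame(rows)


def stats_tables(
    summary_df: pd.DataFrame,
    latency_df: pd.DataFrame | None,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA and post-hoc tables for every feature (and muscle latency)."""
    responses: list[tuple[str, RmDataset]] = [
        (feat, rm_dataset_from_summaries(summary_df, feat)) for feat in FEATURES
    ]
    if latency_df is not None and len(latency_df):
        for muscle, sub in latency_df.groupby("muscle", sort=True):
            df = sub.rename(columns={"latency": "value"})[
                ["participant", "ball_mode", "cell", "value"]
            ]
            order = {"baseline": 0, "TV": 1, "TH": 2, "TM": 3}
            df = df.sort_values(
                ["participant", "ball_mode", "cell"],
                key=lambda c: c.map(order) if c.name == "cell" else c,
                kind="stable",
            ).reset_index(drop=True)
            responses.append((f"latency[{muscle}]", RmDataset(data=df)))

    anova_rows, posthoc_rows = [], []
    for name, data in responses:
        table = rm_anova2(data, sphericity_policy=cfg.sphericity_policy)
        for eff in table.effects:
            anova_rows.append(
                {
                    "response": name,
                    "effect": {"A": "ballsize", "B": "feedback", "A*B": "ballsize+feedback"}[eff.effect],
                    "F": eff.f,
                    "df": eff.df,
                    "df_error": eff.df_error,
                    "p": eff.p,
                    "mauchly_W": eff.mauchly_w,
                    "mauchly_p": eff.mauchly_p,
                    "epsilon": eff.epsilon,
                    "sig": _stars(eff.p),
                }
            )
        levels = data.b_levels
        comparisons = (
            [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
            if cfg.all_pairs_posthoc
            else None
        )
        for ph in posthoc_bonferroni(data, factor="B", comparisons=comparisons):
            posthoc_rows.append(
                {
                    "response": name,
                    "ball_mode": ph.split,
                    "comparison": f"{ph.comparison[0]} vs {ph.comparison[1]}",
                    "n": ph.n,
                    "t": ph.t,
                    "mean_diff": ph.mean_diff,
                    "p_raw": ph.p_raw,
                    "p_bonferroni": ph.p_adjusted,
                    "m": ph.m,
                    "sig": _stars(ph.p_adjusted),
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(posthoc_rows)


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reachmetrics v{__version__}; seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    logging.basicConfig(level=cfg.log_level, stream=sys.stderr)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": _config_echo(cfg),
        "stages": {},
    }

    sessions: list[tuple[str, object, object, EventLog]] = []  # (id, traj, emg, events)
    if cfg.mode in ("simulate", "full"):
        log.info("simulating %d participants", sim.n_participants)
        for p in range(sim.n_participants):
            pid = f"P{p:02d}"
            session = simulate_session(sim, p)
            if cfg.mode == "simulate" or cfg.write_sessions:
                session.write(out / "sessions" / pid)
            sessions.append((pid, session.trajectory, session.emg, session.events))
        manifest["stages"]["simulate"] = {
            "participants": sim.n_participants,
            "trials_per_participant": len(sessions[0][3]),
            "ball_modes": list(sim.ball_modes),
            "blocks_per_mode": len(sim.protocol),
        }
    if cfg.mode == "analyze":
        root = Path(cfg.session_dir)
        for pdir in sorted(d for d in root.iterdir() if d.is_dir()):
            for fname in ("trajectory.csv", "events.jsonl"):
                if not (pdir / fname).exists():
                    raise FileNotFoundError(f"analyze: {pdir / fname} is missing")
            traj = read_trajectory(pdir / "trajectory.csv")
            events = read_events(pdir / "events.jsonl")
            emg_path = pdir / "emg.csv"
            emg_rec = read_emg(emg_path) if emg_path.exists() else None
            sessions.append((pdir.name, traj, emg_rec, events))
        if not sessions:
            raise FileNotFoundError(f"analyze: no session directories in {root}")

    if cfg.mode in ("analyze", "full"):
        features_all, summaries_all, latencies_all = [], [], []
        for pid, traj, emg_rec, events in sessions:
            log.info("analyzing %s", pid)
            feats, summ = analyze_session(traj, events, pid, cfg)
            features_all.append(feats)
            summaries_all.append(summ)
            if emg_rec is not None:
                latencies_all.append(_session_latencies(emg_rec, events, pid, cfg))
        features_df = pd.concat(features_all, ignore_index=True)
        summary_df = pd.concat(summaries_all, ignore_index=True)
        latency_df = (
            pd.concat(latencies_all, ignore_index=True) if latencies_all else None
        )
        _write_csv(features_df, out / "features.csv", cfg.seed)
        _write_csv(summary_df, out / "summaries.csv", cfg.seed)
        if latency_df is not None:
            _write_csv(latency_df, out / "latency.csv", cfg.seed)
        manifest["stages"]["features"] = {
            "segments": int(len(features_df)),
            "cells": int(len(summary_df)),
            "latencies": int(len(latency_df)) if latency_df is not None else 0,
        }
        if summary_df["participant"].nunique() >= 2:
            anova_df, posthoc_df = stats_tables(summary_df, latency_df, cfg)
            _write_csv(anova_df, out / "anova.csv", cfg.seed)
            _write_csv(posthoc_df, out / "posthoc.csv", cfg.seed)
            manifest["stages"]["stats"] = {
                "responses": int(anova_df["response"].nunique()),
                "posthoc_rows": int(len(posthoc_df)),
            }
        else:
            log.info("fewer than 2 participants: skipping inference stage")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_echo(cfg: RunConfig) -> Mapping:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, Mapping):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)
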