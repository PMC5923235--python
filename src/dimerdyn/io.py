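"""Readers, writers, configuration and pipeline plumbing.

Package-wide unit conventions: micrometres, seconds, camera counts,
densities in receptors per um^2; converters live at the I/O boundary
only.  Frame indices are 0-based throughout (TrackMate's 0-based frames
pass through unchanged).  Floating-point outputs are serialised with 17
significant digits so that write-then-read round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinetics, mc_sim, synthetic
from .kinetics import MIN_TRACK_LENGTH, TrackTable

__all__ = [
    "parse_track_table",
    "write_track_table",
    "write_trace_csv",
    "read_trace_csv",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("dimerdyn")

FLOAT_FMT = "%.17g"

# TrackMate export aliases -> native column names
_ALIASES = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
    "TOTAL_INTENSITY": "intensity",
    "MEAN_INTENSITY": "intensity",
}
_NATIVE = ("track_id", "frame", "x_um", "y_um")


def parse_track_table(path, dialect: str = "auto",
                      frame_interval: float = kinetics.FRAME_INTERVAL_DEFAULT,
                      min_track_length: int = MIN_TRACK_LENGTH) -> TrackTable:
    """Read a track CSV in native or TrackMate-export dialect.

    Column aliases (TRACK_ID, FRAME, POSITION_X, POSITION_Y) are mapped
    to the native header; tracks shorter than ``min_track_length`` frames
    are dropped with a logged count.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if dialect == "auto":
        if set(_NATIVE) <= cols:
            dialect = "native"
        elif {"TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"} <= cols:
            dialect = "trackmate"
        else:
            raise ValueError(
                f"unrecognised track-table header {sorted(cols)}; accepted "
                "dialects: native (track_id, frame, x_um, y_um[, intensity, "
                "channel]) or trackmate (TRACK_ID, FRAME, POSITION_X, "
                "POSITION_Y)")
    if dialect == "trackmate":
        df = df.rename(columns=_ALIASES)
    missing = [c for c in _NATIVE if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing} "
                         f"for dialect {dialect!r}")
    if "intensity" not in df.columns:
        df["intensity"] = np.nan
    if "channel" not in df.columns:
        df["channel"] = "donor"
    df = df[["track_id", "frame", "x_um", "y_um", "intensity", "channel"]]
    df = df.sort_values(["track_id", "frame"], kind="stable")
    sizes = df.groupby("track_id")["frame"].size()
    short = sizes[sizes < min_track_length].index
    if len(short):
        log.info("dropping %d track(s) shorter than %d frames",
                 len(short), min_track_length)
    df = df[~df["track_id"].isin(short)].reset_index(drop=True)
    return TrackTable(df, frame_interval)


def write_track_table(tracks: TrackTable, path) -> None:
    tracks.data.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trace_csv(trace: mc_sim.SimulationTrace, path) -> None:
    df = pd.DataFrame({
        "time_s": trace.times,
        "n_monomer": trace.monomer_count,
        "n_dimer": trace.dimer_count,
        "n_collisions": trace.collision_events,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace_csv(path) -> mc_sim.SimulationTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return mc_sim.SimulationTrace(
        df["time_s"].to_numpy(), df["n_monomer"].to_numpy(),
        df["n_dimer"].to_numpy(), df["n_collisions"].to_numpy())


def load_config(path) -> dict:
    """Load and minimally validate a YAML pipeline/simulation config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def simulation_config_from_dict(d: dict) -> mc_sim.SimulationConfig:
    known = {f for f in mc_sim.SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return mc_sim.SimulationConfig(**d)


STAGES = ("synth", "kinetics", "simulate")


def run_pipeline(config: dict, stages: Sequence[str], outdir) -> dict:
    """Execute pipeline stages in dependency order; returns a result map.

    Stages: ``synth`` writes synthetic Brownian tracks (tracks.csv plus
    truth JSON); ``kinetics`` estimates D and rate constants from
    tracks.csv and writes rates.json; ``simulate`` runs the particle
    Monte Carlo from the ``simulation`` config section and writes
    trace.csv.  An empty stage list just validates and echoes the
    config.  Outputs include every seed and parameter used, so reruns
    with the same config are bit-identical.
    """
    outdir = Path(outdir)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    results = {"config": config}
    if not stages:
        return results
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    order = [s for s in STAGES if s in stages]
    for stage in order:
        if stage == "synth":
            params = dict(config.get("synth", {}))
            params.setdefault("seed", seed)
            tracks, truth = synthetic.gen_brownian_tracks(**params)
            write_track_table(tracks, outdir / "tracks.csv")
            truth.write_json(outdir / "tracks_truth.json")
            results["synth"] = {"tracks": str(outdir / "tracks.csv")}
        elif stage == "kinetics":
            tracks_path = outdir / "tracks.csv"
            if not tracks_path.exists():
                raise FileNotFoundError(
                    "kinetics stage needs tracks.csv; run the synth stage "
                    "first or place a track table in the output directory")
            kin = dict(config.get("kinetics", {}))
            fi = kin.get("frame_interval", kinetics.FRAME_INTERVAL_DEFAULT)
            tracks = parse_track_table(tracks_path, frame_interval=fi)
            curve = kinetics.msd_curve(tracks,
                                       max_lag=int(kin.get("max_lag", 10)))
            fit = kinetics.fit_diffusion(curve,
                                         n_fit_lags=int(kin.get("n_fit_lags", 4)))
            k_on = kin.get("k_on", 0.081)
            k_off = kin.get("k_off", 0.58)
            rates = kinetics.derive_rate_constants(k_on=k_on, k_off=k_off)
            payload = {
                "seed": seed,
                "D_um2_per_s": fit.D,
                "D_ci95": list(fit.ci95),
                "k_on_um2_per_s": rates.k_on,
                "k_off_per_s": rates.k_off,
                "K_d_per_um2": rates.K_d,
                "t_half_s": rates.t_half,
            }
            with open(outdir / "rates.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            results["kinetics"] = payload
        elif stage == "simulate":
            sim = dict(config.get("simulation", {}))
            sim.setdefault("seed", seed)
            cfg = simulation_config_from_dict(sim)
            trace = mc_sim.run_simulation(cfg)
            write_trace_csv(trace, outdir / "trace.csv")
            frac, se = mc_sim.dimer_fraction(trace)
            results["simulate"] = {
                "trace": str(outdir / "trace.csv"),
                "dimer_receptor_fraction": frac,
                "dimer_receptor_fraction_se": se,
                "seed": cfg.seed,
            }
    with open(outdir / "pipeline_log.json", "w") as fh:
        json.dump({"stages": list(order), "seed": seed, "config": config},
                  fh, indent=2, default=str)
    return results
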