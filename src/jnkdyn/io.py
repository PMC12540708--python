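"""Readers and writers for the pipeline's tabular formats, plus run configs.

Conventions: long (tidy) layouts, UTF-8, mandatory headers; traces are
comma-separated (cell_id, time_h, cn_ratio), gene tables tab-separated.
Every run can drop a JSON metadata sidecar with the exact configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterSet
from .fitting import ExpressionProfile, FitSurface
from .model import ModelParameters, StimulusProgram, Trajectory, make_stimulus
from .traces import CellTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_deg_table",
    "write_deg_table",
    "read_profiles",
    "write_profiles",
    "write_cluster_set",
    "read_cluster_assignments",
    "write_fit_surface",
    "read_fit_surface",
    "write_trajectory",
    "load_config",
    "write_run_metadata",
]

_TRACE_COLS = ("cell_id", "time_h", "cn_ratio")


def _require(frame: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def read_traces(
    path,
    n_baseline_frames: int = 4,
    treatment_time: float = 0.0,
) -> list[CellTrace]:
    """Load per-cell C/N traces from a long CSV (cell_id, time_h, cn_ratio)."""
    frame = pd.read_csv(path)
    _require(frame, _TRACE_COLS, "trace CSV")
    traces = []
    for cell, sub in frame.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_h")
        traces.append(
            CellTrace(
                str(cell),
                sub["time_h"].to_numpy(float),
                sub["cn_ratio"].to_numpy(float),
                n_baseline_frames=n_baseline_frames,
                treatment_time=treatment_time,
            )
        )
    return traces


def write_traces(traces: list[CellTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {"cell_id": tr.cell_id, "time_h": tr.frame_times, "cn_ratio": tr.cn_ratio}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_DEG_COLS = ("gene_id", "biotype", "fdr", "max_group_mean")


def read_deg_table(path) -> pd.DataFrame:
    """Load a DEG table (TSV; one row per gene per condition)."""
    frame = pd.read_csv(path, sep="\t")
    _require(frame, _DEG_COLS, "DEG table")
    if not any(c.startswith("log2fc_") for c in frame.columns):
        raise ValueError("DEG table is missing log2fc_* columns")
    return frame


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_profiles(profiles: pd.DataFrame, condition: str, path) -> None:
    """Write a gene/cluster × timepoint matrix as tidy TSV."""
    long = profiles.stack().rename("scaled_value").reset_index()
    long.columns = ["profile_id", "time_h", "scaled_value"]
    long.insert(0, "condition", condition)
    long.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> dict[str, ExpressionProfile]:
    """Read tidy profiles TSV into :class:`ExpressionProfile` objects."""
    frame = pd.read_csv(path, sep="\t")
    _require(frame, ("condition", "profile_id", "time_h", "scaled_value"), "profile TSV")
    out = {}
    for pid, sub in frame.groupby("profile_id", sort=True):
        sub = sub.sort_values("time_h")
        out[str(pid)] = ExpressionProfile(
            condition=str(sub["condition"].iloc[0]),
            values=tuple(sub["scaled_value"].astype(float)),
            timepoints=tuple(sub["time_h"].astype(float)),
        )
    return out


def write_cluster_set(cs: ClusterSet, path) -> None:
    """Cluster assignments as TSV (gene_id, condition, cluster)."""
    pd.DataFrame(
        {
            "gene_id": cs.assignments.index,
            "condition": cs.condition,
            "cluster": cs.assignments.to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_cluster_assignments(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require(frame, ("gene_id", "condition", "cluster"), "cluster TSV")
    return frame


def write_fit_surface(fs: FitSurface, csv_path, summary_path=None) -> None:
    """RMSE grid as long CSV plus an optional JSON summary sidecar."""
    fs.to_frame().to_csv(csv_path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(fs.summary(), indent=2))


def read_fit_surface(csv_path) -> FitSurface:
    frame = pd.read_csv(csv_path)
    _require(frame, ("alpha_m", "rmse"), "fit surface CSV")
    alpha = np.unique(frame["alpha_m"])
    K = np.unique(frame["K"]) if "K" in frame.columns else None
    delay = np.unique(frame["delay_h"]) if "delay_h" in frame.columns else None
    shape = [alpha.size] + ([K.size] if K is not None else []) + (
        [delay.size] if delay is not None else []
    )
    sort_cols = ["alpha_m"] + (["K"] if K is not None else []) + (
        ["delay_h"] if delay is not None else []
    )
    rmse = frame.sort_values(sort_cols)["rmse"].to_numpy(float).reshape(shape)
    return FitSurface(alpha, rmse, K_grid=K, delay_grid=delay)


def write_trajectory(traj: Trajectory, csv_path, metadata_path=None) -> None:
    """Tidy trajectory CSV (time_h, species, value_Cs) + metadata sidecar."""
    traj.to_frame().to_csv(csv_path, index=False)
    if metadata_path is not None:
        meta = {
            "params": {
                k: getattr(traj.params, k)
                for k in ModelParameters.__dataclass_fields__
            },
            "stimulus": {
                "label": traj.stimulus.label,
                "on_intervals": [list(iv) for iv in traj.stimulus.on_intervals],
            },
            "variant": traj.variant,
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def load_config(path) -> dict:
    """Load a YAML run config, validating parameter symbols and stimulus.

    Recognised keys: params (symbol → value overrides), stimulus (label or
    list of [start, end] on-intervals), variant, t_end, dt_out, seed.
    Unknown parameter symbols are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"params", "stimulus", "variant", "t_end", "dt_out", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {
        "params": ModelParameters().with_(**(raw.get("params") or {})),
        "variant": raw.get("variant", "mass_action"),
        "t_end": float(raw.get("t_end", 8.0)),
        "dt_out": float(raw.get("dt_out", 0.05)),
        "seed": int(raw.get("seed", 0)),
    }
    stim = raw.get("stimulus", "sustained")
    if isinstance(stim, str):
        cfg["stimulus"] = make_stimulus(stim)
    else:
        cfg["stimulus"] = StimulusProgram(
            tuple((float(a), float(b)) for a, b in stim), label="custom"
        )
    return cfg


def write_run_metadata(path, **fields) -> None:
    """JSON sidecar recording the exact settings of a pipeline run."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(fields, indent=2, default=default))
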