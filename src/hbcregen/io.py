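"""Readers and writers for the package's plain-text interchange formats.

CSV for tabular data (EdU time courses, trajectories, ratio cohorts),
YAML or JSON for parameter sets, JSON for moment summaries and
ground-truth sidecars, multi-page TIFF for z-stacks.  Every writer's
output round-trips losslessly through its paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .partition import MomentSummary, PartitionParams, RatioCohort
from .quantify import ZStack
from .regeneration import CellCycleParams, OETrajectory

__all__ = [
    "read_edu_timecourse", "write_edu_timecourse",
    "read_trajectory", "write_trajectory",
    "read_cell_cycle_params", "write_cell_cycle_params",
    "read_partition_params", "write_partition_params",
    "read_cohort", "write_cohort",
    "read_moment_summary", "write_moment_summary",
    "read_zstack", "write_zstack",
    "write_json_sidecar",
]

_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def read_edu_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not ({"day", "fraction"} <= cols or {"day", "n_cells", "n_positive"} <= cols):
        raise ValueError(
            f"{path}: expected columns day,n_cells,n_positive or day,fraction"
        )
    return df


def write_edu_timecourse(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> OETrajectory:
    df = pd.read_csv(path)
    missing = {"t", "H1", "H2", "H3", "D"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {sorted(missing)}")
    return OETrajectory(df["t"].to_numpy(), df[["H1", "H2", "H3", "D"]].to_numpy())


def write_trajectory(traj: OETrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    # fall back on YAML, a superset of JSON
    return yaml.safe_load(text)


def _write_mapping(d: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_cell_cycle_params(path) -> CellCycleParams:
    return CellCycleParams.from_dict(_read_mapping(path))


def write_cell_cycle_params(params: CellCycleParams, path) -> None:
    _write_mapping(params.to_dict(), path)


def read_partition_params(path) -> PartitionParams:
    d = _read_mapping(path)
    return PartitionParams(ps=float(d["ps"]), sigma=float(d["sigma"]), pb=float(d["pb"]))


def write_partition_params(params: PartitionParams, path) -> None:
    _write_mapping(params.to_dict(), path)


def read_cohort(path) -> RatioCohort:
    """Read a cohort CSV: either cell_id,x1,x2[,mode] or cell_id,ratio."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"x1", "x2"} <= cols:
        ratios = (np.maximum(df["x1"], df["x2"]) / np.minimum(df["x1"], df["x2"])).to_numpy()
        modes = df["mode"].to_numpy() if "mode" in cols else None
        return RatioCohort(ratios, modes)
    if "ratio" in cols:
        modes = df["mode"].to_numpy() if "mode" in cols else None
        return RatioCohort(df["ratio"].to_numpy(), modes)
    raise ValueError(f"{path}: expected columns cell_id,x1,x2[,mode] or cell_id,ratio")


def write_cohort(cohort: RatioCohort, path) -> None:
    df = pd.DataFrame({"cell_id": np.arange(cohort.n), "ratio": cohort.ratios})
    if cohort.modes is not None:
        df["mode"] = cohort.modes
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_moment_summary(path) -> MomentSummary:
    d = json.loads(Path(path).read_text())
    return MomentSummary(
        mean=d["mean"], cv=d["cv"], skewness=d["skewness"], n=d["n"],
        ci_mean=tuple(d["ci_mean"]) if "ci_mean" in d else None,
        ci_cv=tuple(d["ci_cv"]) if "ci_cv" in d else None,
        ci_skew=tuple(d["ci_skew"]) if "ci_skew" in d else None,
    )


def write_moment_summary(summary: MomentSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def read_zstack(path, background: float = 0.0) -> ZStack:
    """Read a multi-page TIFF (or .npy array) as a z-stack."""
    path = Path(path)
    if path.suffix == ".npy":
        voxels = np.load(path)
    else:
        import tifffile

        voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ZStack(voxels=np.asarray(voxels, dtype=float), background=background)


def write_zstack(stack: ZStack, path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack.voxels)
    else:
        import tifffile

        tifffile.imwrite(path, stack.voxels.astype(np.float32),
                         photometric="minisblack")


def write_json_sidecar(record: dict, path) -> None:
    """Write a ground-truth/manifest sidecar, coercing numpy types."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(record, indent=2, default=default) + "\n")
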