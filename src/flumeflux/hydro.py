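"""Node- and flume-level flow statistics from velocimetry grids.

A flume's flow field is mapped with an acoustic Doppler velocimeter on a
regular grid; each node carries a time series of the three velocity
components (u, v, w) in cm/s and a water depth in cm.  Per node we report
the time-mean length of the 3-D velocity vector (``R_xyz``), turbulent
kinetic energy (``TKE``) and turbulence intensity (``TI``).  The spatial
standard deviation of the node means, ``SD_Rxyz``, is the flume-level
measure of flow heterogeneity used throughout the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlowField",
    "NodeStats",
    "FlumeHydroSummary",
    "summarize_node",
    "flume_summary",
    "read_flow_field",
    "write_flow_field",
]


@dataclass
class FlowField:
    """Velocity time series at grid nodes for one flume.

    Parameters
    ----------
    node_ids : array of node identifiers, shape (n_nodes,)
    xy : node coordinates in cm, shape (n_nodes, 2)
    depth : water depth at each node in cm, shape (n_nodes,)
    velocities : instantaneous (u, v, w) in cm/s, shape (n_nodes, n_t, 3)
    """

    node_ids: np.ndarray
    xy: np.ndarray
    depth: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.velocities.ndim != 3 or self.velocities.shape[2] != 3:
            raise ValueError("velocities must have shape (n_nodes, n_t, 3)")
        if self.velocities.shape[1] < 2:
            raise ValueError("need at least 2 time steps per node")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.velocities.shape[0]


@dataclass(frozen=True)
class NodeStats:
    """Summary statistics for one grid node."""

    r_xyz: float  # time-mean 3-D speed, cm/s
    tke: float  # turbulent kinetic energy, cm^2/s^2
    ti: float  # turbulence intensity (RMS fluctuation / mean speed); NaN if undefined
    depth: float  # cm
    ti_undefined: bool = field(default=False)


@dataclass(frozen=True)
class FlumeHydroSummary:
    """Flume-level hydraulic summary."""

    mean_rxyz: float  # cm/s
    sd_rxyz: float  # spatial SD of node-mean speed, cm/s (sample SD)
    mean_depth: float  # cm
    residence_time_min: float  # min; NaN if mean velocity is zero


def summarize_node(series: np.ndarray, depth: float) -> NodeStats:
    """Summarize one node's (u, v, w) time series.

    ``R_xyz`` is the time mean of the instantaneous 3-D speed
    sqrt(u^2 + v^2 + w^2).  ``TKE = (var(u) + var(v) + var(w)) / 2`` with
    population variances (long, stationary time series).  ``TI`` is the RMS
    velocity fluctuation sqrt((var(u)+var(v)+var(w)) / 3) divided by R_xyz;
    when R_xyz is zero with nonzero fluctuation TI is undefined and returned
    as NaN with ``ti_undefined`` set, never silently infinite.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("series must have shape (n_t, 3)")
    if series.shape[0] < 2:
        raise ValueError("need at least 2 time steps")
    speeds = np.linalg.norm(series, axis=1)
    r_xyz = float(speeds.mean())
    var_sum = float(series.var(axis=0, ddof=0).sum())
    tke = 0.5 * var_sum
    rms = np.sqrt(var_sum / 3.0)
    if r_xyz > 0:
        ti = rms / r_xyz
        undefined = False
    elif rms == 0.0:
        ti = 0.0
        undefined = False
    else:
        ti = float("nan")
        undefined = True
    return NodeStats(r_xyz=r_xyz, tke=tke, ti=ti, depth=float(depth), ti_undefined=undefined)


def flume_summary(field: FlowField, flume_length_m: float = 40.0) -> FlumeHydroSummary:
    """Flume-level summary from all node statistics.

    ``SD_Rxyz`` is the sample (n-1) standard deviation of the node-mean
    speeds — node means, not pooled instantaneous samples, enter the spatial
    SD.  Residence time is flume length over mean velocity, reported in
    minutes (NaN when the mean velocity is zero).
    """
    if field.n_nodes < 2:
        raise ValueError("need at least 2 nodes for a spatial summary")
    stats = [summarize_node(field.velocities[i], field.depth[i]) for i in range(field.n_nodes)]
    r = np.array([s.r_xyz for s in stats])
    mean_r = float(r.mean())
    sd_r = float(r.std(ddof=1))
    mean_depth = float(field.depth.mean())
    if mean_r > 0:
        rt = residence_time_min(flume_length_m, mean_r)
    else:
        rt = float("nan")
    return FlumeHydroSummary(mean_rxyz=mean_r, sd_rxyz=sd_r, mean_depth=mean_depth,
                             residence_time_min=rt)


def residence_time_min(flume_length_m: float, mean_velocity_cm_s: float) -> float:
    """Hydraulic residence time in minutes from length (m) and velocity (cm/s)."""
    if mean_velocity_cm_s <= 0:
        raise ValueError("mean velocity must be positive")
    return flume_length_m * 100.0 / mean_velocity_cm_s / 60.0


# -- CSV interchange (long format: node_id,x_cm,y_cm,depth_cm,t_index,u,v,w) --

def write_flow_field(field: FlowField, path) -> None:
    n_nodes, n_t, _ = field.velocities.shape
    rows = {
        "node_id": np.repeat(field.node_ids, n_t),
        "x_cm": np.repeat(field.xy[:, 0], n_t),
        "y_cm": np.repeat(field.xy[:, 1], n_t),
        "depth_cm": np.repeat(field.depth, n_t),
        "t_index": np.tile(np.arange(n_t), n_nodes),
        "u": field.velocities[:, :, 0].ravel(),
        "v": field.velocities[:, :, 1].ravel(),
        "w": field.velocities[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flow_field(path) -> FlowField:
    df = pd.read_csv(path)
    df = df.sort_values(["node_id", "t_index"])
    ids = df["node_id"].unique()
    n_t = df["t_index"].nunique()
    vel = df[["u", "v", "w"]].to_numpy().reshape(len(ids), n_t, 3)
    per_node = df.drop_duplicates("node_id").set_index("node_id").loc[ids]
    return FlowField(
        node_ids=np.asarray(ids),
        xy=per_node[["x_cm", "y_cm"]].to_numpy(),
        depth=per_node["depth_cm"].to_numpy(),
        velocities=vel,
    )
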