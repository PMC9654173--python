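"""Per-chain characterizations over a snapshot window: topography height,
root-mean-square fluctuation, and hydration-shell water counting.

Height uses the three marker carbons per chain: per frame,
``h1 = z(C_TR, R0) - z(C_TR, R3)`` and ``h2 = z(C_IN, R1) - z(C_TR, R3)``;
negative values clamp to zero and the frame height is ``max(h1, h2)``; the
chain height is the mean over the window.

RMSF is measured in the lab frame (chains are grafted, so no superposition)
for every non-anchored side-group atom, then averaged per chain.

Hydration counts water hydrogens within a cutoff (default 3 A, minimum
image) of the chain's ester/sulfonate oxygens; a hydrogen near several
oxygens of the same chain counts once for that chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ROLE_ESTER_O,
    ROLE_MARKER_R0,
    ROLE_MARKER_R1,
    ROLE_MARKER_R3,
    ROLE_SULFONATE_O,
    ROLE_WATER_H,
    BrushTopology,
    Trajectory,
    Window,
    resolve_window,
)
from .trajectory_io import pairwise_min_image_distances

HYDRATION_CUTOFF = 3.0

METRICS = ("height", "rmsf", "hydration")


@dataclass
class ChainProfile:
    """One scalar per chain for one metric over one frame window."""

    metric: str
    chain_ids: np.ndarray
    values: np.ndarray
    window: Window
    per_group: pd.DataFrame | None = None  # optional per-side-group breakdown

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if len(self.chain_ids) != len(self.values):
            raise ValueError("one value per chain required")

    def as_frame(self, grid=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chain_id": self.chain_ids, "metric": self.metric, "value": self.values}
        )
        if grid is not None:
            ij = {cid: (i, j) for cid, i, j in grid.lattice_coords()}
            df["grid_i"] = [ij[c][0] for c in self.chain_ids]
            df["grid_j"] = [ij[c][1] for c in self.chain_ids]
        df["window_start"] = self.window.start
        df["window_stop"] = self.window.stop
        return df

    def value_for(self, chain_id: int) -> float:
        idx = np.flatnonzero(self.chain_ids == chain_id)
        if len(idx) != 1:
            raise KeyError(chain_id)
        return float(self.values[idx[0]])


# ---------------------------------------------------------------------------
# Height
# ---------------------------------------------------------------------------


def chain_height_series(
    traj: Trajectory,
    topology: BrushTopology,
    chain_id: int,
    window: Window | tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-frame brush height of one chain over the window."""
    win = resolve_window(traj, window)
    try:
        i_r0 = topology.marker_index(chain_id, ROLE_MARKER_R0)
        i_r1 = topology.marker_index(chain_id, ROLE_MARKER_R1)
        i_r3 = topology.marker_index(chain_id, ROLE_MARKER_R3)
    except ValueError as exc:
        raise ValueError(f"chain {chain_id}: missing marker atom ({exc})") from exc
    z = traj.coords[win.start:win.stop, :, 2]
    h1 = np.clip(z[:, i_r0] - z[:, i_r3], 0.0, None)
    h2 = np.clip(z[:, i_r1] - z[:, i_r3], 0.0, None)
    return np.maximum(h1, h2)


def chain_height(
    traj: Trajectory,
    topology: BrushTopology,
    chain_id: int,
    window: Window | tuple[int, int] | None = None,
) -> float:
    """Window-mean brush height (A) of one chain."""
    return float(chain_height_series(traj, topology, chain_id, window).mean())


def _annotated_chain_ids(topology: BrushTopology) -> np.ndarray:
    cids = topology.chain_ids()
    if len(cids) == 0:
        raise ValueError(
            "no polymer chains annotated in topology (chain 0: missing "
            "marker roles; is the annotation sidecar present?)"
        )
    return cids


def height_profile(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
) -> ChainProfile:
    win = resolve_window(traj, window)
    cids = _annotated_chain_ids(topology)
    values = np.array(
        [chain_height(traj, topology, int(c), win) for c in cids]
    )
    return ChainProfile("height", cids, values, win)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


def chain_rmsf(
    traj: Trajectory,
    topology: BrushTopology,
    chain_id: int,
    window: Window | tuple[int, int] | None = None,
) -> float:
    """Mean over the chain's non-anchored side-group atoms of each atom's RMS
    displacement from its window-mean position."""
    win = resolve_window(traj, window)
    if win.n_frames < 2:
        raise ValueError(
            f"RMSF requires a window of >= 2 frames, got {win.n_frames}"
        )
    mask = (
        (topology.atoms["chain_id"] == chain_id)
        & (topology.atoms["group_id"] >= 0)
        & ~topology.atoms["anchored"]
    ).to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"chain {chain_id}: no side-group atoms")
    xyz = traj.coords[win.start:win.stop, idx, :]
    mean_pos = xyz.mean(axis=0)
    sq = ((xyz - mean_pos) ** 2).sum(axis=2)  # (frames, atoms)
    per_atom = np.sqrt(sq.mean(axis=0))
    return float(per_atom.mean())


def rmsf_profile(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
) -> ChainProfile:
    win = resolve_window(traj, window)
    cids = _annotated_chain_ids(topology)
    values = np.array([chain_rmsf(traj, topology, int(c), win) for c in cids])
    return ChainProfile("rmsf", cids, values, win)


# ---------------------------------------------------------------------------
# Hydration
# ---------------------------------------------------------------------------


def chain_hydration(
    traj: Trajectory,
    topology: BrushTopology,
    chain_id: int,
    window: Window | tuple[int, int] | None = None,
    cutoff: float = HYDRATION_CUTOFF,
    box: tuple[float, float, float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Window-mean count of water hydrogens within ``cutoff`` of the chain's
    ester/sulfonate oxygens (minimum image, inclusive boundary).

    Returns (mean count, per-group breakdown DataFrame).  A hydrogen within
    the shell of several oxygens counts once per chain (and once per group in
    the breakdown).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    win = resolve_window(traj, window)
    water_h = topology.role_indices(ROLE_WATER_H)
    if len(water_h) == 0:
        raise ValueError(
            "topology contains no water hydrogens; hydration is undefined"
        )
    atoms = topology.atoms
    oxy_mask = (
        (atoms["chain_id"] == chain_id)
        & atoms["role"].isin([ROLE_ESTER_O, ROLE_SULFONATE_O])
    ).to_numpy()
    oxy = np.flatnonzero(oxy_mask)
    if len(oxy) == 0:
        raise ValueError(f"chain {chain_id}: no ester/sulfonate oxygens")
    groups = atoms["group_id"].to_numpy()[oxy]
    if box is None:
        box = topology.box

    per_frame = np.empty(win.n_frames, dtype=float)
    group_ids = np.unique(groups)
    per_group_frames = np.zeros((win.n_frames, len(group_ids)), dtype=float)
    for k, f in enumerate(win.frames()):
        d = pairwise_min_image_distances(
            traj.coords[f, water_h], traj.coords[f, oxy], box
        )
        within = d <= cutoff
        per_frame[k] = np.count_nonzero(within.any(axis=1))
        for gi, g in enumerate(group_ids):
            per_group_frames[k, gi] = np.count_nonzero(
                within[:, groups == g].any(axis=1)
            )
    breakdown = pd.DataFrame(
        {
            "group_id": group_ids,
            "mean_count": per_group_frames.mean(axis=0),
        }
    )
    return float(per_frame.mean()), breakdown


def hydration_profile(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
    cutoff: float = HYDRATION_CUTOFF,
) -> ChainProfile:
    win = resolve_window(traj, window)
    cids = _annotated_chain_ids(topology)
    values = []
    breakdowns = []
    for c in cids:
        v, b = chain_hydration(traj, topology, int(c), win, cutoff)
        values.append(v)
        b = b.assign(chain_id=int(c))
        breakdowns.append(b)
    per_group = pd.concat(breakdowns, ignore_index=True)
    return ChainProfile("hydration", cids, np.array(values), win, per_group)


def compute_profile(
    metric: str,
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
    **kwargs,
) -> ChainProfile:
    """Dispatch by metric name: height, rmsf or hydration."""
    if metric == "height":
        return height_profile(traj, topology, window)
    if metric == "rmsf":
        return rmsf_profile(traj, topology, window)
    if metric == "hydration":
        return hydration_profile(traj, topology, window, **kwargs)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
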