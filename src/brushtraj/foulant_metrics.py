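"""Foulant trajectory characterization: vertical detachment series,
component RMSD with optimal superposition, and mechanism classification.

The detachment height of frame t is the lowest foulant CA z in that frame
minus the lowest foulant CA z in the reference frame: positive = receding
from the surface, negative = penetration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    FOULANT_ROLES,
    POLYMER_ROLES,
    ROLE_FOULANT_CA,
    BrushTopology,
    Trajectory,
    Window,
    resolve_window,
)

COMPONENTS = ("foulant", "polymer", "combined")

#: Default mechanism thresholds (A); the terminal statistic is the mean
#: height over the last tenth of the window.
DETACH_THRESHOLD = 10.0
PENETRATE_THRESHOLD = 5.0
TERMINAL_FRACTION = 0.1


@dataclass
class HeightSeries:
    """Per-frame foulant height change relative to the reference frame."""

    heights: np.ndarray
    lowest_ca_z: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if abs(self.heights[self.reference_frame]) > 1e-12:
            raise ValueError("height at the reference frame must be zero")
        if len(self.heights) != len(self.lowest_ca_z):
            raise ValueError("series length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.heights)

    def terminal_mean(self, fraction: float = TERMINAL_FRACTION) -> float:
        n = max(1, int(round(self.n_frames * fraction)))
        return float(self.heights[-n:].mean())


@dataclass(frozen=True)
class MechanismCall:
    label: str  # detached | anchored | penetrated
    terminal_mean_height: float
    detach_threshold: float
    penetrate_threshold: float
    max_contact_percent: float


def detachment_height(
    traj: Trajectory,
    topology: BrushTopology,
    reference_frame: int = 0,
) -> HeightSeries:
    """Lowest-CA height series relative to ``reference_frame``."""
    ca = topology.role_indices(ROLE_FOULANT_CA)
    if len(ca) == 0:
        raise ValueError("topology contains no foulant CA atoms")
    lowest = traj.coords[:, ca, 2].min(axis=1)
    return HeightSeries(
        heights=lowest - lowest[reference_frame],
        lowest_ca_z=lowest,
        reference_frame=reference_frame,
    )


# ---------------------------------------------------------------------------
# Component RMSD (Kabsch superposition)
# ---------------------------------------------------------------------------


def _component_indices(topology: BrushTopology, component: str) -> np.ndarray:
    if component == "foulant":
        idx = topology.role_indices(*FOULANT_ROLES)
    elif component == "polymer":
        idx = topology.role_indices(*POLYMER_ROLES)
    elif component == "combined":
        idx = topology.role_indices(*FOULANT_ROLES, *POLYMER_ROLES)
    else:
        raise ValueError(
            f"unknown component {component!r}; expected one of {COMPONENTS}"
        )
    if len(idx) == 0:
        raise ValueError(f"component {component!r} selects no atoms")
    return idx


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (rotation + translation).

    Uses the SVD-based optimal rotation; degenerate (<3 atoms or collinear)
    sets are rejected because the rotation is then underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shapes")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(
            f"superposition needs >= 3 atoms, got {n}"
        )
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("superposition degenerate: reference atoms collinear")
    mob_c = mobile - mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    resid = rot.apply(mob_c) - ref_c
    return float(np.sqrt((resid**2).sum() / n))


def component_rmsd(
    traj: Trajectory,
    topology: BrushTopology,
    component: str = "combined",
    reference_frame: int = 0,
    window: Window | tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD of one component onto the reference frame after
    per-component optimal superposition."""
    if traj.n_frames < 2:
        raise ValueError("component RMSD requires at least 2 frames")
    win = resolve_window(traj, window)
    idx = _component_indices(topology, component)
    ref = traj.coords[reference_frame, idx, :]
    out = np.empty(win.n_frames, dtype=float)
    for k, f in enumerate(win.frames()):
        out[k] = superposed_rmsd(traj.coords[f, idx, :], ref)
    return out


def convergence_flags(
    rmsd_series: np.ndarray,
    frame_interval_ps: float,
    rolling_ns: float = 20.0,
    tol_fraction: float = 0.05,
) -> np.ndarray:
    """Boolean per-frame flags: True once the rolling-ns mean RMSD changes by
    less than ``tol_fraction`` relative to the previous rolling mean.
    Advisory only."""
    n_roll = max(2, int(round(rolling_ns * 1000.0 / frame_interval_ps)))
    n = len(rmsd_series)
    flags = np.zeros(n, dtype=bool)
    prev = None
    for i in range(n):
        lo = max(0, i - n_roll + 1)
        cur = rmsd_series[lo : i + 1].mean()
        if prev is not None and abs(cur - prev) <= tol_fraction * max(abs(prev), 1e-12):
            flags[i] = True
        prev = cur
    return flags


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------


def classify_mechanism(
    series: HeightSeries,
    contacts=None,
    detach_threshold: float = DETACH_THRESHOLD,
    penetrate_threshold: float = PENETRATE_THRESHOLD,
    terminal_fraction: float = TERMINAL_FRACTION,
    occurrence_floor: float = 5.0,
) -> MechanismCall:
    """Label a trajectory detached / anchored / penetrated.

    Terminal mean height above ``detach_threshold`` => detached; below
    ``-penetrate_threshold`` => penetrated; otherwise anchored when any
    foulant-polymer contact clears the occurrence floor, else detached.
    ``contacts`` is an interactions.OccurrenceTable (or None for no
    contacts).
    """
    if series.n_frames == 0:
        raise ValueError("empty height series")
    terminal = series.terminal_mean(terminal_fraction)
    max_pct = 0.0
    if contacts is not None and len(contacts.data) > 0:
        max_pct = float(contacts.data["percent"].max())
    if terminal > detach_threshold:
        label = "detached"
    elif terminal < -penetrate_threshold:
        label = "penetrated"
    elif max_pct >= occurrence_floor:
        label = "anchored"
    else:
        label = "detached"
    return MechanismCall(
        label=label,
        terminal_mean_height=terminal,
        detach_threshold=detach_threshold,
        penetrate_threshold=penetrate_threshold,
        max_contact_percent=max_pct,
    )
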