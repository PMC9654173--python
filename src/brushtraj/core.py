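"""Core data structures shared by every analysis stage.

A :class:`BrushTopology` is an annotated atom table (roles, chain/group
membership, anchoring flags) together with the grafting grid and the periodic
box.  A :class:`Trajectory` is an ordered stack of coordinate frames aligned
to that atom table.  All coordinates are in angstroms, times in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Atom roles
# ---------------------------------------------------------------------------

ROLE_BACKBONE = "polymer_backbone"
ROLE_MARKER_R0 = "marker_CTR_R0"
ROLE_MARKER_R1 = "marker_CIN_R1"
ROLE_MARKER_R3 = "marker_CTR_R3"
ROLE_ESTER_O = "ester_O"
ROLE_SULFONATE_O = "sulfonate_O"
ROLE_AMMONIUM_N = "ammonium_N"
ROLE_WATER_O = "water_O"
ROLE_WATER_H = "water_H"
ROLE_FOULANT_CA = "foulant_CA"
ROLE_FOULANT_NEG = "foulant_neg_atom"
ROLE_FOULANT_POS = "foulant_pos_atom"
ROLE_FOULANT_POLAR_H = "foulant_polar_H"
ROLE_OTHER = "other"

ROLES: tuple[str, ...] = (
    ROLE_BACKBONE,
    ROLE_MARKER_R0,
    ROLE_MARKER_R1,
    ROLE_MARKER_R3,
    ROLE_ESTER_O,
    ROLE_SULFONATE_O,
    ROLE_AMMONIUM_N,
    ROLE_WATER_O,
    ROLE_WATER_H,
    ROLE_FOULANT_CA,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POS,
    ROLE_FOULANT_POLAR_H,
    ROLE_OTHER,
)

MARKER_ROLES: tuple[str, ...] = (ROLE_MARKER_R0, ROLE_MARKER_R1, ROLE_MARKER_R3)

#: Roles that belong to grafted polymer chains.
POLYMER_ROLES: tuple[str, ...] = (
    ROLE_BACKBONE,
    ROLE_MARKER_R0,
    ROLE_MARKER_R1,
    ROLE_MARKER_R3,
    ROLE_ESTER_O,
    ROLE_SULFONATE_O,
    ROLE_AMMONIUM_N,
)

#: Roles that belong to the foulant.
FOULANT_ROLES: tuple[str, ...] = (
    ROLE_FOULANT_CA,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POS,
    ROLE_FOULANT_POLAR_H,
)

#: Formal charge sign per role (+1 / -1); roles absent here are neutral.
CHARGE_BY_ROLE: dict[str, int] = {
    ROLE_AMMONIUM_N: +1,
    ROLE_SULFONATE_O: -1,
    ROLE_FOULANT_POS: +1,
    ROLE_FOULANT_NEG: -1,
}

#: Hydrogen-bond donor hydrogens and acceptor oxygens.
DONOR_ROLES: tuple[str, ...] = (ROLE_FOULANT_POLAR_H,)
ACCEPTOR_ROLES: tuple[str, ...] = (ROLE_ESTER_O, ROLE_SULFONATE_O)

ATOM_COLUMNS: tuple[str, ...] = (
    "serial",
    "name",
    "element",
    "resname",
    "resseq",
    "role",
    "chain_id",
    "group_id",
    "anchored",
    "x",
    "y",
    "z",
)


def empty_atom_table() -> pd.DataFrame:
    """Return an empty atom table with the canonical column layout."""
    return pd.DataFrame(
        {
            "serial": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "element": pd.Series(dtype=str),
            "resname": pd.Series(dtype=str),
            "resseq": pd.Series(dtype=np.int64),
            "role": pd.Series(dtype=str),
            "chain_id": pd.Series(dtype=np.int64),
            "group_id": pd.Series(dtype=np.int64),
            "anchored": pd.Series(dtype=bool),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "z": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Grafting grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraftingGrid:
    """Rectangular lattice of grafting points in the xy plane.

    The periodic box is ``n * spacing`` along each axis so the lattice tiles
    seamlessly under periodic boundary conditions.
    """

    spacing_x: float
    spacing_y: float
    n_x: int
    n_y: int
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError(f"grid spacing must be positive, got "
                             f"({self.spacing_x}, {self.spacing_y})")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError(f"grid counts must be >= 1, got ({self.n_x}, {self.n_y})")

    @property
    def box_x(self) -> float:
        return self.n_x * self.spacing_x

    @property
    def box_y(self) -> float:
        return self.n_y * self.spacing_y

    @property
    def n_chains(self) -> int:
        return self.n_x * self.n_y

    def points(self) -> np.ndarray:
        """(n_chains, 2) grafting-point coordinates, x-major order."""
        ox, oy = self.origin
        xs = ox + self.spacing_x * np.arange(self.n_x)
        ys = oy + self.spacing_y * np.arange(self.n_y)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def chain_index(self, i: int, j: int) -> int:
        """Chain id at lattice coordinate (i, j), x-major order."""
        return i * self.n_y + j

    def lattice_coords(self) -> Iterator[tuple[int, int, int]]:
        """Yield (chain_id, i, j) triples in chain-id order."""
        for i in range(self.n_x):
            for j in range(self.n_y):
                yield self.chain_index(i, j), i, j

    @property
    def center(self) -> tuple[float, float]:
        ox, oy = self.origin
        return (
            ox + self.spacing_x * (self.n_x - 1) / 2.0,
            oy + self.spacing_y * (self.n_y - 1) / 2.0,
        )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class BrushTopology:
    """Annotated atom table plus grid and box metadata.

    ``atoms`` carries reference (frame-0 construction) coordinates; analysis
    modules read coordinates from a :class:`Trajectory` aligned to this table.
    """

    atoms: pd.DataFrame
    grid: GraftingGrid | None = None
    box: tuple[float, float, float] = (0.0, 0.0, 0.0)
    foulant_orientation: str | None = None
    foulant_charge_ratio: tuple[float, float] | None = None

    # -- basic accessors ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords0(self) -> np.ndarray:
        """Reference coordinates, shape (n_atoms, 3)."""
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def chain_ids(self) -> np.ndarray:
        cids = self.atoms.loc[self.atoms["chain_id"] >= 0, "chain_id"].unique()
        return np.sort(cids)

    def role_indices(self, *roles: str) -> np.ndarray:
        """0-based row indices of atoms having any of the given roles."""
        return np.flatnonzero(self.atoms["role"].isin(roles).to_numpy())

    def chain_indices(self, chain_id: int, *roles: str) -> np.ndarray:
        mask = (self.atoms["chain_id"] == chain_id).to_numpy()
        if roles:
            mask &= self.atoms["role"].isin(roles).to_numpy()
        return np.flatnonzero(mask)

    def marker_index(self, chain_id: int, role: str) -> int:
        """Row index of the unique marker atom of ``role`` on ``chain_id``."""
        idx = self.chain_indices(chain_id, role)
        if len(idx) != 1:
            raise ValueError(
                f"chain {chain_id}: expected exactly one {role} marker, "
                f"found {len(idx)}"
            )
        return int(idx[0])

    def anchored_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atoms["anchored"].to_numpy())

    def has_waters(self) -> bool:
        return bool(self.atoms["role"].isin([ROLE_WATER_O, ROLE_WATER_H]).any())

    def has_foulant(self) -> bool:
        return bool(self.atoms["role"].isin(FOULANT_ROLES).any())

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        atoms = self.atoms
        missing = set(ATOM_COLUMNS) - set(atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        unknown = set(atoms["role"].unique()) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}")
        if atoms["serial"].duplicated().any():
            raise ValueError("duplicate atom serial numbers")
        for cid in self.chain_ids():
            for role in MARKER_ROLES:
                n = len(self.chain_indices(cid, role))
                if n != 1:
                    raise ValueError(
                        f"chain {cid}: expected exactly one {role}, found {n}"
                    )
            n_sulf = len(self.chain_indices(cid, ROLE_SULFONATE_O))
            if n_sulf % 3 != 0:
                raise ValueError(
                    f"chain {cid}: sulfonate oxygen count {n_sulf} "
                    "not divisible by 3"
                )


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

DEFAULT_FRAME_INTERVAL_PS = 10.0


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    Periodic in x and y (solvent tiles laterally); aperiodic in z (solvent
    above, grafting plane below).
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval_ps <= 0:
            raise ValueError(f"frame interval must be positive, "
                             f"got {self.frame_interval_ps}")
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_interval_ps / 1000.0

    def times_ps(self) -> np.ndarray:
        return self.frame_interval_ps * np.arange(self.n_frames)


# ---------------------------------------------------------------------------
# Frame windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Half-open frame-index window [start, stop)."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.stop <= self.start:
            raise ValueError(f"invalid window [{self.start}, {self.stop})")

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


def resolve_window(traj: Trajectory, window: Window | tuple[int, int] | None) -> Window:
    """Normalize a window argument against a trajectory's frame count."""
    if window is None:
        return Window(0, traj.n_frames)
    if isinstance(window, tuple):
        window = Window(*window)
    if window.stop > traj.n_frames:
        raise ValueError(
            f"window [{window.start}, {window.stop}) exceeds trajectory "
            f"of {traj.n_frames} frames"
        )
    return window
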