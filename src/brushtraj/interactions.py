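"""Occurrence statistics for foulant-polymer electrostatic contacts,
hydrogen bonds, and polymer inter-chain salt bridges.

A pair is in contact in a frame when its minimum-image distance is within
the cutoff (inclusive) and, for electrostatics, the two atoms carry opposite
formal charge.  Occurrence percent = 100 * frames-in-contact / window
frames.  Rows under the neglect floor (default 5%, strict-less) are dropped
by :func:`apply_neglect_floor`; the raw table always keeps them.

Cutoffs: 4.0 A electrostatic, 2.4 A hydrogen bond (distance-only; an
optional donor-H...acceptor angle filter exists but defaults off).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    CHARGE_BY_ROLE,
    ROLE_AMMONIUM_N,
    ROLE_ESTER_O,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POLAR_H,
    ROLE_FOULANT_POS,
    ROLE_SULFONATE_O,
    BrushTopology,
    Trajectory,
    Window,
    resolve_window,
)
from .trajectory_io import pairwise_min_image_distances

ELECTROSTATIC_CUTOFF = 4.0
HBOND_CUTOFF = 2.4
NEGLECT_FLOOR_PERCENT = 5.0

TABLE_COLUMNS = (
    "atom_serial",
    "residue",
    "residue_id",
    "partner_serial",
    "partner_role",
    "chain_id",
    "type",
    "frames",
    "percent",
)


@dataclass
class OccurrenceTable:
    """Interaction pairs with their % occurrence over an analysis window."""

    data: pd.DataFrame
    interaction: str  # electrostatic | hbond | interchain_electrostatic
    n_frames: int
    cutoff: float
    mean_contacts_per_chain: float | None = None

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")
        pct = self.data["percent"]
        if len(pct) and (pct.min() < 0 or pct.max() > 100):
            raise ValueError("occurrence percent outside [0, 100]")

    def __len__(self) -> int:
        return len(self.data)

    def by_residue(self) -> pd.DataFrame:
        """Residue-level aggregation: max percent over the residue's atom
        pairs, for reporting contact residues."""
        if len(self.data) == 0:
            return self.data.copy()
        return (
            self.data.groupby(["residue", "residue_id"], as_index=False)
            .agg(percent=("percent", "max"), n_pairs=("percent", "size"))
            .sort_values("percent", ascending=False, ignore_index=True)
        )


def _occurrence_table(
    traj: Trajectory,
    topology: BrushTopology,
    win: Window,
    left_idx: np.ndarray,
    right_idx: np.ndarray,
    pair_ok: np.ndarray,
    cutoff: float,
    interaction: str,
    normalize_chains: bool,
) -> OccurrenceTable:
    """Count in-contact frames for every admissible (left, right) pair."""
    atoms = topology.atoms
    n_l, n_r = len(left_idx), len(right_idx)
    counts = np.zeros((n_l, n_r), dtype=np.int64)
    total_contacts = np.zeros(win.n_frames, dtype=np.int64)
    for k, f in enumerate(win.frames()):
        d = pairwise_min_image_distances(
            traj.coords[f, left_idx], traj.coords[f, right_idx], topology.box
        )
        within = (d <= cutoff) & pair_ok
        counts += within
        total_contacts[k] = int(within.sum())

    rows = []
    li, ri = np.nonzero(counts)
    for a, b in zip(li, ri):
        ia, ib = int(left_idx[a]), int(right_idx[b])
        rows.append(
            {
                "atom_serial": int(atoms.iloc[ia]["serial"]),
                "residue": str(atoms.iloc[ia]["resname"]),
                "residue_id": int(atoms.iloc[ia]["resseq"]),
                "partner_serial": int(atoms.iloc[ib]["serial"]),
                "partner_role": str(atoms.iloc[ib]["role"]),
                "chain_id": int(atoms.iloc[ib]["chain_id"]),
                "type": interaction,
                "frames": int(counts[a, b]),
                "percent": 100.0 * counts[a, b] / win.n_frames,
            }
        )
    data = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))

    mean_per_chain = None
    if normalize_chains:
        n_chains = len(topology.chain_ids())
        if n_chains > 0:
            # separate surface-level statistic: per-snapshot contact total
            # divided by the chain count, then averaged over the window
            mean_per_chain = float(total_contacts.mean() / n_chains)
    return OccurrenceTable(
        data=data,
        interaction=interaction,
        n_frames=win.n_frames,
        cutoff=cutoff,
        mean_contacts_per_chain=mean_per_chain,
    )


# ---------------------------------------------------------------------------
# Foulant-polymer electrostatics
# ---------------------------------------------------------------------------


def electrostatic_contacts(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
    cutoff: float = ELECTROSTATIC_CUTOFF,
) -> OccurrenceTable:
    """Oppositely charged foulant-atom/polymer-atom pairs within the cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    win = resolve_window(traj, window)
    atoms = topology.atoms
    foul = np.flatnonzero(
        atoms["role"].isin([ROLE_FOULANT_POS, ROLE_FOULANT_NEG]).to_numpy()
    )
    poly = np.flatnonzero(
        atoms["role"].isin([ROLE_AMMONIUM_N, ROLE_SULFONATE_O]).to_numpy()
    )
    if len(foul) == 0:
        raise ValueError("no charged foulant atoms in topology")
    if len(poly) == 0:
        raise ValueError("no charged polymer atoms in topology")
    qf = np.array([CHARGE_BY_ROLE[r] for r in atoms.iloc[foul]["role"]])
    qp = np.array([CHARGE_BY_ROLE[r] for r in atoms.iloc[poly]["role"]])
    opposite = qf[:, None] * qp[None, :] < 0
    return _occurrence_table(
        traj, topology, win, foul, poly, opposite, cutoff,
        "electrostatic", normalize_chains=True,
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def hydrogen_bonds(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
    cutoff: float = HBOND_CUTOFF,
    angle_min_deg: float | None = None,
) -> OccurrenceTable:
    """Foulant polar-H donors to polymer carbonyl/sulfonate-O acceptors,
    distance criterion only by default."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if angle_min_deg is not None:
        raise NotImplementedError(
            "angle filtering is reserved; the criterion is distance-only"
        )
    win = resolve_window(traj, window)
    atoms = topology.atoms
    donors = np.flatnonzero((atoms["role"] == ROLE_FOULANT_POLAR_H).to_numpy())
    acceptors = np.flatnonzero(
        atoms["role"].isin([ROLE_ESTER_O, ROLE_SULFONATE_O]).to_numpy()
    )
    if len(donors) == 0:
        raise ValueError("no polar-hydrogen donors in topology")
    if len(acceptors) == 0:
        raise ValueError("no oxygen acceptors in topology")
    ok = np.ones((len(donors), len(acceptors)), dtype=bool)
    return _occurrence_table(
        traj, topology, win, donors, acceptors, ok, cutoff,
        "hbond", normalize_chains=False,
    )


# ---------------------------------------------------------------------------
# Inter-chain electrostatics
# ---------------------------------------------------------------------------


def interchain_contacts(
    traj: Trajectory,
    topology: BrushTopology,
    window: Window | tuple[int, int] | None = None,
    cutoff: float = ELECTROSTATIC_CUTOFF,
) -> OccurrenceTable:
    """Ammonium-N / sulfonate-O pairs across distinct polymer chains."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    win = resolve_window(traj, window)
    if len(topology.chain_ids()) < 2:
        raise ValueError("inter-chain contacts require at least two chains")
    atoms = topology.atoms
    amm = np.flatnonzero((atoms["role"] == ROLE_AMMONIUM_N).to_numpy())
    sul = np.flatnonzero((atoms["role"] == ROLE_SULFONATE_O).to_numpy())
    cid_a = atoms.iloc[amm]["chain_id"].to_numpy()
    cid_s = atoms.iloc[sul]["chain_id"].to_numpy()
    cross = cid_a[:, None] != cid_s[None, :]
    return _occurrence_table(
        traj, topology, win, amm, sul, cross, cutoff,
        "interchain_electrostatic", normalize_chains=True,
    )


# ---------------------------------------------------------------------------
# Neglect floor
# ---------------------------------------------------------------------------


def apply_neglect_floor(
    table: OccurrenceTable,
    floor: float = NEGLECT_FLOOR_PERCENT,
) -> OccurrenceTable:
    """Drop rows with occurrence strictly below ``floor`` percent."""
    kept = table.data[table.data["percent"] >= floor].reset_index(drop=True)
    return replace(table, data=kept)
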