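"""Construct brush-surface models: grafting grids, coarse polymer chains with
marker atoms, and a rigid charged foulant placed above the brush.

Chains are coarse role-level templates (markers, anchored carbon, charge
sites, side-group beads) rather than all-atom chemistry: every downstream
analysis consumes only these roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ROLE_AMMONIUM_N,
    ROLE_BACKBONE,
    ROLE_ESTER_O,
    ROLE_FOULANT_CA,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POLAR_H,
    ROLE_FOULANT_POS,
    ROLE_MARKER_R0,
    ROLE_MARKER_R1,
    ROLE_MARKER_R3,
    MARKER_ROLES,
    BrushTopology,
    GraftingGrid,
    empty_atom_table,
)

# Charge ratios (positive:negative surface residues) recorded per orientation.
ORIENTATION_CHARGE_RATIOS: dict[str, tuple[float, float]] = {
    "A": (1.0, 1.6),
    "B": (1.0, 1.9),
    "C": (1.0, 2.0),
}

#: Clash/solvation margin used as the default foulant-to-brush gap.
DEFAULT_INITIAL_GAP = 2.5


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


def build_grid(domain_side: float, spacing: float) -> GraftingGrid:
    """Square lattice of grafting points covering ``domain_side`` per axis.

    Points sit at ``origin + i * spacing`` for every i with
    ``i * spacing <= domain_side``; the periodic box closes the lattice at
    ``n * spacing`` per axis.

    >>> build_grid(100, 32).n_chains
    16
    """
    if domain_side <= 0:
        raise ValueError(f"domain side must be positive, got {domain_side}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if spacing > domain_side:
        raise ValueError(
            f"spacing {spacing} exceeds domain side {domain_side}"
        )
    if math.isclose(spacing, domain_side):
        # degenerate single-chain grid: the second point would be the
        # periodic image of the origin
        n = 1
    else:
        n = int(math.floor(domain_side / spacing)) + 1
    return GraftingGrid(spacing_x=spacing, spacing_y=spacing, n_x=n, n_y=n)


def build_low_density_grid() -> GraftingGrid:
    """4 x 4 lattice at 32 A spacing over a ~100 A footprint (16 chains)."""
    return build_grid(100.0, 32.0)


def build_high_density_grid() -> GraftingGrid:
    """7 x 8 lattice at 16 A spacing (56 chains, footprint 96 x 112 A).

    The 7 x 8 shape is the only small rectangular factorization of 56 chains
    compatible with a ~100 A footprint at 16 A spacing.
    """
    return GraftingGrid(spacing_x=16.0, spacing_y=16.0, n_x=7, n_y=8)


# ---------------------------------------------------------------------------
# Chain template
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    role: str
    group_id: int  # 0..3 for R0..R3, -1 for backbone/anchored
    offset: tuple[float, float, float]  # relative to the grafting point
    anchored: bool = False


@dataclass(frozen=True)
class ChainTemplate:
    """Coarse single-chain template translated to each grafting point.

    ``tacticity`` records the alternating stereocenter labels of the four
    repeat units (syndiotactic form); it has no geometric consequence here.
    """

    name: str
    atoms: tuple[TemplateAtom, ...]
    tacticity: tuple[str, ...] = ("R", "S", "R", "S")

    def __post_init__(self) -> None:
        roles = [a.role for a in self.atoms]
        for role in MARKER_ROLES:
            if roles.count(role) != 1:
                raise ValueError(
                    f"chain template {self.name!r} must define exactly one "
                    f"{role} atom"
                )
        if not any(a.anchored for a in self.atoms):
            raise ValueError(
                f"chain template {self.name!r} must define at least one "
                "anchored atom"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def marker_z(self, role: str) -> float:
        for a in self.atoms:
            if a.role == role:
                return a.offset[2]
        raise KeyError(role)


def _side_group(group_id: int, z: float, sign: float) -> list[TemplateAtom]:
    """One repeat-unit side group: ester O, ammonium N, three sulfonate O."""
    g = group_id
    return [
        TemplateAtom(f"OE{g}", "O", ROLE_ESTER_O, g, (1.2 * sign, 0.4, z - 2.0)),
        TemplateAtom(f"N{g}", "N", ROLE_AMMONIUM_N, g, (2.0 * sign, -0.5, z - 1.0)),
        TemplateAtom(f"OS{g}A", "O", "sulfonate_O", g, (2.6 * sign, 0.8, z - 0.4)),
        TemplateAtom(f"OS{g}B", "O", "sulfonate_O", g, (3.0 * sign, -0.2, z + 0.4)),
        TemplateAtom(f"OS{g}C", "O", "sulfonate_O", g, (2.6 * sign, -1.0, z - 0.2)),
    ]


def default_chain_template() -> ChainTemplate:
    """Four-repeat-unit chain: R3 at the grafted bottom, R0 at the free top.

    Marker heights (R3 C_TR at 10 A, R1 C_IN at 25 A, R0 C_TR at 30 A above
    the grafting plane) give a frame-0 brush height of 20 A.
    """
    atoms: list[TemplateAtom] = [
        TemplateAtom("CM", "C", ROLE_BACKBONE, -1, (0.0, 0.0, 0.0), anchored=True),
        TemplateAtom("CB3", "C", ROLE_BACKBONE, -1, (0.0, 0.3, 4.0)),
        TemplateAtom("CTR3", "C", ROLE_MARKER_R3, 3, (0.4, 0.0, 10.0)),
        TemplateAtom("CB2", "C", ROLE_BACKBONE, -1, (0.0, -0.3, 14.0)),
        TemplateAtom("CB1", "C", ROLE_BACKBONE, -1, (0.0, 0.3, 20.0)),
        TemplateAtom("CIN1", "C", ROLE_MARKER_R1, 1, (-0.4, 0.0, 25.0)),
        TemplateAtom("CB0", "C", ROLE_BACKBONE, -1, (0.0, -0.3, 27.0)),
        TemplateAtom("CTR0", "C", ROLE_MARKER_R0, 0, (0.4, 0.0, 30.0)),
    ]
    # alternating side-group direction mimics the syndiotactic drawing
    atoms += _side_group(3, 9.0, +1.0)
    atoms += _side_group(2, 16.0, -1.0)
    atoms += _side_group(1, 23.0, +1.0)
    atoms += _side_group(0, 29.5, -1.0)
    return ChainTemplate(name="spe4", atoms=tuple(atoms))


CHAIN_TEMPLATES = {"spe4": default_chain_template}


# ---------------------------------------------------------------------------
# Chain instantiation
# ---------------------------------------------------------------------------


def instantiate_chains(
    grid: GraftingGrid,
    template: ChainTemplate | None = None,
    box_z_margin: float = 15.0,
) -> BrushTopology:
    """One chain per grafting point; template translated to the point with
    anchored atoms on the grafting plane (z = 0)."""
    if template is None:
        template = default_chain_template()
    points = grid.points()
    records: list[dict] = []
    serial = 1
    for cid in range(grid.n_chains):
        gx, gy = points[cid]
        for ta in template.atoms:
            records.append(
                {
                    "serial": serial,
                    "name": ta.name,
                    "element": ta.element,
                    "resname": "SPE",
                    "resseq": cid + 1,
                    "role": ta.role,
                    "chain_id": cid,
                    "group_id": ta.group_id,
                    "anchored": ta.anchored,
                    "x": gx + ta.offset[0],
                    "y": gy + ta.offset[1],
                    "z": ta.offset[2],
                }
            )
            serial += 1
    atoms = pd.DataFrame.from_records(records)
    top_z = float(atoms["z"].max())
    topo = BrushTopology(
        atoms=atoms,
        grid=grid,
        box=(grid.box_x, grid.box_y, top_z + box_z_margin),
    )
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# Foulant
# ---------------------------------------------------------------------------


def build_foulant(
    n_residues: int = 24,
    radius: float = 10.0,
    charge_ratio: tuple[float, float] = (1.0, 1.6),
    n_polar_h: int = 6,
) -> pd.DataFrame:
    """Rigid BSA-like blob: CA atoms on a Fibonacci sphere, a subset of
    residues carrying charged side-chain atoms at the stated pos:neg ratio,
    plus a few polar donor hydrogens.  Deterministic for fixed arguments.
    """
    if n_residues < 1:
        raise ValueError("foulant needs at least one residue")
    pos_w, neg_w = charge_ratio
    if pos_w <= 0 or neg_w <= 0:
        raise ValueError(f"charge ratio weights must be positive, got {charge_ratio}")

    # Fibonacci sphere: evenly spread, reproducible without randomness.
    k = np.arange(n_residues)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    zs = 1.0 - 2.0 * (k + 0.5) / n_residues
    rs = np.sqrt(1.0 - zs**2)
    theta = golden * k
    ca = radius * np.column_stack([rs * np.cos(theta), rs * np.sin(theta), zs])

    n_charged = max(2, n_residues // 2)
    n_pos = max(1, round(n_charged * pos_w / (pos_w + neg_w)))
    n_neg = max(1, n_charged - n_pos)

    records: list[dict] = []
    serial = 1
    for i in range(n_residues):
        records.append(
            {
                "serial": serial,
                "name": "CA",
                "element": "C",
                "resname": "FLB",
                "resseq": i + 1,
                "role": ROLE_FOULANT_CA,
                "chain_id": -1,
                "group_id": -1,
                "anchored": False,
                "x": ca[i, 0],
                "y": ca[i, 1],
                "z": ca[i, 2],
            }
        )
        serial += 1
    # charged atoms ride 1.5 A outside their residue's CA
    charged_residues = list(range(n_pos + n_neg))
    for j, i in enumerate(charged_residues):
        sign_pos = j < n_pos
        u = ca[i] / np.linalg.norm(ca[i])
        pos = ca[i] + 1.5 * u
        records.append(
            {
                "serial": serial,
                "name": "NZ" if sign_pos else "OD",
                "element": "N" if sign_pos else "O",
                "resname": "FLB",
                "resseq": i + 1,
                "role": ROLE_FOULANT_POS if sign_pos else ROLE_FOULANT_NEG,
                "chain_id": -1,
                "group_id": -1,
                "anchored": False,
                "x": pos[0],
                "y": pos[1],
                "z": pos[2],
            }
        )
        serial += 1
    for j in range(n_polar_h):
        i = (len(charged_residues) + j) % n_residues
        u = ca[i] / np.linalg.norm(ca[i])
        pos = ca[i] + 1.0 * u
        records.append(
            {
                "serial": serial,
                "name": "HP",
                "element": "H",
                "resname": "FLB",
                "resseq": i + 1,
                "role": ROLE_FOULANT_POLAR_H,
                "chain_id": -1,
                "group_id": -1,
                "anchored": False,
                "x": pos[0],
                "y": pos[1],
                "z": pos[2],
            }
        )
        serial += 1
    return pd.DataFrame.from_records(records)


def _orientation_rotation(orientation: str) -> np.ndarray:
    """Fixed rotation preset: A = identity, B = 90 deg about x, C = 90 deg
    about y.  Conventions, not reproductions of the original orientations."""
    if orientation == "A":
        return np.eye(3)
    if orientation == "B":
        return np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
    if orientation == "C":
        return np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]])
    raise ValueError(f"unknown orientation {orientation!r}; expected A, B or C")


def place_foulant(
    topology: BrushTopology,
    foulant: pd.DataFrame,
    orientation: str = "A",
    initial_gap: float = DEFAULT_INITIAL_GAP,
    charge_ratio: tuple[float, float] | None = None,
) -> BrushTopology:
    """Rotate the foulant by the orientation preset and drop it centrally on
    the brush with its lowest atom ``initial_gap`` above the highest brush
    atom.  Returns a new topology; the input is not modified."""
    if len(foulant) == 0:
        raise ValueError("cannot place an empty foulant")
    if not (foulant["role"] == ROLE_FOULANT_CA).any():
        raise ValueError("foulant must contain at least one CA atom")
    for role in (ROLE_FOULANT_POS, ROLE_FOULANT_NEG):
        if not (foulant["role"] == role).any():
            raise ValueError(f"foulant must contain at least one {role} atom")
    if topology.grid is None:
        raise ValueError("topology has no grafting grid to center the foulant on")

    rot = _orientation_rotation(orientation)
    coords = foulant[["x", "y", "z"]].to_numpy(dtype=float) @ rot.T
    cx, cy = topology.grid.center
    coords[:, 0] += cx - coords[:, 0].mean()
    coords[:, 1] += cy - coords[:, 1].mean()
    brush_top = float(topology.atoms["z"].max())
    coords[:, 2] += brush_top + initial_gap - coords[:, 2].min()

    placed = foulant.copy()
    placed[["x", "y", "z"]] = coords
    placed["serial"] = np.arange(
        topology.n_atoms + 1, topology.n_atoms + 1 + len(placed)
    )

    atoms = pd.concat([topology.atoms, placed], ignore_index=True)
    box_z = max(topology.box[2], float(atoms["z"].max()) + 15.0)
    out = BrushTopology(
        atoms=atoms,
        grid=topology.grid,
        box=(topology.box[0], topology.box[1], box_z),
        foulant_orientation=orientation,
        foulant_charge_ratio=(
            charge_ratio
            if charge_ratio is not None
            else ORIENTATION_CHARGE_RATIOS.get(orientation)
        ),
    )
    out.validate()
    return out
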