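"""Read/write the interchange formats and provide geometry primitives.

Coordinates travel as multi-model PDB (one MODEL block per frame, fixed
columns, angstroms).  Atom roles travel in a delimited-text sidecar keyed by
atom serial.  Anchored atoms are written with occupancy and B-factor 0.00,
mirroring the fix-by-zero-temperature-factor convention; all other atoms get
1.00.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ROLE_OTHER,
    ROLES,
    ACCEPTOR_ROLES,
    CHARGE_BY_ROLE,
    DONOR_ROLES,
    BrushTopology,
    GraftingGrid,
    Trajectory,
    Window,
    resolve_window,
)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_annotations",
    "read_annotations",
    "select_window",
    "last_ns_window",
    "min_image_distance",
    "min_image_displacement",
    "pairwise_min_image_distances",
]


# ---------------------------------------------------------------------------
# PDB coordinate I/O
# ---------------------------------------------------------------------------

_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s} {resname:<4s}{chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{beta:6.2f}          {element:>2s}\n"
)


def _chain_letter(chain_id: int) -> str:
    if chain_id < 0:
        return "X"
    return chr(ord("A") + chain_id % 26)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in columns 13-14
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_trajectory(
    path: str | os.PathLike,
    topology: BrushTopology,
    traj: Trajectory,
) -> None:
    """Write a multi-model PDB; one MODEL/ENDMDL block per frame."""
    if traj.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {traj.n_atoms} atoms but topology has "
            f"{topology.n_atoms}"
        )
    atoms = topology.atoms
    bx, by, bz = topology.box
    lines: list[str] = []
    lines.append(
        f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    lines.append(
        f"REMARK   6 FRAME_INTERVAL_PS {traj.frame_interval_ps:g}\n"
    )
    serials = atoms["serial"].to_numpy()
    names = [
        _format_atom_name(n, e)
        for n, e in zip(atoms["name"], atoms["element"])
    ]
    resnames = atoms["resname"].tolist()
    chains = [_chain_letter(int(c)) for c in atoms["chain_id"]]
    resseqs = atoms["resseq"].to_numpy()
    anchored = atoms["anchored"].to_numpy()
    elements = atoms["element"].tolist()
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}\n")
        xyz = traj.coords[f]
        for i in range(topology.n_atoms):
            flag = 0.0 if anchored[i] else 1.0
            lines.append(
                _PDB_ATOM_FMT.format(
                    serial=int(serials[i]) % 100000,
                    name=names[i],
                    resname=resnames[i][:4],
                    chain=chains[i],
                    resseq=int(resseqs[i]) % 10000,
                    x=xyz[i, 0],
                    y=xyz[i, 1],
                    z=xyz[i, 2],
                    occ=flag,
                    beta=flag,
                    element=elements[i][:2],
                )
            )
        lines.append("ENDMDL\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def read_trajectory(
    coordinate_path: str | os.PathLike,
    annotation_path: str | os.PathLike | None = None,
) -> tuple[BrushTopology, Trajectory]:
    """Parse a multi-model PDB (plus optional role sidecar).

    MODEL blocks become frames in order.  Atoms lacking a sidecar entry get
    role ``other``.  Malformed coordinate lines and frame-size mismatches are
    reported with their location.
    """
    frames: list[list[tuple]] = []
    current: list[tuple] | None = None
    box = (0.0, 0.0, 0.0)
    frame_interval = 10.0
    with open(coordinate_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
            elif line.startswith("REMARK   6 FRAME_INTERVAL_PS"):
                frame_interval = float(line.split()[-1])
            elif rec == "MODEL ":
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ValueError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    # tolerate naked ATOM records before the first MODEL
                    current = []
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ = float(line[54:60]) if line[54:60].strip() else 1.0
                    element = line[76:78].strip() or name[:1]
                except ValueError as exc:
                    raise ValueError(
                        f"{coordinate_path}: malformed coordinate line "
                        f"{lineno}: {line.rstrip()!r}"
                    ) from exc
                current.append((serial, name, resname, resseq, x, y, z, occ, element))
    if current:  # trailing frame without ENDMDL
        frames.append(current)
    if not frames:
        raise ValueError(f"{coordinate_path}: no MODEL blocks found")

    n_atoms = len(frames[0])
    for f, frame in enumerate(frames):
        if len(frame) != n_atoms:
            raise ValueError(
                f"frame {f}: expected {n_atoms} atoms, found {len(frame)}"
            )

    first = frames[0]
    coords = np.empty((len(frames), n_atoms, 3), dtype=float)
    for f, frame in enumerate(frames):
        for i, rec in enumerate(frame):
            coords[f, i, 0] = rec[4]
            coords[f, i, 1] = rec[5]
            coords[f, i, 2] = rec[6]

    atoms = pd.DataFrame(
        {
            "serial": [r[0] for r in first],
            "name": [r[1] for r in first],
            "element": [r[8] for r in first],
            "resname": [r[2] for r in first],
            "resseq": [r[3] for r in first],
            "role": ROLE_OTHER,
            "chain_id": -1,
            "group_id": -1,
            "anchored": [r[7] == 0.0 for r in first],
            "x": coords[0, :, 0],
            "y": coords[0, :, 1],
            "z": coords[0, :, 2],
        }
    )

    grid = None
    if annotation_path is not None:
        ann, grid = read_annotations(annotation_path)
        missing = set(ann["serial"]) - set(atoms["serial"])
        if missing:
            raise ValueError(
                f"annotation serials absent from coordinates: "
                f"{sorted(missing)[:5]}"
            )
        ann = ann.set_index("serial")
        idx = atoms["serial"].to_numpy()
        present = np.isin(idx, ann.index.to_numpy())
        for col in ("role", "chain_id", "group_id", "anchored"):
            vals = atoms[col].to_numpy(dtype=object)
            vals[present] = ann.loc[idx[present], col].to_numpy()
            atoms[col] = vals
        atoms["chain_id"] = atoms["chain_id"].astype(np.int64)
        atoms["group_id"] = atoms["group_id"].astype(np.int64)
        atoms["anchored"] = atoms["anchored"].astype(bool)

    topo = BrushTopology(atoms=atoms, grid=grid, box=box)
    traj = Trajectory(coords=coords, frame_interval_ps=frame_interval)
    return topo, traj


# ---------------------------------------------------------------------------
# Annotation sidecar
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["serial", "role", "chain_id", "group_id", "charge", "hbond", "anchored"]


def write_annotations(path: str | os.PathLike, topology: BrushTopology) -> None:
    """Delimited-text sidecar: serial, role, chain, R-group, charge class,
    donor/acceptor flag, anchored flag.  Grid metadata in # header lines."""
    atoms = topology.atoms
    lines = []
    if topology.grid is not None:
        g = topology.grid
        lines.append(
            f"# grid\t{g.spacing_x:g}\t{g.spacing_y:g}\t{g.n_x}\t{g.n_y}"
            f"\t{g.origin[0]:g}\t{g.origin[1]:g}\n"
        )
    lines.append("\t".join(_ANN_COLUMNS) + "\n")
    for row in atoms.itertuples(index=False):
        charge = CHARGE_BY_ROLE.get(row.role, 0)
        charge_cls = {1: "pos", -1: "neg", 0: "none"}[charge]
        if row.role in DONOR_ROLES:
            hbond = "donor"
        elif row.role in ACCEPTOR_ROLES:
            hbond = "acceptor"
        else:
            hbond = "none"
        lines.append(
            f"{row.serial}\t{row.role}\t{row.chain_id}\t{row.group_id}"
            f"\t{charge_cls}\t{hbond}\t{int(row.anchored)}\n"
        )
    Path(path).write_text("".join(lines))


def read_annotations(
    path: str | os.PathLike,
) -> tuple[pd.DataFrame, GraftingGrid | None]:
    grid = None
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# grid"):
                _, sx, sy, nx, ny, ox, oy = line.rstrip("\n").split("\t")
                grid = GraftingGrid(
                    spacing_x=float(sx),
                    spacing_y=float(sy),
                    n_x=int(nx),
                    n_y=int(ny),
                    origin=(float(ox), float(oy)),
                )
                header_rows += 1
            elif line.startswith("#"):
                header_rows += 1
            else:
                break
    ann = pd.read_csv(path, sep="\t", skiprows=header_rows)
    bad = set(ann["role"].unique()) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown roles in annotation file: {sorted(bad)}")
    ann["anchored"] = ann["anchored"].astype(bool)
    return ann, grid


# ---------------------------------------------------------------------------
# Frame windows
# ---------------------------------------------------------------------------


def select_window(traj: Trajectory, last_ns: float) -> Trajectory:
    """Trailing sub-trajectory covering the last ``last_ns`` nanoseconds.

    At a 10 ps interval, the last 100 ns is exactly 10,000 frames.
    """
    if last_ns <= 0:
        raise ValueError(f"window length must be positive, got {last_ns} ns")
    n = int(round(last_ns * 1000.0 / traj.frame_interval_ps))
    if n > traj.n_frames:
        raise ValueError(
            f"window of {last_ns} ns ({n} frames) exceeds trajectory of "
            f"{traj.n_frames} frames ({traj.duration_ns:g} ns)"
        )
    return Trajectory(
        coords=traj.coords[traj.n_frames - n:],
        frame_interval_ps=traj.frame_interval_ps,
        periodic=traj.periodic,
    )


def last_ns_window(traj: Trajectory, last_ns: float) -> Window:
    """Frame-index window covering the trailing ``last_ns`` nanoseconds."""
    n = int(round(last_ns * 1000.0 / traj.frame_interval_ps))
    if n > traj.n_frames or n < 1:
        raise ValueError(
            f"window of {last_ns} ns ({n} frames) invalid for trajectory of "
            f"{traj.n_frames} frames"
        )
    return Window(traj.n_frames - n, traj.n_frames)


# ---------------------------------------------------------------------------
# Minimum-image geometry
# ---------------------------------------------------------------------------


def min_image_displacement(
    p1: np.ndarray,
    p2: np.ndarray,
    box: tuple[float, float, float],
    periodic: tuple[bool, bool, bool] = (True, True, False),
) -> np.ndarray:
    """Displacement p2 - p1 with periodic components wrapped to [-L/2, L/2]."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    d = np.atleast_2d(d).copy()
    for ax in range(3):
        if periodic[ax]:
            L = box[ax]
            if L <= 0:
                raise ValueError(f"box length along axis {ax} must be positive")
            d[:, ax] -= L * np.round(d[:, ax] / L)
    return d


def min_image_distance(
    p1: np.ndarray,
    p2: np.ndarray,
    box: tuple[float, float, float],
    periodic: tuple[bool, bool, bool] = (True, True, False),
) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention (z unwrapped
    by default)."""
    d = min_image_displacement(p1, p2, box, periodic)
    out = np.sqrt((d * d).sum(axis=1))
    return float(out[0]) if out.size == 1 and np.ndim(p1) == 1 else out


def pairwise_min_image_distances(
    a: np.ndarray,
    b: np.ndarray,
    box: tuple[float, float, float],
    periodic: tuple[bool, bool, bool] = (True, True, False),
) -> np.ndarray:
    """(len(a), len(b)) distance matrix under minimum image."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a[:, None, :] - b[None, :, :]
    for ax in range(3):
        if periodic[ax]:
            L = box[ax]
            if L <= 0:
                raise ValueError(f"box length along axis {ax} must be positive")
            d[..., ax] -= L * np.round(d[..., ax] / L)
    return np.sqrt((d * d).sum(axis=-1))
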