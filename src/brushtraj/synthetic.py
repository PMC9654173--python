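"""Synthetic multi-frame trajectories with scripted, analytically known
dynamics: fluctuating grafted chains, explicit 3-point waters, and a rigid
foulant following a detach / anchor / penetrate / static mechanism.

Every scripted quantity (height schedule, contact occupancy fraction) is
designed to be recovered exactly by the corresponding analysis module, so
the generator doubles as ground truth for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_FRAME_INTERVAL_PS,
    FOULANT_ROLES,
    MARKER_ROLES,
    POLYMER_ROLES,
    ROLE_AMMONIUM_N,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POS,
    ROLE_SULFONATE_O,
    ROLE_WATER_H,
    ROLE_WATER_O,
    BrushTopology,
    Trajectory,
)

#: Solvent-clash exclusion radius for generated waters.
WATER_CLASH_RADIUS = 2.5

#: Rigid 3-point water geometry (O at origin; TIP3P-like bond/angle).
_WATER_H_OFFSETS = np.array(
    [
        [0.9572, 0.0, 0.0],
        [-0.2400, 0.9266, 0.0],
    ]
)

MECHANISMS = ("detach", "anchor", "penetrate", "static")


@dataclass(frozen=True)
class ContactDirective:
    """Forces one foulant-atom/polymer-atom pair into or out of contact.

    In frames where ``frame_mask`` is True the foulant atom is placed at
    ``cutoff - margin`` above the polymer atom; elsewhere at
    ``cutoff + off_margin``, so occurrence fractions are exact by
    construction.  Atoms are picked by role (first match) unless explicit
    0-based table indices are given.
    """

    foulant_role: str
    polymer_role: str
    frame_mask: np.ndarray
    cutoff: float = 4.0
    margin: float = 0.1
    off_margin: float = 1.0
    foulant_index: int | None = None
    polymer_index: int | None = None


@dataclass(frozen=True)
class ScenarioSpec:
    mechanism: str
    n_frames: int
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS
    chain_fluctuation_sigma: float = 0.5
    foulant_z_schedule: np.ndarray | None = None
    water_count: int = 0
    contact_schedule: tuple[ContactDirective, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of "
                f"{MECHANISMS}"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.chain_fluctuation_sigma < 0:
            raise ValueError("chain_fluctuation_sigma must be >= 0")
        if self.water_count < 0:
            raise ValueError("water_count must be >= 0")
        if self.foulant_z_schedule is not None:
            sched = np.asarray(self.foulant_z_schedule, dtype=float)
            if sched.shape != (self.n_frames,):
                raise ValueError(
                    f"foulant_z_schedule length {sched.shape} does not match "
                    f"n_frames={self.n_frames}"
                )
            object.__setattr__(self, "foulant_z_schedule", sched)
        for d in self.contact_schedule:
            if np.asarray(d.frame_mask).shape != (self.n_frames,):
                raise ValueError(
                    "contact directive frame_mask length does not match "
                    f"n_frames={self.n_frames}"
                )


# ---------------------------------------------------------------------------
# Mechanism presets
# ---------------------------------------------------------------------------


def mechanism_presets(
    mechanism: str,
    n_frames: int = 1000,
    seed: int = 0,
    water_count: int = 0,
    sigma: float = 0.5,
) -> ScenarioSpec:
    """Scripted scenario for each mechanism class.

    detach    — monotone rise ending 40 A above the start, no contacts.
    anchor    — settles at the brush top with a persistent ammonium-N /
                negative-foulant-atom contact.
    penetrate — descends ~25 A below the start (well below mean brush
                height) with a persistent sulfonate-O / positive-foulant-atom
                contact.
    static    — no motion at all.
    """
    t = np.linspace(0.0, 1.0, n_frames)
    if mechanism == "detach":
        schedule = 40.0 * np.minimum(1.0, 2.0 * t)  # rises, then stays away
        contacts: tuple[ContactDirective, ...] = ()
    elif mechanism == "anchor":
        schedule = np.zeros(n_frames)
        contacts = (
            ContactDirective(
                foulant_role=ROLE_FOULANT_NEG,
                polymer_role=ROLE_AMMONIUM_N,
                frame_mask=np.ones(n_frames, dtype=bool),
                cutoff=4.0,
            ),
        )
    elif mechanism == "penetrate":
        schedule = -25.0 * np.minimum(1.0, 2.0 * t)
        contacts = (
            ContactDirective(
                foulant_role=ROLE_FOULANT_POS,
                polymer_role=ROLE_SULFONATE_O,
                frame_mask=t >= 0.5,
                cutoff=4.0,
            ),
        )
    elif mechanism == "static":
        schedule = np.zeros(n_frames)
        contacts = ()
    else:
        raise ValueError(
            f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}"
        )
    return ScenarioSpec(
        mechanism=mechanism,
        n_frames=n_frames,
        chain_fluctuation_sigma=sigma,
        foulant_z_schedule=schedule,
        water_count=water_count,
        contact_schedule=contacts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Water placement
# ---------------------------------------------------------------------------


def _place_waters(
    topology: BrushTopology,
    n_waters: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniform waters in the box, rejecting any molecule with an atom within
    WATER_CLASH_RADIUS of an existing (polymer/foulant) atom at frame 0."""
    from .trajectory_io import pairwise_min_image_distances

    bx, by, bz = topology.box
    solute = topology.coords0()
    records: list[dict] = []
    serial = topology.n_atoms + 1
    resseq = 1
    attempts = 0
    max_attempts = 2000 * max(n_waters, 1)
    while resseq <= n_waters:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_waters} clash-free waters after "
                f"{max_attempts} attempts"
            )
        o = np.array(
            [rng.uniform(0, bx), rng.uniform(0, by), rng.uniform(0, bz)]
        )
        mol = np.vstack([o, o + _WATER_H_OFFSETS])
        dists = pairwise_min_image_distances(mol, solute, topology.box)
        if dists.min() < WATER_CLASH_RADIUS:
            continue
        for name, element, role, xyz in (
            ("OW", "O", ROLE_WATER_O, mol[0]),
            ("HW1", "H", ROLE_WATER_H, mol[1]),
            ("HW2", "H", ROLE_WATER_H, mol[2]),
        ):
            records.append(
                {
                    "serial": serial,
                    "name": name,
                    "element": element,
                    "resname": "HOH",
                    "resseq": resseq,
                    "role": role,
                    "chain_id": -1,
                    "group_id": -1,
                    "anchored": False,
                    "x": xyz[0],
                    "y": xyz[1],
                    "z": xyz[2],
                }
            )
            serial += 1
        resseq += 1
    return pd.DataFrame.from_records(records)


def solvate(topology: BrushTopology, n_waters: int, seed: int = 0) -> BrushTopology:
    """Return a copy of ``topology`` with ``n_waters`` clash-free waters."""
    if n_waters == 0:
        return topology
    rng = np.random.default_rng(seed)
    waters = _place_waters(topology, n_waters, rng)
    atoms = pd.concat([topology.atoms, waters], ignore_index=True)
    return BrushTopology(
        atoms=atoms,
        grid=topology.grid,
        box=topology.box,
        foulant_orientation=topology.foulant_orientation,
        foulant_charge_ratio=topology.foulant_charge_ratio,
    )


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------


def generate(topology: BrushTopology, spec: ScenarioSpec) -> tuple[BrushTopology, Trajectory]:
    """Generate a trajectory honoring the scenario script.

    Returns (topology, trajectory); the returned topology includes any waters
    added for the scenario.  Deterministic for a fixed seed.

    Scripted structure:
      * anchored atoms are immobile in every frame;
      * non-anchored polymer atoms get independent z-only Gaussian noise of
        ``chain_fluctuation_sigma`` per frame, so each atom's RMSF has the
        closed form sigma;
      * the foulant translates rigidly by ``foulant_z_schedule``;
      * waters are static at their frame-0 positions;
      * contact directives override individual foulant atoms per frame.
    """
    rng = np.random.default_rng(spec.seed)
    topo = solvate(topology, spec.water_count, seed=spec.seed)
    base = topo.coords0()
    n_frames, n_atoms = spec.n_frames, topo.n_atoms

    atoms = topo.atoms
    polymer_mask = atoms["role"].isin(POLYMER_ROLES).to_numpy()
    anchored = atoms["anchored"].to_numpy()
    noisy = polymer_mask & ~anchored
    foulant_mask = atoms["role"].isin(FOULANT_ROLES).to_numpy()

    coords = np.broadcast_to(base, (n_frames, n_atoms, 3)).copy()

    if spec.chain_fluctuation_sigma > 0 and noisy.any():
        noise = rng.normal(
            0.0, spec.chain_fluctuation_sigma, size=(n_frames, int(noisy.sum()))
        )
        coords[:, noisy, 2] += noise

    if spec.foulant_z_schedule is not None and foulant_mask.any():
        coords[:, foulant_mask, 2] += spec.foulant_z_schedule[:, None]

    for d in spec.contact_schedule:
        fi = d.foulant_index
        pi = d.polymer_index
        if fi is None:
            cand = np.flatnonzero((atoms["role"] == d.foulant_role).to_numpy())
            if len(cand) == 0:
                raise ValueError(
                    f"contact directive: no atom with role {d.foulant_role!r}"
                )
            fi = int(cand[0])
        if pi is None:
            cand = np.flatnonzero((atoms["role"] == d.polymer_role).to_numpy())
            if len(cand) == 0:
                raise ValueError(
                    f"contact directive: no atom with role {d.polymer_role!r}"
                )
            pi = int(cand[0])
        mask = np.asarray(d.frame_mask, dtype=bool)
        on = d.cutoff - d.margin
        off = d.cutoff + d.off_margin
        coords[mask, fi, :] = coords[mask, pi, :] + np.array([0.0, 0.0, on])
        coords[~mask, fi, :] = coords[~mask, pi, :] + np.array([0.0, 0.0, off])

    traj = Trajectory(coords=coords, frame_interval_ps=spec.frame_interval_ps)
    return topo, traj
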