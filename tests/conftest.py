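"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use naive nested loops and explicit
periodic-image enumeration so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import brushtraj as bt
from brushtraj.core import (
    ROLE_ESTER_O,
    ROLE_MARKER_R0,
    ROLE_MARKER_R1,
    ROLE_MARKER_R3,
    ROLE_SULFONATE_O,
    ROLE_WATER_H,
)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def low_grid():
    return bt.build_grid(100.0, 32.0)


@pytest.fixture(scope="session")
def small_grid():
    return bt.GraftingGrid(spacing_x=32.0, spacing_y=32.0, n_x=2, n_y=2)


@pytest.fixture(scope="session")
def small_topology(small_grid):
    return bt.instantiate_chains(small_grid)


@pytest.fixture(scope="session")
def foulant_topology(small_topology):
    return bt.place_foulant(small_topology, bt.build_foulant(), "A")


@pytest.fixture()
def static_run(foulant_topology):
    spec = bt.ScenarioSpec(
        mechanism="static", n_frames=5, chain_fluctuation_sigma=0.0,
        water_count=20, seed=3,
    )
    return bt.generate(foulant_topology, spec)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_min_image(p1, p2, box, periodic=(True, True, False)):
    """Minimum distance over explicitly enumerated periodic images."""
    shifts = []
    for ax in range(3):
        shifts.append(list(range(-8, 9)) if periodic[ax] else [0])
    best = math.inf
    for sx in shifts[0]:
        for sy in shifts[1]:
            for sz in shifts[2]:
                q = (
                    p2[0] + sx * box[0] - p1[0],
                    p2[1] + sy * box[1] - p1[1],
                    p2[2] + sz * box[2] - p1[2],
                )
                best = min(best, math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2))
    return best


def oracle_chain_height(traj, topology, chain_id, frames):
    """Per-frame clamp-and-max marker height, naive loops."""
    atoms = topology.atoms
    idx = {}
    for role in (ROLE_MARKER_R0, ROLE_MARKER_R1, ROLE_MARKER_R3):
        rows = atoms.index[(atoms["chain_id"] == chain_id) & (atoms["role"] == role)]
        idx[role] = int(rows[0])
    vals = []
    for f in frames:
        z0 = traj.coords[f, idx[ROLE_MARKER_R0], 2]
        z1 = traj.coords[f, idx[ROLE_MARKER_R1], 2]
        z3 = traj.coords[f, idx[ROLE_MARKER_R3], 2]
        h1 = max(0.0, z0 - z3)
        h2 = max(0.0, z1 - z3)
        vals.append(max(h1, h2))
    return sum(vals) / len(vals)


def oracle_chain_rmsf(traj, topology, chain_id, frames):
    atoms = topology.atoms
    rows = atoms.index[
        (atoms["chain_id"] == chain_id)
        & (atoms["group_id"] >= 0)
        & (~atoms["anchored"])
    ]
    per_atom = []
    for i in rows:
        mean = np.zeros(3)
        for f in frames:
            mean += traj.coords[f, i]
        mean /= len(frames)
        acc = 0.0
        for f in frames:
            d = traj.coords[f, i] - mean
            acc += float(d @ d)
        per_atom.append(math.sqrt(acc / len(frames)))
    return sum(per_atom) / len(per_atom)


def oracle_chain_hydration(traj, topology, chain_id, frames, cutoff, box):
    atoms = topology.atoms
    oxy = atoms.index[
        (atoms["chain_id"] == chain_id)
        & atoms["role"].isin([ROLE_ESTER_O, ROLE_SULFONATE_O])
    ]
    wh = atoms.index[atoms["role"] == ROLE_WATER_H]
    per_frame = []
    for f in frames:
        count = 0
        for h in wh:
            near = False
            for o in oxy:
                d = oracle_min_image(traj.coords[f, h], traj.coords[f, o], box)
                if d <= cutoff:
                    near = True
                    break
            if near:
                count += 1
        per_frame.append(count)
    return sum(per_frame) / len(per_frame)


def oracle_occurrence(traj, box, frames, pairs, cutoff):
    """pairs: list of (i, j) atom-index pairs -> {pair: percent}."""
    out = {}
    for (i, j) in pairs:
        n = 0
        for f in frames:
            d = oracle_min_image(traj.coords[f, i], traj.coords[f, j], box)
            if d <= cutoff:
                n += 1
        out[(i, j)] = 100.0 * n / len(frames)
    return out


def oracle_cavity_means(chain_vals):
    """Wrapped-neighbor cavity means on an (n_x, n_y) chain-value array."""
    nx, ny = chain_vals.shape
    out = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            out[i, j] = (
                chain_vals[i, j]
                + chain_vals[(i + 1) % nx, j]
                + chain_vals[i, (j + 1) % ny]
                + chain_vals[(i + 1) % nx, (j + 1) % ny]
            ) / 4.0
    return out
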