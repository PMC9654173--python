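import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brushtraj as bt
from brushtraj.core import (
    ROLE_AMMONIUM_N,
    ROLE_FOULANT_NEG,
    ROLE_FOULANT_POLAR_H,
    ROLE_FOULANT_POS,
    ROLE_SULFONATE_O,
)
from brushtraj.interactions import (
    NEGLECT_FLOOR_PERCENT,
    OccurrenceTable,
    TABLE_COLUMNS,
)

from conftest import oracle_occurrence


def _place(topology, role, where, which=0):
    """Return coords0 copy with the which-th atom of `role` moved to `where`."""
    coords = topology.coords0().copy()
    idx = topology.role_indices(role)[which]
    coords[idx] = where
    return coords, idx


class TestElectrostaticContacts:
    def test_scheduled_50_percent(self, foulant_topology):
        n = 10
        mask = np.zeros(n, dtype=bool)
        mask[::2] = True
        spec = bt.ScenarioSpec(
            mechanism="anchor", n_frames=n, chain_fluctuation_sigma=0.0,
            contact_schedule=(
                bt.ContactDirective(ROLE_FOULANT_NEG, ROLE_AMMONIUM_N, mask),
            ),
        )
        topo, traj = bt.generate(foulant_topology, spec)
        table = bt.electrostatic_contacts(traj, topo)
        assert (table.data["percent"] == 50.0).sum() == 1

    def test_like_charges_never_reported(self, foulant_topology):
        # put a positive foulant atom on top of an ammonium nitrogen
        coords, fi = _place(foulant_topology, ROLE_FOULANT_POS, (0, 0, 0))
        ni = foulant_topology.role_indices(ROLE_AMMONIUM_N)[0]
        coords[fi] = coords[ni] + np.array([0, 0, 1.0])
        traj = bt.Trajectory(coords=np.repeat(coords[None], 2, axis=0))
        table = bt.electrostatic_contacts(traj, foulant_topology)
        pos_serial = foulant_topology.atoms.iloc[fi]["serial"]
        rows = table.data[
            (table.data["atom_serial"] == pos_serial)
            & (table.data["partner_role"] == ROLE_AMMONIUM_N)
        ]
        assert len(rows) == 0

    def test_exact_cutoff_inclusive(self, foulant_topology):
        coords, fi = _place(foulant_topology, ROLE_FOULANT_NEG, (0, 0, 0))
        ni = foulant_topology.role_indices(ROLE_AMMONIUM_N)[0]
        coords[fi] = coords[ni] + np.array([0, 0, 4.0])
        traj = bt.Trajectory(coords=np.repeat(coords[None], 3, axis=0))
        table = bt.electrostatic_contacts(traj, foulant_topology)
        serial = foulant_topology.atoms.iloc[fi]["serial"]
        row = table.data[table.data["atom_serial"] == serial]
        assert (row["percent"] == 100.0).any()

    def test_missing_charges_error(self, small_topology):
        traj = bt.Trajectory(coords=small_topology.coords0()[None])
        with pytest.raises(ValueError, match="foulant"):
            bt.electrostatic_contacts(traj, small_topology)

    def test_mean_contacts_per_chain(self, foulant_topology):
        mask = np.ones(4, dtype=bool)
        spec = bt.ScenarioSpec(
            mechanism="anchor", n_frames=4, chain_fluctuation_sigma=0.0,
            contact_schedule=(
                bt.ContactDirective(ROLE_FOULANT_NEG, ROLE_AMMONIUM_N, mask),
            ),
        )
        topo, traj = bt.generate(foulant_topology, spec)
        table = bt.electrostatic_contacts(traj, topo)
        n_chains = len(topo.chain_ids())
        total = table.data["frames"].sum()
        assert table.mean_contacts_per_chain == pytest.approx(
            total / traj.n_frames / n_chains
        )


class TestHydrogenBonds:
    def _traj_with_donor_at(self, topology, offset):
        coords = topology.coords0().copy()
        hi = topology.role_indices(ROLE_FOULANT_POLAR_H)[0]
        oi = topology.role_indices(ROLE_SULFONATE_O)[0]
        coords[hi] = coords[oi] + np.asarray(offset)
        return bt.Trajectory(coords=np.repeat(coords[None], 2, axis=0)), hi

    def test_within_cutoff_100_percent(self, foulant_topology):
        traj, hi = self._traj_with_donor_at(foulant_topology, (0, 0, 2.3))
        table = bt.hydrogen_bonds(traj, foulant_topology)
        serial = foulant_topology.atoms.iloc[hi]["serial"]
        row = table.data[table.data["atom_serial"] == serial]
        assert (row["percent"] == 100.0).any()

    def test_beyond_cutoff_absent(self, foulant_topology):
        traj, hi = self._traj_with_donor_at(foulant_topology, (0, 0, 2.5))
        table = bt.hydrogen_bonds(traj, foulant_topology)
        serial = foulant_topology.atoms.iloc[hi]["serial"]
        oi_serial = foulant_topology.atoms.iloc[
            foulant_topology.role_indices(ROLE_SULFONATE_O)[0]
        ]["serial"]
        row = table.data[
            (table.data["atom_serial"] == serial)
            & (table.data["partner_serial"] == oi_serial)
        ]
        assert len(row) == 0

    def test_scheduled_10_percent(self, foulant_topology):
        n = 10
        mask = np.zeros(n, dtype=bool)
        mask[0] = True
        spec = bt.ScenarioSpec(
            mechanism="anchor", n_frames=n, chain_fluctuation_sigma=0.0,
            contact_schedule=(
                bt.ContactDirective(
                    ROLE_FOULANT_POLAR_H, ROLE_SULFONATE_O, mask, cutoff=2.4
                ),
            ),
        )
        topo, traj = bt.generate(foulant_topology, spec)
        table = bt.hydrogen_bonds(traj, topo)
        assert (table.data["percent"] == 10.0).sum() >= 1

    def test_no_donors_error(self, small_topology):
        traj = bt.Trajectory(coords=small_topology.coords0()[None])
        with pytest.raises(ValueError, match="donor"):
            bt.hydrogen_bonds(traj, small_topology)


class TestInterchainContacts:
    def test_pair_at_3A_every_frame(self, small_topology):
        coords = small_topology.coords0().copy()
        ni = small_topology.chain_indices(0, ROLE_AMMONIUM_N)[0]
        oi = small_topology.chain_indices(1, ROLE_SULFONATE_O)[0]
        coords[oi] = coords[ni] + np.array([0, 0, 3.0])
        traj = bt.Trajectory(coords=np.repeat(coords[None], 2, axis=0))
        table = bt.interchain_contacts(traj, small_topology)
        serial_n = small_topology.atoms.iloc[ni]["serial"]
        serial_o = small_topology.atoms.iloc[oi]["serial"]
        row = table.data[
            (table.data["atom_serial"] == serial_n)
            & (table.data["partner_serial"] == serial_o)
        ]
        assert list(row["percent"]) == [100.0]

    def test_self_chain_pairs_excluded(self, small_topology):
        traj = bt.Trajectory(coords=small_topology.coords0()[None] + 0.0)
        traj = bt.Trajectory(coords=np.repeat(traj.coords, 2, axis=0))
        table = bt.interchain_contacts(traj, small_topology)
        atoms = small_topology.atoms
        for _, row in table.data.iterrows():
            donor_chain = int(
                atoms.loc[atoms["serial"] == row["atom_serial"], "chain_id"].iloc[0]
            )
            assert donor_chain != row["chain_id"]

    def test_far_chains_empty_after_floor(self):
        grid = bt.GraftingGrid(60.0, 60.0, 2, 1)
        topo = bt.instantiate_chains(grid)
        traj = bt.Trajectory(coords=np.repeat(topo.coords0()[None], 2, axis=0))
        table = bt.apply_neglect_floor(bt.interchain_contacts(traj, topo))
        assert len(table.data) == 0

    def test_single_chain_rejected(self):
        topo = bt.instantiate_chains(bt.GraftingGrid(32, 32, 1, 1))
        traj = bt.Trajectory(coords=np.repeat(topo.coords0()[None], 2, axis=0))
        with pytest.raises(ValueError, match="two chains"):
            bt.interchain_contacts(traj, topo)

    def test_matches_brute_force_oracle(self):
        grid = bt.GraftingGrid(8.0, 8.0, 5, 1)
        topo = bt.instantiate_chains(grid)
        spec = bt.ScenarioSpec(mechanism="static", n_frames=8,
                               chain_fluctuation_sigma=2.0, seed=13)
        topo, traj = bt.generate(topo, spec)
        table = bt.interchain_contacts(traj, topo)
        atoms = topo.atoms
        amm = topo.role_indices(ROLE_AMMONIUM_N)
        sul = topo.role_indices(ROLE_SULFONATE_O)
        pairs = [
            (int(i), int(j))
            for i in amm
            for j in sul
            if atoms.iloc[i]["chain_id"] != atoms.iloc[j]["chain_id"]
        ]
        expected = oracle_occurrence(
            traj, topo.box, range(traj.n_frames), pairs, 4.0
        )
        got = {
            (
                int(atoms.index[atoms["serial"] == r["atom_serial"]][0]),
                int(atoms.index[atoms["serial"] == r["partner_serial"]][0]),
            ): r["percent"]
            for _, r in table.data.iterrows()
        }
        for pair, pct in expected.items():
            if pct > 0:
                assert got[pair] == pytest.approx(pct, abs=1e-10)
            else:
                assert pair not in got


class TestNeglectFloor:
    def _table(self, percents):
        n = len(percents)
        df = pd.DataFrame(
            {
                "atom_serial": range(n),
                "residue": ["FLB"] * n,
                "residue_id": range(n),
                "partner_serial": range(n),
                "partner_role": [ROLE_AMMONIUM_N] * n,
                "chain_id": [0] * n,
                "type": ["electrostatic"] * n,
                "frames": [int(p) for p in percents],
                "percent": percents,
            }
        )
        return OccurrenceTable(df, "electrostatic", 100, 4.0)

    def test_strict_less_removal(self):
        table = self._table([4.9, 5.0, 80.0])
        out = bt.apply_neglect_floor(table)
        assert sorted(out.data["percent"]) == [5.0, 80.0]

    def test_empty_table(self):
        table = self._table([])
        assert len(bt.apply_neglect_floor(table).data) == 0

    @given(st.lists(st.floats(0, 100), max_size=100))
    @settings(max_examples=30)
    def test_matches_brute_force_filter(self, percents):
        table = self._table(percents)
        out = bt.apply_neglect_floor(table)
        expected = [p for p in percents if p >= NEGLECT_FLOOR_PERCENT]
        assert list(out.data["percent"]) == expected

    def test_raw_table_unmodified(self):
        table = self._table([1.0, 99.0])
        bt.apply_neglect_floor(table)
        assert len(table.data) == 2


@pytest.fixture(scope="module")
def anchor_run(foulant_topology):
    spec = bt.mechanism_presets("anchor", n_frames=12, sigma=1.0, seed=8)
    return bt.generate(foulant_topology, spec)


class TestOccurrenceInvariants:

    def test_frame_reordering_invariance(self, anchor_run):
        topo, traj = anchor_run
        t1 = bt.electrostatic_contacts(traj, topo)
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = bt.Trajectory(coords=traj.coords[perm])
        t2 = bt.electrostatic_contacts(shuffled, topo)
        merged = t1.data.merge(
            t2.data, on=["atom_serial", "partner_serial"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(t1.data)
        assert np.allclose(merged["percent_a"], merged["percent_b"])

    def test_frame_duplication_invariance(self, anchor_run):
        topo, traj = anchor_run
        t1 = bt.electrostatic_contacts(traj, topo)
        doubled = bt.Trajectory(coords=np.concatenate([traj.coords, traj.coords]))
        t2 = bt.electrostatic_contacts(doubled, topo)
        merged = t1.data.merge(
            t2.data, on=["atom_serial", "partner_serial"], suffixes=("_a", "_b")
        )
        assert np.allclose(merged["percent_a"], merged["percent_b"])

    def test_cutoff_monotonicity(self, anchor_run):
        topo, traj = anchor_run
        small = bt.electrostatic_contacts(traj, topo, cutoff=3.0)
        large = bt.electrostatic_contacts(traj, topo, cutoff=5.0)
        merged = small.data.merge(
            large.data, on=["atom_serial", "partner_serial"], suffixes=("_s", "_l")
        )
        assert len(merged) == len(small.data)  # subset row-wise
        assert (merged["percent_l"] >= merged["percent_s"] - 1e-12).all()

    def test_matches_oracle_on_small_fixture(self, anchor_run):
        topo, traj = anchor_run
        table = bt.electrostatic_contacts(traj, topo)
        atoms = topo.atoms
        foul = np.concatenate([
            topo.role_indices(ROLE_FOULANT_POS), topo.role_indices(ROLE_FOULANT_NEG)
        ])
        poly = np.concatenate([
            topo.role_indices(ROLE_AMMONIUM_N), topo.role_indices(ROLE_SULFONATE_O)
        ])
        sign = {"foulant_pos_atom": 1, "foulant_neg_atom": -1,
                "ammonium_N": 1, "sulfonate_O": -1}
        pairs = [
            (int(i), int(j))
            for i in foul for j in poly
            if sign[atoms.iloc[i]["role"]] * sign[atoms.iloc[j]["role"]] < 0
        ]
        expected = oracle_occurrence(traj, topo.box, range(traj.n_frames), pairs, 4.0)
        got = {
            (
                int(atoms.index[atoms["serial"] == r["atom_serial"]][0]),
                int(atoms.index[atoms["serial"] == r["partner_serial"]][0]),
            ): r["percent"]
            for _, r in table.data.iterrows()
        }
        for pair, pct in expected.items():
            if pct > 0:
                assert got[pair] == pytest.approx(pct, abs=1e-10)
            else:
                assert pair not in got

    def test_by_residue_aggregation(self, anchor_run):
        topo, traj = anchor_run
        table = bt.electrostatic_contacts(traj, topo)
        agg = table.by_residue()
        if len(agg):
            top = agg.iloc[0]
            sub = table.data[table.data["residue_id"] == top["residue_id"]]
            assert top["percent"] == sub["percent"].max()
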