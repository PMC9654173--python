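# brushtraj

Trajectory characterization for grafted zwitterionic polymer-brush surfaces
under foulant adsorption.

The package builds coarse brush-surface models (a rectangular grafting grid
of four-repeat-unit chains with labeled marker atoms), places a rigid charged
foulant on top in one of three orientations, generates synthetic multi-frame
trajectories with scripted dynamics (detach / anchor / penetrate / static),
and computes the full analysis stack:

- **per-chain brush height** from the three marker carbons (clamped
  `max(h1, h2)` per frame, window-averaged),
- **per-chain RMSF** of side-group atoms in the lab frame,
- **hydration-shell counts** of water hydrogens within 3 Å of
  ester/sulfonate oxygens (minimum image),
- **foulant detachment series** (lowest-Cα height change vs. frame 0) and
  component RMSD after Kabsch superposition,
- **occurrence tables** for foulant–polymer electrostatic contacts (4 Å),
  hydrogen bonds (2.4 Å, distance-only) and inter-chain salt bridges, with
  the 5 % neglect floor,
- **mechanism classification** (detached / anchored / penetrated),
- **surface maps**: per-chain values on the grafting lattice with
  periodic-wrapped cavity averaging, bilinear interpolation (5 px per cell)
  and five 5-point smoothing passes.

Coordinates travel as multi-model PDB (one `MODEL` per frame, Å); atom roles
travel in a delimited-text sidecar keyed by atom serial. Two density
presets: low (16 chains, 32 Å spacing) and high (56 chains, 16 Å spacing).

## CLI

```sh
# build a surface and write PDB + role sidecar
brushtraj build-surface --density low --orientation A --out surf

# generate a scripted trajectory (seeded, deterministic)
brushtraj gen-traj --density low --scenario anchor --frames 500 \
    --waters 200 --seed 7 --out run

# analyses (sidecar <prefix>.roles.tsv is picked up automatically)
brushtraj heights    --traj run.pdb --out heights.tsv
brushtraj rmsf       --traj run.pdb --out rmsf.tsv
brushtraj hydration  --traj run.pdb --cutoff 3.0 --out hydration.tsv
brushtraj contacts   --traj run.pdb --cutoff 4.0 --floor 5 --out contacts.tsv
brushtraj hbonds     --traj run.pdb --cutoff 2.4 --out hbonds.tsv
brushtraj interchain --traj run.pdb --out interchain.tsv
brushtraj detachment --traj run.pdb --out detachment.tsv
brushtraj classify   --traj run.pdb
brushtraj map        --traj run.pdb --metric height --window-tag final --out hm

# everything in one go
brushtraj pipeline --density low --scenario penetrate --seed 7 --outdir out/
```

All outputs are delimited text with a provenance header (config hash, seed,
window). Contact commands also write a `.raw` variant without the neglect
floor.

## Library use

```python
import brushtraj as bt

grid = bt.build_grid(100, 32)                       # 16 chains
topo = bt.instantiate_chains(grid)
topo = bt.place_foulant(topo, bt.build_foulant(), "A")
spec = bt.mechanism_presets("anchor", n_frames=1000, water_count=200, seed=1)
topo, traj = bt.generate(topo, spec)

heights = bt.height_profile(traj, topo)
series = bt.detachment_height(traj, topo)
contacts = bt.apply_neglect_floor(bt.electrostatic_contacts(traj, topo))
call = bt.classify_mechanism(series, contacts)
surface = bt.interpolate_and_smooth(bt.build_matrix(heights, topo.grid))
```
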