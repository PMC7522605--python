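# ifacedyn

Interface-dynamics analysis for two-partner protein complexes (an antigen
chain facing an antibody heavy/light pair). The package quantifies a
complex's interface over multi-model PDB trajectories and across replicas:

- **Hydrogen-bond occupancy** — geometric detection (donor–acceptor
  distance < 3.5 Å, H–D–A angle < 30°), per-replica survival ratios,
  max/ave/std replica summaries, a ≥ 0.2 maximum-ratio retention filter,
  and loop classification (N-terminal / BC / FG) of each bond.
- **Buried SASA** — Shrake–Rupley areas with deterministic sphere points;
  interface area as SASA(A) + SASA(B) − SASA(A∪B).
- **Interaction energy** — pairwise Coulomb + Lennard-Jones with a
  CHARMM-style switched 10→12 Å cutoff, parameters from a plain TSV table.
- **Partner-aligned segment RMSD** — Kabsch superposition on the antibody,
  then unrefitted RMSD of the antigen segment.
- **Water accessibility** — distinct waters with oxygen within 4 Å of a
  loop, with replica-level Welch significance comparisons.
- **Scenario construction** — truncate a terminal loop, or rotate a
  segment 90° about a hinge-Cα axis away from the partner (clash-checked),
  turning one native complex into native / N-truncated / N-rotated /
  IgV-rotated variants.
- **Synthetic fixtures** — a toy-complex generator with scripted bond
  on/off schedules (known occupancies), scripted rigid rotations, and
  water shells, so every stage is testable against exact ground truth
  without MD output or downloads.

## Command line

```sh
# synthetic fixture (traj.pdb, params.tsv, truth.json)
ifacedyn synth --preset native --frames 200 --seed 7 --out fixture/

# scenario variant of a native complex, with a clash report sidecar
ifacedyn build-scenario --input complex.pdb --scenario n-rotated \
    --segment P:25-33 --igv P:34-143 --angle 90 --out rotated.pdb

# survival-ratio bond table over replica trajectories
ifacedyn hbonds --traj equ1.pdb equ2.pdb equ3.pdb --side-a P --side-b H,L \
    --dist 3.5 --angle 30 --threshold 0.2 --discard 0.2 --out bonds.tsv

# per-frame buried SASA / energy / H-bond / water series
ifacedyn metrics --traj equ1.pdb --side-a P --side-b H,L \
    --params params.tsv --series metrics.tsv

# recompute max/ave/std + retention from printed per-replica ratios
ifacedyn summarize-table --in src/ifacedyn/data/published_survival_ratios.tsv \
    --system complex_I

# full config-driven run
ifacedyn run --config run.yaml
```

## Layout

| module | role |
| --- | --- |
| `ifacedyn.structure_io` | multi-model PDB read/write, selections, trajectory types |
| `ifacedyn.complex_builder` | truncation, hinge rotations, clash checks |
| `ifacedyn.hbond_analysis` | detection, survival ratios, replica summaries, retention |
| `ifacedyn.interface_metrics` | SASA, interaction energy, Kabsch, aligned RMSD, waters |
| `ifacedyn.replica_stats` | equilibration discard, distributions, Welch comparisons |
| `ifacedyn.synthetic_data` | ground-truth toy complexes, rotations, water shells |
| `ifacedyn.pipeline` | scenario builds, full analysis runs, printed-table ingest |

## Notes

- Residue numbering is author (PDB) numbering; ranges are inclusive on
  both ends.
- The retention threshold is inclusive at 0.20 after rounding the maximum
  ratio to 2 decimals, matching how published tables retain borderline
  rows; replica standard deviations use the sample (n−1) form.
- Geometric H-bond detection requires explicit hydrogens and refuses to
  fall back to a distance-only criterion.
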