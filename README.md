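# shellkit

Analysis toolkit for icosahedral protein nanocompartment shells and their
partial assembly intermediates:

- **`icosa_lattice`** — the rotational icosahedral point group (60
  operators; twofold axes along x/y/z, a fivefold axis in the xz-plane at
  `atan(1/φ) ≈ 31.72°` from +x) and the 60-site T=1 subunit lattice with
  its partition into 30 dimer, 20 trimer and 12 pentamer interface groups,
  labelled adjacency, and minimal local-symmetry operator sets (reference
  excluded: 27 occupied sites → 26 operators).
- **`structure_io`** — PDB/mmCIF models (via biotite), MRC/CCP4 maps
  (self-contained mode 0/1/2 reader/writer with axis-order normalisation),
  and chain → lattice-site assignment by centroid-constellation matching
  (sphere-fit centre, Kabsch, Hungarian matching).
- **`synthetic_shells`** — pseudo-atomic 60-subunit reference shells
  (~23 nm outer diameter), removal-plan partial models, Gaussian-kernel
  density simulation (kernel amplitude halves at 1/resolution) and
  calibrated map noise. Fixture presets reproduce the 48/52/54-subunit
  intermediate occupancy profiles.
- **`occupancy_pipeline`** — masked per-chain map–model cross-correlation
  (soft cosine mask edge), the three-way stability classification
  (cc > 0.75 fully resolved; 0.5–0.75 less resolved; < 0.5 absent),
  occupancy tabulation in the subunit-count convention, and an exhaustive
  dimer-complete profile-consistency search.
- **`interface_energetics`** — Shrake–Rupley SASA on a deterministic
  Fibonacci spiral and buried-surface-area scoring/ranking of the three
  interface classes (BSA is an ordering proxy, not an energy).
- **`assembly_model`** — kinetic Monte-Carlo growth of the shell by dimer
  addition (2³⁰ dimer-subset state space, Philox counter-based RNG), an
  optional detailed-balance variant for equilibrium studies, vacancy-patch
  topology checks, and trajectory statistics against target occupancy
  profiles.
- **`shell_metrics`** — inner/outer shell diameters along symmetry axes,
  axial pore-radius profiles from van-der-Waals surfaces, Kabsch
  superposition RMSD, and global pairwise sequence identity/similarity
  (BLOSUM62, affine gaps, terminal gaps excluded from the denominator).

## Deposited reference data (optional)

Analyses of the deposited models (PDB 7P1T, 9GOT, 9HQ7, 9HQC) and shell
protein sequences (UniProt O07181, B2HH42, K5BEG2, Q9WZP2) read from
`data/deposited/` and `data/sequences/`. Populate them (network required)
with:

```sh
python scripts/fetch_data.py
```

Without these files the corresponding acceptance tests fail with an
explicit diagnostic and the acceptance report omits the affected targets;
everything else runs on synthetic data.

## CLI

```sh
shellkit lattice   --out lattice.json --operators-out ops.txt
shellkit fixtures  --preset 48mer --resolution 4.6 --snr 3 --seed 1 --out fx/
shellkit assign    --model shell.cif --lattice lattice.json --out assign.json
shellkit tabulate  --assign assign.json --out table.tsv
shellkit occupancy --map map.mrc --model model.cif --resolution 4.6 --out occ.json
shellkit interfaces --model shell.cif --max-pairs 3 --out interfaces.tsv
shellkit assemble  --wt -3 --wp 0.5 --beta 1 --n 100 --seed 7 --out traj/
shellkit metrics   --model shell.cif
shellkit seqid     a.fasta b.fasta
```

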