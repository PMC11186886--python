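# crossbeta

Construction and trajectory analysis of twisted cross-β amyloid
protofibril models, built around the amyloid-β (Aβ42) peptide and its
disease-modifying N-terminal variants.

## The scientific problem

Aβ42 protofibrils stack parallel in-register β-strands at a rise of
~4.8 Å along the fibril axis, with two C2-pseudosymmetric layers held
together by steric zippers.  The strands rotate by a small per-strand
twist θ about the axis; the axial length of a half turn — the crossover
distance seen in EM micrographs — is

    n = round(180° / θ),   d_crossover = n · rise

so θ ≈ 2.2°/strand gives 82 strands and ≈ 39 nm.  The hydrophilic
N-terminal domain (residues 1–16) can form an additional β-sheet whose
acidic residues (Asp1, Glu3, Asp7, Glu11 — all at odd positions, hence on
a single face of an in-register strand) together with Arg5, His13 and the
Ala42 C-terminal carboxylate form an *acidic β-sheet domain* that
regioselectively accumulates cations.  Mutations in this region (the
AD-promoting Tottori D7N, the protective rodent R5G/Y10F/H13R) change its
formal charge and its metal-accumulation phenotype.

`crossbeta` provides, as a reusable library plus CLI:

- **Model building** (`crossbeta.builder`): screw-symmetric replication of
  a template strand, C2 two-layer assembly, extended N-terminal grafting,
  periodic-unit sizing (n·θ ≈ 180°), and solvent-ion bookkeeping
  (neutralization + salt concentration + Zn²⁺ equivalents).
- **Morphometrics** (`crossbeta.twist`): fibril-axis estimation,
  per-strand twist, crossover distance, Cα RMSD, steric-zipper distance
  distributions, and the N-to-C terminal Cα distance distribution g(r).
- **Ion analysis** (`crossbeta.ions`): 3.5 Å cutoff contacts per residue /
  strand / frame, enrichment flagging, Zn/Na competition ledgers, and
  time-averaged density grids (OpenDX export).
- **Secondary structure** (`crossbeta.secstruct`): Kabsch–Sander
  hydrogen-bond based assignment (E/B/H/T/C) and per-domain β-sheet
  incidence.
- **Sequence variants** (`crossbeta.sequences`): Aβ42 variant encoding,
  residue classification and exact formal-charge arithmetic.
- **Synthetic data** (`crossbeta.synthetic`): generators with planted
  ground truth (twist, noise, ion enrichment, tail compaction) standing in
  for MD trajectories, so every estimator is validated by parameter
  recovery.
- **Pipeline/CLI** (`crossbeta.pipeline`, `crossbeta` command): YAML-driven
  build → analyze → report runs with cached stages and a self-describing
  JSON report.

## Worked example

```bash
crossbeta report
```

```json
[
  {"variant": "human",   "net_protein_charge_per_strand": -3, "acidic_domain_charge": -4},
  {"variant": "tottori", "net_protein_charge_per_strand": -2, "acidic_domain_charge": -3},
  {"variant": "rodent",  "net_protein_charge_per_strand": -3, "acidic_domain_charge": -4}
]
```

Each Aβ42 strand carries −3 at neutral pH (six acids, three bases, ±1
termini); the Tottori D7N removes one acid (−2), and the acidic β-sheet
domain {1,3,5,7,11,13,42} tallies −4 for human (the rodent R5G/H13R swaps
cancel).  A synthetic twisted fibril analyzed end to end:

```bash
crossbeta synth --n-strands 6 --twist 2.2 --noise-sigma 0.3 --n-frames 10 --seed 1 -o fib.pdb
crossbeta twist fib.pdb --topology fib.topology.csv
```

```json
{"mean_twist_deg": 2.2008, "strands_per_crossover": 82, "crossover_distance_nm": 39.36, ...}
```

The twist estimator recovers the planted 2.2°/strand from the noisy
frames, and the crossover arithmetic turns it into the 82-strand,
≈39.4 nm half-turn morphology.  A multi-stage run is driven by a config
file:

```yaml
seed: 1
stages:
  build: {variant: human, n_per_layer: 18}      # 36-chain two-layer model
  synth: {n_strands: 6, twist: 2.2, noise_sigma: 0.3, n_frames: 10}
  twist: {}
  gofr:  {}
  report: {}
```

```bash
crossbeta run config.yaml -o out/   # out/report.json + per-stage CSV tables
```

The build stage of that report lists 108 neutralizing Na⁺ for the
36-chain model (3 per −3 strand) and a net system charge of 0.

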