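# Methods

This note records the models, conventions and numerical choices behind
`crossbeta`, and what its synthetic-data validation does and does not
demonstrate about real molecular-dynamics data.

## Geometry model

Protofibril models are generated, not fitted: a template strand is
replicated by a screw operation and mirrored into a second layer.

**Template strand.**  The core (residues 17–42) is a planar U-folded
hairpin: an extended segment 17–26, a four-residue chain-reversing turn
27–30, and a returning extended segment 31–42.  The turn dihedrals were
chosen by a one-off grid search over canonical turn motifs to give an
antiparallel return (direction cosine ≈ −0.98) at ≈ 9.5 Å sheet-to-sheet
separation without steric clashes — a steric-zipper-like fold in which the
Ala42 carboxylate ends up near the N-terminal side of the strand.  This
fold is deliberately simplified relative to experimentally determined
β-arches (the two half-strands are coplanar rather than stacked), which is
sufficient for the statistics computed here but not for atomistic
energetics.  Backbone coordinates come from a NeRF internal-coordinate
builder with standard bond lengths/angles; side chains are represented by
Cβ only (plus the C-terminal OXT), so "any atom of the residue" contact
semantics operate on backbone + Cβ.  Amino acids are built L-chiral
(improper N–C–Cα–Cβ ≈ +122°, validated against the CCD ideal residue).

**N-terminal domain.**  Residues 1–16 are grafted in an extended-β
conformation (φ = −139°, ψ = +135°, the ideal antiparallel-sheet values;
configurable).  The prefix is built together with a copy of the anchor
residue and mapped on by least-squares superposition of the anchor's
N/Cα/C, which keeps the junction peptide bond within normal geometry.

**Assembly.**  Strand k of a layer is the template under the k-th power of
the screw (rotation k·θ about the axis, translation k·rise along it;
rise defaults to 4.8 Å).  The layer is lifted off the axis by half the
inter-layer gap (default 10 Å) and duplicated by a 180° rotation about the
axis with a half-rise axial stagger — C2 pseudosymmetry.  Heavy-atom
clashes across the interface warn rather than fail, since downstream
statistics are unaffected.  The periodic-unit size is
argmin over n of |n·θ − 180°| (ties to smaller n): with C2 symmetry the
180°-rotated continuation of the unit is seamless, so θ = 1.915°/strand
gives 94 strands per layer and a box length of 94 × rise.

**Ions.**  `ion_counts` enforces electroneutrality: n_Zn = equivalents ×
chains, n_Cl from concentration × box volume (counts round half away from
zero), and n_Na balances the total charge after rounding.  Note that a
published composition table for one Zn-containing system lists ion counts
that do not sum to neutrality against a −3/chain protein; this builder
always neutralizes and will therefore differ from such a row by
construction.  Random placement keeps a 2.5 Å clearance from protein and
other ions and is reproducible under a fixed seed.

## Estimators

**Fibril axis.**  Per-strand core (17–42) Cα centroids advance by one
rise per strand index within a layer, so the axis is the least-squares
slope of centroid vs strand index, fit per layer and averaged after sign
alignment.  Fitting per layer is essential: pooled PCA would pick up the
lateral offset between the two C2 layers instead of the axis.

**Per-strand twist.**  A per-strand director (default Cα18→Cα26, a stable
core segment; configurable) is projected onto the plane perpendicular to
the axis; the signed angle between consecutive strands' projections
(right-handed about the axis positive) is pooled over layers and averaged.
On noise-free builder output this recovers the input twist to < 10⁻³ °;
at σ = 0.5 Å i.i.d. noise over 100 frames the mean is within ~0.02° of
the planted value.  The measurement is invariant under global rigid
motion because only relative orientations enter.

**Crossover.**  strands = round(180/θ); distance = strands × rise
(round-then-multiply, matching how printed tables do the arithmetic;
an unrounded mode is available).  The rise is an argument: published
crossover tables are consistent with per-model measured rises of
4.72–4.84 Å rather than a fixed 4.8 Å, and this package does not guess
which was used.

**RMSD.**  Cα RMSD with optional optimal superposition (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`).  Coordinates are stored
float32 (the structure-container convention), which bounds exact-recovery
tests at ~10⁻⁵ Å rather than machine epsilon.

**Distance distributions.**  The steric-zipper and N-to-C terminal
distributions are plain normalized histograms (default bin width 1 Å,
g(r) is *not* volume-corrected; its mode is the bin centre of the maximum
bin).  For mode-recovery on ensembles with σ ≈ 3 Å the analysis scripts
use 2 Å bins (≈ Scott's rule at these sample sizes), which caps the
quantization error of the mode at 1 Å; 1 Å bins on such a flat peak make
the argmax bin a coin flip between near-equiprobable neighbours.

**Ion contacts.**  An ion is in contact with a residue if it lies within
3.5 Å (default) of any atom of the residue; minimum-image convention under
periodic boxes.  The engine is a periodic k-d tree; tests assert exact
equality with an all-pairs brute force, including wrap-around.  A bridging
ion counts once per strand in the per-strand ledgers but is credited to
every contacted residue in the per-residue profile (both conventions are
deliberate: the first prevents double-counting in load ledgers, the second
preserves the spatial profile).  Ledger identities hold exactly by
construction: cations = Na + Zn, total ion charge = Na + 2·Zn − Cl.
Enrichment flagging requires a position to exceed 4× the median profile
value *and* be a local maximum — an ion in one residue's contact shell is
usually within the cutoff of its sequence neighbours, so without the
local-maximum condition every flank of a genuine hot spot would be
flagged.  On uniform (λ = 0) baths the false-positive rate is < 5% across
seeds; on planted anchors the flagged set matches the planted set.

**Density grids.**  Frames are aligned to the window's first frame on core
Cα before gridding (1 Å voxels, last-20%-of-trajectory default window);
the stored quantity is occupancy density in ions/Å³, so grid sum × voxel
volume equals the window-averaged in-region ion count (tested to 10⁻⁶
relative).  Published isovalues for such maps do not always state units;
this package documents its own and makes no claim of equivalence.

**Secondary structure.**  Backbone H-bonds use the Kabsch–Sander
electrostatic energy E = 0.42·0.20·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol with the −0.5 kcal/mol threshold, a 9 Å Cα prefilter, and
amide hydrogens reconstructed on the C(i−1)–N / Cα–N bisector at 1.01 Å
when absent.  Bridges follow the standard parallel/antiparallel patterns;
ladders of ≥ 2 consecutive bridges are E, isolated bridges B, i→i+4 runs
H, other turns T, else C (priority H > E > B > T).  On constructed ideal
geometries the labels agree with an independent DSSP implementation
(mdtraj) exactly for the β stack and for all helix-interior residues.
Dihedral-augmented assigners (e.g. STRIDE) can differ by a few points in
absolute β percentages; incidence comparisons should stay within one
method.  β-sheet incidence statistics count label E only (excluding B;
configurable).

## Synthetic data: what it emulates, and what it does not

The generators plant known parameters and expose them in
machine-readable `Trajectory.metadata`:

- `make_fibril_trajectory`: ideal builder geometry + i.i.d. Gaussian
  displacement per atom per frame.  This validates estimator bias and
  variance but has no correlated motion, no thermostat physics, and no
  relaxation — a trajectory whose twist *changes* over time is outside the
  planted model.
- `make_ion_bath`: per frame, each ion is enriched with probability
  λ/(1+λ) (uniform in the 2.0–3.5 Å shell of a random acidic anchor:
  Asp/Glu Cβ and the C-terminal carboxylate oxygens; anchor set
  restrictable) or uniform in the box.  Placements are independent across
  frames, so time correlations of real ion binding are absent; an optional
  exponential approach 1 − exp(−rate·t) of the enriched fraction emulates
  attachment kinetics for saturation/rate-fitting tests.
- `make_tail_ensemble`: N-terminal tails rebuilt per strand per frame at a
  compaction solved against a per-strand lookup of compaction → Cα1–Cα42
  distance, targeting draws from a Gaussian (folded 30 ± 3 Å, extended
  43 ± 3 Å; explicit pairs accepted); clashing rebuilds are redrawn, core
  atoms are bit-identical untouched.  The tails move rigidly per frame
  with no chain-to-chain interactions.

Randomness is split into three independent substreams (geometry noise, ion
placement, tails) spawned from one seed, so adding one component never
perturbs another; identical spec + seed is bit-reproducible.

Passing recovery tests on these generators shows the *estimators* are
correct and unbiased under known conditions; it does not reproduce
MD-derived observables (per-domain β percentages, per-strand ion loads,
g(r) maxima of real trajectories), which depend on 100-ns all-atom
simulations of 10⁵–10⁶-atom systems and are out of desk scale.  Problem
sizes used by the shipped analyses — 8–24 strands, 10–125 frames, tens of
ions — are the package's validation conditions, chosen so the statistical
targets above (e.g. twist within 0.05°, modes within 1 Å) are met with
margin.

## Other conventions and limitations

- Units: Å and ps throughout; 1-based Aβ numbering (1–42); orthorhombic
  boxes only.
- Formal charges: neutral-pH regime with His as the neutral Nδ tautomer;
  Asp/Glu −1, Arg/Lys +1, N-terminal amine +1, C-terminal carboxylate −1.
  In per-domain ledgers the C-terminal carboxylate is attributed to
  position 42, but the N-terminal amine is **not** attributed to position
  1 — it belongs to the backbone terminus.  This is the only convention
  consistent with net −3/−2/−3 alongside acidic-domain −4/−3/−4 across the
  three variants, and it makes domain charges additive with
  net = Σ(partition) + 1.
- Glycine is classed "polar" in the four-way residue colouring by default
  (configurable); custom sequences must be exactly 42 residues so Aβ
  numbering stays unambiguous.
- Chain ids cycle through a 62-character alphabet in PDB output; strand
  identity is carried by a sidecar topology CSV (chain, layer,
  strand_index) and, failing that, reconstructed from chain-id change
  boundaries (strands are contiguous atom blocks).
- The curvature (arching) metric is the max residual of per-layer strand
  centroids from their own best-fit 3D line; it is reported for
  completeness but has no reference value to compare against.
- No force fields, no explicit solvent, no energy minimization, no MD:
  models are geometric constructs for analysis-method validation and
  visual inspection.
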