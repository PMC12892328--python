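# Methods

This note documents the modelling choices behind `pkagraph`: what each
stage assumes, which parameters matter and why their defaults are what
they are, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Scope and data model

The package predicts the pKa of the four ionizable residue types Asp,
Glu, His and Lys from a protein structure plus a table of per-atom
induced dipole moments.  Cys, Tyr and chain-terminal residues are out of
scope, as are structure repair, protonation assignment and the
computation of the dipoles themselves — the dipole table is an input,
expected to come from a polarizable-force-field energy minimization.
Dipoles are stored in Debye; a table tagged C·m is divided by
3.33564e-30 on ingest.  Coordinates are Angstrom everywhere.

PDB ingest drops water HETATM records and keeps other heteroatoms
(ions, cofactors) with their element parsed; they can occlude surface
and contribute to neighbor counts but never become graph nodes.  A
hydrogen is classified as backbone iff its covalent partner — from
explicit connectivity when available, else the nearest heavy atom within
1.2 A — is a backbone heavy atom (N, CA, C, O); this puts both the amide
H and HA on the backbone side of the atom-type one-hot.

## Local frame

The frame is built from three anchors of the target residue only:
origin at Calpha, e_x along Calpha->C, e_z = unit(e_x x unit(O - C)),
e_y = e_z x e_x.  Using only the residue's own carbonyl group (rather
than atoms of residue i+1) keeps the frame computable next to chain
termini; the peptide-plane argument is the physical motivation, not part
of the construction.  The cross-product order fixes the handedness so
the carbonyl O lands at positive local Y — (2.163, 1.054, 0) for ideal
geometry — and the frame determinant is +1 always (no reflections).
Degenerate anchors (|C - Calpha| <= 0.5 A, or O within 1e-6 of the
Calpha->C line) raise rather than produce an ill-conditioned frame.

Dipole vectors are rotated into the local frame (rotation only, no
origin shift).  Leaving them in the global frame would silently break
the pose invariance that is the frame's entire purpose; this is a
deliberate design decision, configurable nowhere.

## Microenvironment descriptors

* **Crop.**  The environment is the closed ball of radius r around the
  target Calpha, r in {7, 8, 9, 10, 11} A by convention (any positive
  value is accepted).  Atoms exactly at distance r are included.
* **Neighbor counts** (features 11–14) count context heavy atoms C/N/O/S
  within a radius of *each atom*.  The counting radius defaults to the
  dataset's crop radius — one radius per dataset variant, giving four
  count features; any radius list can be configured.  Target-residue
  atoms never count.
* **Hydrogen bonds** (features 15–16) use a fixed geometric criterion:
  donor and acceptor are N or O in different residues, H···acceptor
  <= 2.5 A, donor–H–acceptor angle >= 120 deg.  Both thresholds are
  configurable; the defaults are the widely used geometric test.
  Structures without hydrogens simply yield zero counts.
* **SASA** (feature 17) is a Shrake–Rupley estimate: 960 deterministic
  golden-spiral points per atom on the solvent-expanded sphere
  (r_vdw + 1.4 A probe; vdW radii C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20).  SASA is computed on the *full* structure and reported for
  target-residue atoms — cropping first would fabricate exposed surface
  at the sphere boundary.  The quadrature directions are expressed in
  each residue's own local frame, which makes the estimate exactly
  covariant under rigid motion of the structure (a globally fixed point
  set would be invariant only to within quadrature noise); residues
  without valid frame anchors fall back to the global axes.

## Graph assembly and normalization

Nodes are the target residue's atoms, hydrogens included; the
environment enters only through features 11–17.  Edges are intra-residue
covalent bonds — from explicit Tinker connectivity when present, else a
per-residue-type bond template, else a distance fallback (heavy–heavy
<= 1.9 A, X–H <= 1.2 A) — plus a self-loop on every node.  The residue
one-hot is ordered alphabetically (ASP, GLU, HIS, LYS); sulfur gets a
single atom-type slot with no backbone/side-chain split, which is what
makes the 9-slot atom-type block close the 26-feature budget.

Features 11–16 are min–max scaled to [0, 1] with extrema pooled over all
nodes of all graphs; constant slots map to 0.  Min–max (rather than
z-scoring) keeps zero counts at exactly zero and respects the features'
hard lower bound.  Coordinates, dipoles and SASA keep their physical
scales: the network is allowed to see absolute geometry.  The stored
constants are reapplied verbatim at inference.

## Architectures and training

All three networks are input layer -> one hidden layer -> output stage:

* **GCN** — two convolutions (26->hidden with ReLU inside the layer,
  hidden->1 linear), then mean pooling.  The degree in the 1/sqrt(d_i d_j)
  normalization counts the closed neighborhood, matching the adjacency's
  unit diagonal.  No activation after the output layer: a regression
  head must reach pKa values both above 12 and below 0 shifts.
* **GIN** — aggregation over the open neighborhood with the (1+eps) self
  term (eps initialized to 0, learnable), a linear–ReLU–linear MLP with
  both widths equal to hidden_channels, ReLU + dropout, mean or add
  pooling, linear head.
* **GATv2** — multi-head attention layer (26->hidden per head, heads
  concatenated), ReLU + dropout, a second single-head attention layer to
  width 1, mean pooling.  LeakyReLU slope 0.2; attention rows are
  normalized over the closed neighborhood with a detached row-max
  subtracted before exponentiation as an overflow guard.

Weights are Glorot-uniform, seeded from the config; evaluation is
deterministic, dropout acts only in training.  Batches stack graphs of
equal node count into one tensor (residue graphs of one type share a
template size, so bucketing is cheap).  Training is Adam at the
configured learning rate and batch size; after each epoch the validation
loss (same loss kind as training) is evaluated, and training stops after
20 epochs without improvement, restoring best-epoch weights.
max_epochs defaults to 500.  Grid axes follow the standard sweep
(hidden 16/32/48/64, batch 16/24/32/40, dropout 0.2–0.5, three losses,
GIN pooling, GAT heads 4/6/8); learning-rate lists are free-form.

Everything runs on a ~300-line reverse-mode autodiff engine over NumPy
(`pkagraph/_autodiff.py`): broadcasting arithmetic, batched matmul, the
needed nonlinearities, reductions and concatenation, with gradients
checked implicitly by the training tests (loss decreases, planted
mechanisms are recovered) and explicitly by the dense-oracle layer
tests.

Cross-validation partitions graphs into k near-equal seeded random
folds (stratification by residue type is available but off by default,
since plain random splits are the simpler protocol); each fold's model
early-stops on its own held-out fold, and metrics are pooled over the
held-out predictions so every graph is scored exactly once.

## Evaluation suite

MAE and RMSE overall and per residue type; a quantile report that
buckets pairs by |experimental shift| = |pKa_exp - reference(type)| into
left-closed/right-open intervals on caller-supplied boundaries (defaults
0.2 / 0.5 / 1.0, with an open-topped last bucket so nothing is dropped)
with Q_last/Q_first ratios; the null model returning the type reference
(Asp 3.7, Glu 4.2, His 6.5, Lys 10.4); and the Pearson correlation of
predicted vs experimental shifts, which is the honest headline number
when most labels sit near their references.  Normal-approximation CIs
(mean ± 1.96 sd/sqrt(n)) cover small-test-set reporting; bootstrap CIs
are out of scope.

## Explainer

The masking objective for a regression model is

    (f(A o M_e, X o M_f) - f(A, X))^2
      + lambda1 * mean(M_f) + lambda2 * sum(H_b(mask entries))

with sigmoid-parameterized masks (so they stay in [0, 1] at every step),
H_b the binary entropy, lambda1 = 0.05, lambda2 = 0.01, 200 Adam steps
at lr 0.05 by default, convergence when the objective moves < 1e-6.
The squared-deviation fidelity term is the regression surrogate for the
conditional-entropy term of the classification-oriented formulation.
The feature mask is shared across a graph's nodes (26 values, not
N x 26), matching per-feature importance profiles; the edge mask is
symmetrized.  Logits start near 0 (masks near 0.5, where the entropy
term is flat) so that the sparsity penalty pushes unused entries down
while fidelity pulls load-bearing entries up; a slot with zero fidelity
gradient can occasionally drift to 1 on a single graph, which is why
importance is read from the aggregated (mean, max-rescaled) profile
rather than single-graph masks.

## Synthetic fixtures and what they show

The generator builds peptides from ideal-geometry residue templates:
Calpha–C 1.53 A, C=O 1.23 A, Calpha–C–O 121 deg, exactly planar
carbonyl, standard bond lengths elsewhere, one fixed clash-free rotamer
per type.  Residues are chained with 1.33 A peptide links and small
random inter-residue rotations, keeping Calpha–Calpha spacings in the
3.0–4.2 A band of real backbones; GLY/ALA spacers interleave the
ionizable residues so the context-count features are non-trivial.  Every
atom gets an isotropic N(0, 0.5 Debye) dipole.  Planted labels are
reference(type) + c · mean-pooled node features + N(0, sigma), with a
sparse default c emphasizing SASA, oxygen/carbon neighbor counts, the
local x coordinate and the dipole x component — a caricature of burial
and local electrostatics — scaled so shifts span roughly ±2 pKa units.

What the fixtures do **not** emulate: real rotamer diversity, tertiary
packing, inter-residue hydrogen-bond networks (the extended toy chains
rarely satisfy the H-bond criterion, so features 15–16 are mostly zero
there), solvation structure, or any genuine electrostatic physics in the
dipoles.  Passing the recovery tests therefore demonstrates that the
pipeline is wired correctly end-to-end — features carry the planted
signal, the networks can learn it, CV bookkeeping is honest — not that
the models predict real protein pKa values; performance on experimental
corpora must be established with real training data through the same
code paths.

Recovery experiments use 400 graphs at sigma = 0.3 with a small fixed
configuration (hidden 16, dropout 0.2, MSE, lr 0.01, batch 32, 10-fold
CV, max 150 epochs): large enough that all three architectures reach the
noise floor, small enough to run on one CPU in minutes.  The noise sweep
sigma in {0, 0.3, 0.6} checks that pooled CV MAE is non-decreasing in
label noise at the same seeds.

## Numerical choices and degenerate inputs

* Frame construction errors on coincident/collinear anchors instead of
  returning a near-singular basis.
* Min–max normalization maps constant slots to 0 (no division by zero).
* Softmax attention subtracts a detached row max; exp/sigmoid inputs are
  clipped at +-700 / +-60.
* Empty graphs cannot be pooled, empty datasets cannot be normalized or
  saved, k > n cross-validation is rejected — all explicit errors.
* Graphs with missing dipoles featurize with zero-filled dipole slots
  and a logged warning; residues failing frame construction are skipped
  with a recorded reason rather than aborting the dataset build.
* SASA needs at least 16 quadrature points; the fixed golden-spiral set
  keeps results bit-reproducible for a given point count.

## Known limitations

* The atomic graphs have no inter-residue edges and no edge features;
  the environment is visible only through scalar node features.
* SmoothL1/L1/MSE are the only losses; no uncertainty estimates beyond
  the normal-approximation CI.
* The NumPy autodiff engine is single-threaded and tuned for the small
  graphs of this problem (tens of nodes); it is not a general-purpose
  training stack.
* Tinker .xyz carries no residue metadata, so structures read from it
  alone cannot be featurized per-residue without a companion PDB; the
  reader exists to import connectivity and coordinates.
* The explainer's per-graph masks can saturate a zero-gradient slot;
  interpret aggregated profiles, not single graphs.
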