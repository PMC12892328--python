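# pkagraph

Residue-centric protein pKa prediction with atomic graph neural networks.

## The problem

The pKa of an ionizable side chain (Asp, Glu, His, Lys) sets its
protonation state at a given pH and with it much of a protein's
electrostatics, catalysis and stability.  Buried or strongly interacting
residues can shift several pKa units away from their model-compound
references (Asp 3.7, Glu 4.2, His 6.5, Lys 10.4) — exactly the residues
that matter in enzyme active sites — and predicting those shifts from
structure is a long-standing problem.

`pkagraph` treats each ionizable residue as a small atomic graph and
regresses its pKa with a graph neural network.  The package is aimed at
structural bioinformaticians who want an end-to-end, fully testable
pipeline: structure in, per-residue graphs out, three trainable GNN
architectures, a benchmarking suite, and a feature-importance explainer.

## The method

**Local coordinate frame.**  For a target residue, place the origin at
C&alpha;, take **e**<sub>x</sub> = unit(C &minus; C&alpha;) along the
carbonyl bond, **e**<sub>z</sub> = unit(**e**<sub>x</sub> &times;
unit(O &minus; C)) normal to the carbonyl plane, and
**e**<sub>y</sub> = **e**<sub>z</sub> &times; **e**<sub>x</sub>.  Every
atom position (and every induced-dipole vector) is re-expressed in this
right-handed orthonormal frame, so the representation is invariant to
the protein's global pose: C&alpha; sits at (0, 0, 0), the carbonyl C at
(1.53, 0, 0) and the carbonyl O near (2.17, 1.06, 0) for ideal geometry.

**Residue graph.**  Nodes are the atoms of the target residue itself
(hydrogens included); edges are its covalent bonds plus a self-loop on
every node.  Each node carries 26 features: residue-type one-hot (4),
local-frame coordinates (3), local-frame induced dipole components in
Debye (3), counts of context heavy atoms C/N/O/S within the crop radius
(4), hydrogen bonds as acceptor and as donor (2), atomic SASA (1), and
an atom-type one-hot splitting N/C/O/H into backbone vs side chain plus
one sulfur slot (9).  The surrounding microenvironment — all atoms
within a 7–11 &Aring; sphere of C&alpha; — enters only through the
count / H-bond / SASA features.  Count and H-bond slots are min–max
normalized dataset-wide.

**Regressors.**  Three message-passing layers, each implemented exactly
as its update equation and verified against literal dense evaluations:

- GCN: h&prime;<sub>i</sub> = ReLU( &Sigma;<sub>j&isin;N(i)&cup;{i}</sub>
  W h<sub>j</sub> / &radic;(|N(i)||N(j)|) ) with closed-neighborhood degrees;
- GIN: h&prime;<sub>i</sub> = MLP( (1+&epsilon;) h<sub>i</sub> +
  &Sigma;<sub>j&isin;N(i)</sub> h<sub>j</sub> ) with a learnable &epsilon;;
- GATv2: &alpha;<sub>ij</sub> &prop; exp( a&#7488;
  LeakyReLU(W<sub>s</sub> h<sub>i</sub> + W<sub>t</sub> h<sub>j</sub>) ),
  normalized over the closed neighborhood, heads concatenated.

Each network is input layer &rarr; one hidden layer (ReLU, dropout)
&rarr; output stage with global mean (or add) pooling to a single pKa.
Training is mini-batch Adam with 10-fold cross-validation and early
stopping (patience 20); a grid search covers hidden width, batch size,
learning rate, dropout, loss (SmoothL1 &beta;=0.5, L1, MSE), GIN pooling
and GAT head count.

**Evaluation.**  MAE/RMSE overall and per residue type; a rolling
quantile segmentation of |&Delta;pKa<sub>exp</sub>| (default cuts 0.2 /
0.5 / 1.0) with Q4/Q1 ratios; a null model predicting each type's
reference pKa; and the Pearson R between predicted and experimental
shifts.

**Explainer.**  A mutual-information-style masking optimization: a
shared 26-entry feature mask and a per-edge mask (sigmoid-parameterized,
in [0, 1]) are fitted so the masked graph reproduces the model's
prediction while staying sparse; aggregated masks give per-feature
importance profiles.

Induced atomic dipole moments are *inputs* (a TSV of per-atom 3-vectors
from a polarizable-force-field minimization); the package never computes
them.

## Worked example

Generate a synthetic planted-mechanism dataset (labels are a known
linear readout of the features plus N(0, 0.3) noise) and cross-validate
a GCN:

```python
>>> from pkagraph import ModelConfig, cross_validate
>>> from pkagraph.synthetic_fixtures import make_planted_dataset
>>> graphs, record = make_planted_dataset(n_graphs=120, noise_sd=0.3, seed=42)
>>> len(graphs), graphs[0].node_features.shape
(120, (12, 26))
>>> cfg = ModelConfig(architecture="GCN", hidden_channels=16, dropout_rate=0.2,
...                   loss="mse", learning_rate=0.01, batch_size=32, seed=0)
>>> cv = cross_validate(graphs, cfg, k=5, seed=0, max_epochs=150, patience=20)
>>> print(cv.summary())
5-fold cross-validation, GCN
n = 120   MAE = 0.275   RMSE = 0.339   shift R = 0.969
  ASP: MAE 0.279  RMSE 0.350
  GLU: MAE 0.301  RMSE 0.356
  HIS: MAE 0.240  RMSE 0.307
  LYS: MAE 0.280  RMSE 0.341
  Q1 |dpKa| in [0.00, 0.20): n=9  MAE 0.431  RMSE 0.447
  Q2 |dpKa| in [0.20, 0.50): n=19  MAE 0.262  RMSE 0.337
  Q3 |dpKa| in [0.50, 1.00): n=31  MAE 0.210  RMSE 0.248
  Q4 |dpKa| in [1.00, inf): n=61  MAE 0.289  RMSE 0.360
  Q4/Q1 ratios: MAE 0.67  RMSE 0.81
```

The pooled MAE of 0.275 sits close to the noise floor of the planted
labels (mean |N(0, 0.3)| &asymp; 0.24), i.e. the network has recovered
essentially all of the planted structure–pKa mechanism; the shift
correlation R = 0.97 says the *shifts*, not just the type references,
are being predicted.  Held-out predictions, per-fold histories and the
same report as JSON are available on the returned result object.

The same pipeline runs from the shell:

```bash
pkagraph simulate --n-residues 16 --seed 7 --out-dir runs/sim
pkagraph build-dataset --structure runs/sim/toy.pdb \
    --dipoles runs/sim/toy_dipoles.tsv --labels runs/sim/toy_labels.csv \
    --radius 9.0 --out-dir runs/ds
pkagraph train --dataset runs/ds/dataset.json --architecture GAT \
    --hidden 16 --seed 1 --out-dir runs/gat
pkagraph explain --model runs/gat/model.json --dataset runs/ds/dataset.json \
    --seed 1 --out-dir runs/explain
```

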