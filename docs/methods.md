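# Methods

This note documents the modeling choices, defaults and limitations of
molfuse in the package's own terms. Nothing here reports an empirical
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Molecular inputs

SMILES strings are canonicalized with RDKit; a record is valid iff it parses
to a molecule with at least one heavy atom. Cleaning removes invalid records
and canonical-SMILES duplicates, keeping the **first** occurrence of each
duplicate group; conflicting labels within a group are logged, never merged.
Cleaning is idempotent and its report reconciles
(`n_output = n_input − n_duplicates − n_invalid`).

One conformer per molecule is embedded with ETKDG distance geometry followed
by Universal-Force-Field optimization ("general force field" is read as UFF;
MMFF94 is available via `force_field="mmff"`). Embedding runs with explicit
hydrogens and keeps only heavy-atom coordinates. If embedding fails the
record falls back to the planar 2D layout with z = 0 and is flagged rather
than dropped, so pipelines never silently shrink. Embedding is deterministic
per seed; in dataset context each record gets a seed derived from the
dataset seed and its position, so results do not depend on neighboring rows.

## Feature schemas (136 / 39)

The atom- and bond-feature widths (136 and 39) are the binding contract; the
block composition is declared in `molfuse.graphs` and hashed into every
checkpoint:

* **Atom (136)**: element one-hot over atomic numbers 1–83 plus "other"
  (84); degree 0–6+other (8); formal charge −2…+2+other (6); chirality tag
  (4); hybridization (7); total-H count 0–4+other (6); total valence
  0–6+other (8); radical electrons (4); aromatic flag (1); ring flag (1);
  ring-size 3–8 flags (6); atomic mass / 100 (1).
* **Bond (39)**: bond-type one-hot incl. aromatic + other (5); conjugation
  (1); ring flag (1); stereo one-hot (6); ring-size 3–8 flags (6);
  symmetrized end-atom element counts over {C,N,O,S,P,F,Cl,Br,I,other} (10);
  end-atom aromatic count one-hot (3); end-atom hybridization counts (4);
  rotatable flag (1); both-ends-in-ring flag (1); bond length in Å from the
  embedded coordinates (1).

End-atom blocks are counts over the unordered atom pair, so bond features
are independent of bond orientation. Bond length is measured from the
embedded conformer, not a tabulated ideal length. All feature entries are
invariant under rigid motion of the coordinates (the only geometric entry is
a distance). Hydrogens are implicit — never graph nodes — so `N` is always
the heavy-atom count. The bond graph is the line graph of the atom graph
(bonds adjacent iff they share exactly one atom); its node coordinates are
bond midpoints, which gives the bond channel a geometry that transforms
exactly like the atom channel's.

## Encoder

Per graph channel: a GCN stack (default 2 layers, ReLU, no bias) over
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}` (the standard symmetric normalization; it is the
form that preserves symmetry and row-stochasticity on regular graphs), then
a learned CLS row is prepended, then `encoder_blocks` (default 3) blocks of
[equivariant graph operation → multi-head self-attention with residual +
layer norm]. The CLS row is excluded from all geometric computation and
never acquires coordinates. Attention weights are the standard
`softmax(QKᵀ/√d_k)` — the value matrix enters only once, in the output
product — with 4 heads by default; each block's weights are retained
(detached) for interpretability.

Equivariant operation defaults, all config-exposed:

* **Neighborhood**: the complete graph over the channel's nodes
  (`egnn_neighborhood="full"`). Bonded-only neighborhoods
  (`"bonded"`) are supported, but bonded distances are nearly constant in
  optimized geometries, so the complete graph is what lets the geometric
  channel see shape (it is also the standard choice for E(n)-GNNs on small
  molecules). Equivariance and permutation-invariance hold either way.
* **Coordinate update**: degree-normalized mean of `w_ij (x_j − x_i)`
  (`coord_update="mean"`), keeping updates bounded as molecules grow; the
  plain sum is available via `"sum"`. `w_ij` passes through tanh to bound
  step sizes. Isolated nodes keep their coordinates.
* Squared distances are scaled by 0.1 before entering `φ_e` (squared
  Ångström distances are O(10); this keeps MLP inputs O(1)).

Variants: `GCN` (convolution stack + mean pooling, no transformer), `Atom`,
`AtomBond`, `FP`, `AtomBondFP`, `Full` (the only variant with the
equivariant operation) and `Mini` (Full minus the equivariant operation).
A bondless molecule (e.g. methane) degenerates the bond channel to attention
over the CLS row alone, which is well-defined and finite.

Fusion is concatenation of channel embeddings — no gating — into a
two-layer FNN head. Classification outputs are per-task sigmoid
probabilities; regression targets are z-scored with training-set statistics
and predictions de-standardized. Real-valued fingerprint columns (EState,
ErG) are likewise z-scored with training-set statistics; binary columns pass
through.

## Training

Masked binary cross-entropy (classification) or masked MSE on standardized
targets (regression); molecules with all-missing labels contribute exactly
zero gradient. Adam, lr 1e-3, batch size 32, dropout 0.1 (fingerprint
channel and fused embedding), early stopping on the validation metric
(ROC-AUC up / RMSE down) with patience 20 and best-epoch restoration.
`TrainSettings.target_val_metric` optionally stops a run once the validation
metric reaches a requested level. Everything — parameter init, batch order,
dropout, splits, noise — derives from explicit integer seeds; two runs with
the same seed produce identical histories.

The whole stack is float64 NumPy with a small tape-based reverse-mode
autodiff (`molfuse.nn`); hot paths (attention, layer norm, graph
convolution, affine maps) are fused single-tape ops with hand-written
backward rules, each verified against central finite differences in the test
suite.

## Protocol harnesses

* **Splits**: 8:1:1 by default. Random splits draw a seeded permutation with
  floor-allocated validation/test sizes and the remainder to train
  (maximizes training data, deterministic). Scaffold splits group by
  Bemis–Murcko scaffold, never straddle a group across partitions, and fill
  train, then validation, then test, largest groups first with seeded
  tie-shuffling — common benchmark practice.
* **Label noise**: flips exactly `round(rate · n_eligible)` labels where
  eligible entries are the non-missing train∪validation labels (equal to
  `round(rate · |train∪val|)` for complete single-task data), after
  splitting, so the test partition is provably clean. Missing labels are
  never flipped.
* **Fingerprint selection**: all C(8,k) combinations for k ∈ {1,2,3}, one
  fingerprint-only FNN per combination per seed — identical architecture,
  only the input width varies — ranked by mean test metric, with a tally of
  family membership in the top-3 combinations.
* **Ablation**: the six-variant grid trained on the same seeded splits
  (verifiable via a split index hash), reporting mean ± sd of the task
  metric.

ROC-AUC / PRC-AUC are computed with scikit-learn behind the package's metric
functions; one-class inputs raise an explicit undefined-metric error and are
reported as missing, never as 0.

## Synthetic fixtures

The generator assembles molecules from a curated pool of 20 drug-like
fragments (aromatic and saturated rings, heteroatom chains, halides, amides,
…) joined by single bonds at free-valence atoms through a seeded grammar —
validity is guaranteed by construction, outputs are canonical and
deduplicated. Three label modes emulate the label structure of
property-prediction benchmarks:

* `motif_classification`: label 1 iff the molecule matches a SMARTS motif
  (default benzene), optionally flipped with probability `noise_rate` —
  substructure-driven activity;
* `additive_regression`: a fixed per-element contribution sum plus Gaussian
  noise — additive physicochemical properties;
* `geometry_regression`: heavy-atom radius of gyration of the embedded
  conformer plus noise — a conformation-dependent property whose signal
  exists **only** in the 3D geometry, which is what makes the equivariant
  channel's contribution measurable against the EGNN-free variants.

What passing on these fixtures does and does not show: it demonstrates the
machinery — featurization, symmetries, optimization, protocol bookkeeping,
attention extraction — on cleanly separable or analytically constructed
signals. It does not demonstrate accuracy on real assay data, whose label
noise, activity cliffs, scaffold skew and class imbalance the generator does
not attempt to match.

## Experiment sizes and defaults

Architecture defaults are hidden 256, 2 GCN layers, 3 encoder blocks,
4 heads, dropout 0.1. The packaged experiments (tests and
`scripts/acceptance.py`) run desk-scale configurations — hidden 32, 2
encoder blocks, 160–500 molecules, 5 seeds — chosen so every experiment
re-runs from scratch in minutes on one CPU while preserving the qualitative
contrasts of interest (separable motif learning, Full vs AtomBondFP on
geometry, attention localization, noise degradation). The interpretability
experiment trains the `Atom` variant so the gradient signal necessarily
flows through the attention channel being inspected; attention saliency is
the final block's CLS query row, head-averaged, CLS self-entry dropped and
renormalized to sum 1 (per-head and per-block extraction available).

## Known limitations

* One conformer per molecule; conformational ensembles are out of scope.
* The fingerprint channel dominates easily fingerprint-separable tasks, so
  attention maps from fused variants can be diffuse; interpretability
  studies should use graph-channel variants or verify saliency stability.
* No pretrained weights, GPU kernels or uncertainty estimates.
* The NumPy training loop is adequate for datasets up to a few thousand
  molecules; it is not a large-scale training engine.
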