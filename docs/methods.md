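# Methods

This document records the model, the exact formulas implemented, the
configuration constants, and the numerical and scope decisions behind
`ifaceqe`.

## Problem statement

Given a structural model of a two-chain (dimeric) protein complex, estimate
its interface quality without access to the native structure at prediction
time. The estimator is trained on decoy models whose true quality is known,
learns to regress per-contact quality, and aggregates the per-contact
predictions into a single score Q in (0, 1) that should rank models the way
DockQ would.

## Interface graph

A model's interface graph contains one node per **interface residue** — a
residue whose interaction coordinate lies within 10 Å of some residue on
the partner chain — and one undirected edge per inter-chain residue pair
within that cutoff. The interaction coordinate is the Cβ atom, or Cα for
glycine; when a Cβ is missing it is reconstructed from the backbone N, Cα
and C atoms with ideal tetrahedral geometry. Intra-chain edges are never
added: quality estimation concerns the inter-chain interface only. A model
with no inter-chain pair under 10 Å has an empty graph; such models are
excluded from training and scored Q = 0.

## Node features (17 per residue)

| Slice | Width | Content |
|---|---|---|
| 0–4 | 5 | one-hot physicochemical residue class (polar, nonpolar, positive, negative, other/non-standard) |
| 5 | 1 | relative sequence position, `seq_index / chain_length` |
| 6–8 | 3 | one-hot secondary structure (helix / strand / coil), from DSSP when a file is supplied, otherwise from a backbone-torsion window heuristic |
| 9–10 | 2 | one-hot burial state: relative solvent accessibility below / above 0.25, from DSSP accessibility or an internal Shrake–Rupley calculation on the backbone + Cβ representation, normalized by per-residue maximum ASA |
| 11–14 | 4 | sin/cos of the backbone torsions φ and ψ (zeros at chain termini) |
| 15 | 1 | normalized effective sequence count (Neff / √L) of the residue's own chain's MSA |
| 16 | 1 | normalized Neff of the paired (two-chain) MSA, shared by all nodes |

MSA inputs are optional; without them the evolutionary entries fall back to
neutral constants so the feature width is always exactly 17.

## Edge features (27 per contact)

| Slice | Width | Content |
|---|---|---|
| 0–16 | 17 | one-hot distance bin: bins 1–16 cover [2 Å, 10 Å) in 0.5 Å steps; bin 17 is the sub-2 Å clash bin. Distances ≥ 10 Å cannot be edges. |
| 17–26 | 10 | sin/cos of five inter-residue orientation angles (below) |

The five orientation angles for residues *i*, *j* with frames
(N, Cα, Cβ):

- **Ω** — dihedral Cαᵢ–Cβᵢ–Cβⱼ–Cαⱼ (symmetric under order swap),
- **τ₁₂, τ₂₁** — dihedrals Nᵢ–Cαᵢ–Cβᵢ–Cβⱼ and Nⱼ–Cαⱼ–Cβⱼ–Cβᵢ
  (exchanged under order swap),
- **λ₁₂, λ₂₁** — planar angles Cαᵢ–Cβᵢ–Cβⱼ and Cαⱼ–Cβⱼ–Cβᵢ
  (exchanged under order swap).

All five are invariant to rigid motion of the complex (verified to 1e-9 in
the test suite). Degenerate (collinear) geometry yields all-zero sin/cos
pairs rather than NaNs. For glycine the orientation Cβ is the
reconstructed virtual Cβ.

## Edge quality labels

For an edge with model distance *d* and the same residue pair's distance
*d\** in the native structure:

```
z = 1                                 if d < 10 Å and d* < 10 Å
z = 1 / (1 + ((d − d*) / d0)²),       d0 = 10 Å, otherwise
```

so z ∈ (0, 1]; e.g. z = 0.2 at |d − d*| = 20 Å. Residue correspondence
between model and native is by chain and sequence index.

## Network

A 4-layer multi-head graph attention network over the interface graph:

- layer widths 32, 16, 8, 4 with 4, 4, 4, 1 heads (head outputs
  concatenated, so hidden node embeddings have 128, 64, 32, 4 entries);
- each layer transforms, per directed edge (j → i), the source embedding
  concatenated with the raw edge features, `z_ij = W [h_j ‖ e_ij]` — edge
  features enter both the messages and the attention mechanism;
- attention logits are a LeakyReLU (slope 0.2) of a learned linear map of
  the destination-side and source-side transformed vectors, normalized
  with a softmax over each destination node's in-neighbours (rows sum to
  1 exactly);
- ReLU between layers; the final layer is linear (one head);
- per-edge score: the logistic sigmoid of the dot product of the two
  endpoint embeddings, `s_ij = σ(h_i · h_j)` ∈ (0, 1);
- overall quality: `Q = mean(s_ij)` over the graph's edges.

Q is invariant to node relabeling by construction (verified in the tests).
The network is implemented directly in NumPy with an analytic backward
pass; the analytic gradients agree with central finite differences to a
relative error below 1e-4 (worst parameter, 6-node graph).

## Training

- Loss: **sum-reduced** squared error between predicted edge scores and
  labels z.
- Optimizer: Adam, learning rate 0.001, L2 weight decay 0.0005 added to
  the gradient, β = (0.9, 0.999), ε = 1e-8.
- Xavier (Glorot) initialization at every layer.
- At most 500 epochs with early stopping at patience 40 on validation
  loss; the returned parameters are those of the best validation epoch.
- The validation split is taken at the **target** level so decoys of one
  complex never straddle the split (default validation fraction 0.1).
- Optimizer steps use minibatches of 8 graphs with summed gradients.
  This choice is load-bearing: with single-graph steps, the roughly half
  of decoy graphs whose labels are all exactly 1 push the sigmoid head
  into saturation (every per-graph optimum is at an infinite logit), the
  model collapses to Q ≈ 1 everywhere, and early stopping fires during
  the resulting validation-loss plateau. Mixed-quality minibatches keep
  counter-pressure inside every step.

Everything is reproducible from the training seed, which drives the
train/validation split, the epoch shuffles and (by default) the Xavier
initialization.

## Evaluation stack

- **Fnat**: fraction of native inter-chain residue contacts (interaction
  coordinates under 10 Å) reproduced in the model.
- **LRMS**: ligand (chain 2) backbone RMSD after Kabsch superposition on
  the receptor (chain 1) backbone.
- **iRMS**: backbone RMSD over native-interface residues after
  superposing on exactly those residues.
- **DockQ** = (Fnat + 1/(1+(LRMS/8.5)²) + 1/(1+(iRMS/1.5)²)) / 3, so
  (Fnat, LRMS, iRMS) = (0.5, 8.5, 1.5) gives exactly 0.5.
- **CAPRI classes**: high ≥ 0.80, medium ≥ 0.49, acceptable ≥ 0.23,
  otherwise incorrect.
- **SR(N)**: % of targets with ≥ 1 acceptable decoy among the top N by
  predicted score. **HR(N)**: % of all acceptable decoys captured within
  per-target top-N lists. Both verified against exhaustive brute force.
- **Spearman(Q, DockQ)** and **ROC-AUC** (acceptable vs incorrect at the
  0.23 cutoff) are computed pooled over all decoys of all evaluated
  targets.
- `minmax_normalize` maps lower-is-better raw energies onto [0, 1] for
  comparison with probability-like scores.

## Synthetic benchmark generator

External decoy benchmarks are out of scope, so the package ships a
deterministic generator of desk-scale surrogates:

- A **native** is a pair of torsion-jittered ideal α-helices (40–60
  residues each by default) packed antiparallel until the interface holds
  at least 10 residue pairs under 8 Å, then placed at a random global
  orientation.
- **Decoys** rigidly rotate/translate the ligand chain by one of seven
  graded magnitude levels — from ≤ 1°/0.3 Å (near-native) to
  ≤ 180°/30 Å (incorrect) — plus 0.1 Å Gaussian jitter on every backbone
  atom. Each decoy's true DockQ is computed and attached. Median DockQ
  per level decreases strictly with the level's magnitude.
- **MSAs** are the query plus mutated copies at a controllable
  per-position substitution rate, with a paired (row-concatenated) MSA
  for inter-chain signal.

The default bundle is 20 targets × 30 decoys. Sequence identity for Neff
weighting is the fraction of identical alignment positions (gap–gap
counts as a match), so self-identity is exactly 1.

## Numerical choices

- Kabsch superposition uses `scipy.spatial.transform.Rotation.align_vectors`;
  recovery of a known rigid motion is exact to ~1e-6 (the library's
  working precision), which bounds RMSD differences far below any
  decision threshold used here.
- Dihedrals use the atan2 formulation (stable near 0 and π) and lie in
  (−π, π]; planar angles in [0, π].
- Spearman uses average-rank tie handling (`scipy.stats.spearmanr`); AUC
  uses `sklearn.metrics.roc_auc_score` (ties count half).
- PDB output keeps the fixed-column format's 1e-3 Å precision; the
  round trip is covered by tests.

## Scope and limitations

- Dimers only; larger assemblies, nucleic acids and ligands are out of
  scope. No side-chain atoms beyond Cβ are used.
- The generator produces rigid-body decoys of helical toy dimers. This
  controls DockQ spread analytically but under-represents the diversity
  of real docking decoys (loop remodeling, clashes, alternative
  interfaces), so absolute metric values on it do not transfer to real
  benchmarks.
- With only ~16 training targets, held-out ranking performance is
  limited by cross-target generalization, not by model capacity: trained
  on the held-out targets' own decoys the same architecture reaches a
  substantially higher pooled Spearman than when transferring from
  disjoint targets. See the README's results section for measured
  values.
- CAPRI's full multi-criterion classification and normalization variants
  beyond min–max are not implemented.
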