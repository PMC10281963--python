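# ifaceqe

Interface quality estimation for protein–protein complex models with a
multi-head graph attention network.

Given a structural model of a dimeric complex (a docking decoy or a
predicted structure), `ifaceqe` builds a graph over the inter-chain
interface — one node per interface residue, one edge per residue contact
under 10 Å — featurizes it with physicochemical, geometric and
evolutionary descriptors, and passes it through a 4-layer graph attention
network that regresses a quality score for every interface contact. The
per-contact scores are averaged into a single quality estimate
**Q ∈ (0, 1)** that ranks models by how close their interface is to the
(unseen) native structure, as measured by DockQ.

The package is self-contained: it ships the full evaluation stack (Fnat,
LRMS, iRMS, DockQ, CAPRI classes, success/hit rates, Spearman, ROC-AUC)
and a deterministic synthetic decoy generator, so the entire
train-score-evaluate cycle runs offline on one CPU in minutes. See
[docs/methods.md](docs/methods.md) for the model and all formulas.

## Worked example

Simulate a tiny benchmark, train a model on it, and score decoys — all on
the command line. With `spec.yaml`:

```yaml
n_targets: 4
decoys_per_target: 12
chain_length_range: [30, 40]
msa_depth: 10
```

and `train.yaml`:

```yaml
max_epochs: 60
patience: 15
validation_fraction: 0.25
seed: 0
```

run:

```console
$ iface-qe simulate --spec spec.yaml --out bundle --seed 5
wrote 4 targets, 48 decoys to bundle

$ head -4 bundle/manifest.tsv
target  decoy      fnat    lrms   irms   dockq     capri_class
T000    T000_d000  0.7500  0.420  0.223  0.908620  high
T000    T000_d001  0.5000  1.281  0.632  0.775695  medium
T000    T000_d002  0.7500  1.090  0.441  0.884759  high

$ iface-qe train --bundle bundle --config train.yaml --checkpoint gat.npz
best epoch 42; early stopping at epoch 57; checkpoint -> gat.npz

$ iface-qe score bundle/T000/T000_d000.pdb bundle/T000/T000_d004.pdb \
      --checkpoint gat.npz --msa1 bundle/T000/chain1.a3m \
      --msa2 bundle/T000/chain2.a3m --paired-msa bundle/T000/paired.a3m
bundle/T000/T000_d000.pdb	Q=0.9973
bundle/T000/T000_d004.pdb	Q=0.8335
```

(`T000_d000` really is the better model: its true DockQ is 0.91 — high
quality — against 0.19 — incorrect — for `d004`.) `iface-qe evaluate` scores a whole bundle and writes
per-target and summary tables; `iface-qe featurize` dumps one model's
interface graph as a TSV. Note this toy demo trains and scores the same
four targets — held-out numbers come from the experiment below.

The same pipeline is available from Python:

```python
from ifaceqe.pipeline import run_experiment
from ifaceqe.synthetic_data import SyntheticSpec
from ifaceqe.training import TrainingConfig

params, log, metrics = run_experiment(SyntheticSpec(seed=0),
                                      TrainingConfig(seed=1))
print(metrics["spearman"], metrics["auc"], metrics["SR10"])
```

`run_experiment` simulates the default bundle (20 targets × 30 decoys),
trains on 80 % of the targets (validating on a target-level split of the
training half), and reports pooled metrics on the held-out 20 %.

## Repository layout

```
src/ifaceqe/
  structure_model.py   PDB parsing, residues, torsions, virtual C-beta
  interface_graph.py   interface graph construction (10 A contact cutoff)
  node_features.py     17-entry node descriptors
  edge_features.py     27-entry edge descriptors (distance bins + angles)
  msa_features.py      MSA reading, Neff, evolutionary features
  labeling.py          ground-truth per-edge quality labels
  gat_network.py       numpy GAT: forward, analytic backward, checkpoints
  training.py          Adam, minibatched training loop, early stopping
  evaluation.py        Fnat/LRMS/iRMS/DockQ, SR/HR, Spearman, AUC
  synthetic_data.py    deterministic toy-dimer decoy/MSA generator
  pipeline.py          end-to-end glue
  cli.py               the `iface-qe` command
tests/                 unit, property and acceptance tests
scripts/acceptance.py  recompute the headline numbers from scratch
docs/methods.md        model, formulas, assumptions, limitations
```
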