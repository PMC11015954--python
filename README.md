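# mgbind

Multigranular protein–ligand binding prediction: a single model that
jointly predicts a continuous binding affinity and a binding region on
the protein sequence.

Ligands (SMILES) are encoded three ways in parallel — a graph-attention
network over the molecular graph (atomic environments), a residual 1-D
CNN over character codes (global sequence), and a transformer over
frequency-ranked sub-structure tokens (local mutual effects). Proteins
(amino-acid sequences, overlapping 3-mers) are encoded by a
gated-convolution variational autoencoder whose decoder reconstructs a
per-position profile. A pairwise interaction module builds a
ligand-kernel response vector over protein positions, combines it with
the reconstruction-derived saliency into a binding-region profile, and
fuses bilinear interaction maps of all three ligand granularities into
the affinity prediction. Training minimises
`psi * MSE(affinity) + (1 - psi) * Rwing(region)` with `psi = 0.4`
(plus small VAE reconstruction/KL terms).

All neural components run on a small, gradient-checked numpy autodiff
engine (`mgbind.nn`) — no GPU or deep-learning framework required.

## Library layout

| module | contents |
| --- | --- |
| `mgbind.featurize` | SMILES→graph (78-dim atom descriptors), frozen 64-letter character codes, sub-structure vocabulary + greedy tokenizer, protein 3-mers |
| `mgbind.ligand_encoders` | GAT / residual-CNN / transformer encoders and their math cores |
| `mgbind.protein_vae` | gated-conv VAE, reparameterization, deconvolutional decoder, binding-saliency profile |
| `mgbind.interaction` | ligand kernel, response vector, region assembly, bilinear maps, attention fusion, affinity head |
| `mgbind.model` | `BindingModel` + `ModelConfig` gluing everything, batch collation, checkpoints |
| `mgbind.training` | losses (MSE, Rwing, combined), pKd transform, random/cold splits, CI/MSE/rm²/AUPR/region metrics, train loop, CV runner |
| `mgbind.synthetic_data` | desk-scale generator with planted motif–pharmacophore binding rules |
| `mgbind.io_cli` | pairs-table/FASTA/prediction/BED I/O, YAML run config, CLI |
| `mgbind.nn` | numpy reverse-mode autodiff tensor, layers, Adam |

## CLI

```bash
mgbind simulate --n-pairs 500 --seed 0 --out-dir data/
mgbind featurize --pairs data/pairs.tsv --out summary.tsv
mgbind train --pairs data/pairs.tsv --regime joint --epochs 10 --out-dir run/
mgbind predict --pairs data/pairs.tsv --checkpoint run/checkpoint.npz --out pred.tsv
mgbind evaluate --predictions pred.tsv
```

Every run logs its resolved configuration and seed to stderr; outputs are
plain TSV/JSON/YAML and are byte-reproducible given the same seed.

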