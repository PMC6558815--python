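# paleotrait

Fossil-inclusive phylogenetic comparative analysis of meristic (count) traits:

- **treekit** — dated-tree model, multi-tree Newick I/O, minimum-branch-length
  (MBL) stratigraphic time-scaling with fossil tip-age resampling, pruning,
  unit-height rescaling, and phylogenetic covariance.
- **traitio** — count-table reading/validation, the ±1 soft-range rule for
  records without reported intraspecific variation, ceiling discretization for
  Markov models, and record-to-tip mapping (with congeneric swap support).
- **contmodels** — exact Gaussian likelihoods, ML fitting, simulation,
  Akaike-weight comparison and GLS ancestral states for five continuous
  models: Brownian motion (BM), Ornstein–Uhlenbeck with a fixed root (OU),
  early burst (EB), BM with a trend, and white noise (WN).
- **mkmodels** — ordered (single-step gain/loss) Markov models, symmetric and
  asymmetric, with Felsenstein-pruning likelihoods and a likelihood-ratio
  test for rate asymmetry.
- **adequacy** — phylogenetic independent contrasts and contrast-based model
  adequacy (mean squared contrast, coefficient of variation of |contrasts|,
  the |contrast|-vs-nodal-value slope, and a Kolmogorov–Smirnov distance)
  with posterior-predictive Monte-Carlo p-values.
- **resampling** — multi-tree ensemble fitting and fossil/extant jackknife
  experiments with deterministic per-cell seeding.
- **synth** — birth–death trees with sampled fossil tips plus trait tables
  simulated under any of the models above, so the whole pipeline runs at desk
  scale with known truth.

## CLI

```sh
# make a synthetic fixture (trees.tre + traits.csv + truth.json)
paleotrait simulate --name tiny --out-dir fixtures --n-extant 16 --seed 8

# continuous-model comparison over a tree ensemble
paleotrait fit --trees fixtures/tiny/trees.tre --traits fixtures/tiny/traits.csv --out-dir results/fit

# ordered Markov models + likelihood-ratio test (mean / soft-min / soft-max states)
paleotrait mk --trees ... --traits ... --out-dir results/mk

# contrast-based model adequacy with Monte-Carlo p-values
paleotrait adequacy --trees ... --traits ... --model EB --n-sim 1000 --out-dir results/adq

# fossil (or extant) jackknife
paleotrait jackknife --trees ... --traits ... --group fossil --steps 10 --reps 20 --out-dir results/jk

# MBL time-scaling with fossil tip-age resampling
paleotrait timescale --trees one_tree.tre --traits traits.csv --min-bl 1 --n-trees 50 --seed 0 --out rescaled.tre
```

Options can also come from a YAML config (`--config run.yaml`); flags
override the file. Every run writes a `manifest.json` with input hashes,
the config and library versions, and all outputs are deterministic given the
inputs and seed.

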