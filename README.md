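# atlkit

Active transfer learning (ATL) for batch reaction-condition optimization over
combinatorial reagent spaces.

A campaign starts from an ensemble of simple (depth-one) random-forest
classifiers trained on a *source* domain of previously collected reactions.
The ensemble proposes batches of conditions for a new *target* substrate pair
by query-by-vote: each member nominates its top-N candidates by predicted
probability of improving on the baseline yield, and the most-nominated
conditions form the next batch. After each batch is observed, trees that
endorsed failed conditions are pruned, a fresh generation of members is
trained on the target data collected so far, and the generations are
concatenated. A synthetic yield-landscape simulator and baseline strategies
(uniform random, pure active learning, frozen transfer, oracle-greedy) make
the whole protocol testable without laboratory data.

## Layout

- `atlkit.reagent_space` — reagent catalogs, Cartesian enumeration of the
  condition space, block-structured featurization (continuous descriptors for
  substrates/ligands/solvents; one-hot precatalysts; independent cation/anion
  one-hots for additives, all-zero for the designated `none` additive).
- `atlkit.ensemble` — improves-over-threshold labeling, depth-limited forest
  training, per-member improvement probabilities, failure-driven tree
  pruning, generational combination, and split-node descriptor-usage
  attribution.
- `atlkit.loop` — vote-based batch selection, the campaign engine
  (propose → observe → prune → retrain → combine), stopping heuristic
  (`n_classes - 1` iterations), human-in-the-loop suggestion.
- `atlkit.synthetic` — ground-truth landscapes (descriptor-linear main
  effects, sparse interactions, Gaussian noise, clipping to [0, 100]),
  source/target landscape pairs sharing ligand effects, and the strategy
  benchmark harness.
- `atlkit.io` / `atlkit.cli` — CSV/JSON/YAML readers and writers, run
  manifests, and the `atl` command line.
- `atlkit.fixtures` — a packaged example catalog with class sizes
  (5 precatalysts × 29 ligands × 14 additives × 9 solvents = 18,270
  conditions) and synthetic descriptor values.

## CLI

```sh
# enumerate the combinatorial space (18,270 rows on the packaged fixture)
atl enumerate --catalog fixture --out space.csv
atl enumerate --fix ligand=L01 --out space_l01.csv          # 630 rows

# propose the next batch from reaction records on disk (lab-in-the-loop)
atl suggest --records records.csv --pair Am1,Ac1 --threshold 55 \
    --batch-size 6 --out proposal.csv

# closed-loop campaign against a synthetic oracle
atl run --config config.yaml --out-dir out/     # writes trace.jsonl + manifest

# draw and serialize a source/target landscape pair
atl simulate --seed 3 --out pair.json

# compare strategies on a synthetic landscape pair
atl benchmark --strategies atl,random,active --replicates 20 --out bench.csv

# summarize a campaign trace into per-iteration tables
atl report --trace out/trace.jsonl --out-dir report/
```

A `run` config is YAML:

```yaml
space:
  catalog: fixture          # or a directory of per-class CSVs
  substrate_pair: [Am1, Ac1]
  fixed: {ligand: L01}      # optional: pin classes
model: {n_models: 100, trees_per_model: 10, max_depth: 1}
loop: {batch_size: 6, n_iterations: 3, seed: 7, threshold_percent: 55}
oracle: {spec: {noise_sd: 5.0}, n_source: 72, noisy: true}
```

Catalog directories contain `precatalysts.csv`, `ligands.csv`,
`additives.csv` (id, cation, anion), `solvents.csv`, `substrates.csv`
(id, role, descriptors); first column is the identifier, remaining columns
are numeric descriptors.

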