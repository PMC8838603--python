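# rxnsa

Synthetic-accessibility (SA) estimation from a reaction knowledge graph.

Generative models and virtual screening produce molecules faster than
chemists can triage them; the recurring question is *can this compound
actually be made, and in how many steps?* Complexity-based SA scores answer
a different question (how ornate is the structure). `rxnsa` instead mines
historical reaction records: it builds a directed substance network from
atom-mapped reaction SMILES, finds each compound's **shortest reaction path
(SRP)** — the minimum number of reaction steps from any purchasable building
block — and labels compounds **ES** (easy-to-synthesize, `SRP <= cutoff`) or
**HS** (hard-to-synthesize). Classifiers trained on those labels then score
unseen molecules. The package is for cheminformaticians who want the whole
pipeline — corpus cleaning, reaction-role designation, network construction,
SRP, dataset curation, model training and evaluation — as a library with a
thin CLI on top.

## What it computes

* **Cleaning** — parse `reactants>agents>products` records, deduplicate on
  key multisets, reject incomplete/self-loop/unmappable records.
* **Templates & roles** — extract radius-1 reaction templates (forward and
  inverse rewrite SMARTS) from the atom mapping; apply the inverse template
  to the product to predict reactants (PRs); match PRs against the pooled
  reactant-side species by exact key, then ECFP4 Tanimoto; the leftovers are
  reagents and never enter the network.
* **Network & SRP** — directed multigraph (substances -> substances, edges
  tagged with reaction ids, weights counting supporting documents); terminal
  vs normal node typing; starting materials = terminal nodes on the
  building-block list; SRP by multi-source BFS; `UNREACHABLE` when no
  evidence exists. MW/LogP windows (defaults 200-500 and 0-5) pick label
  candidates without touching the graph.
* **Curation** — ES/HS labeling at a cut-off (2, 3 or 4; boundary
  inclusive), leader-clustering diversity downsampling of the ES surplus
  (default Tanimoto thresholds 0.35/0.615/0.655 per cut-off), stratified
  8:1:1 splits, and an unbalanced test set that adds back the ES compounds
  dropped by balancing.
* **Models & metrics** — RF on six physicochemical descriptors, a
  feed-forward network on 2048-bit ECFP4 (RMSprop, BCE loss, plateau LR
  decay 0.5), and a communicative message-passing graph network (depth 3,
  sum*max edge pooling); ACC, MCC (zero-denominator convention -> 0) and
  rank-statistic ROC-AUC, with ES as the positive class.
* **Synthetic fixtures** — layered reaction corpora with planted roles,
  SRPs, duplicates and misfiled reagents; molecule sets with planted
  classifier signal; everything byte-reproducible per seed, so the full
  pipeline runs and is testable with no external data.

## Worked example

```python
from rxnsa import run_pipeline
from rxnsa.fixtures import FixtureSpec, generate_reaction_corpus, records_from_lines

spec = FixtureSpec(n_building_blocks=14, depth=3, branching=2,
                   reagent_injection_rate=0.3, seed=2)
lines, truth = generate_reaction_corpus(spec)
result = run_pipeline(records_from_lines(lines),
                      building_blocks=set(truth.building_blocks),
                      cutoff=2, mw_range=(100, 2000), logp_range=(-6, 14))
```

Running `python examples/03_network_and_srp.py` (the same computation)
prints:

```
network          : 210 substances, 392 reaction edges
terminal nodes   : 14 (14 purchasable starting materials)
product nodes    : 196
SRP distribution : {1: 28, 2: 56, 3: 112}
labels at cutoff 2: 84 ES / 112 HS
```

All 14 building blocks are recovered as starting materials even though 30%
of the records carry misfiled reagents; products sit at SRP 1-3 matching
their planted synthesis depth; at cut-off 2 the two shallow layers are ES
and the deepest layer is HS. The other scripts in `examples/` walk the
remaining capabilities one at a time (cleaning, role designation, curation,
model training), each printing the numbers it computes.

The same pipeline is scriptable from the shell:

```bash
rxnsa simulate --building-blocks 20 --depth 3 --reagent-rate 0.3 --seed 9 --out demo
rxnsa build-graph --reactions demo/reactions.smi --out demo/net.graphml
rxnsa srp --graph demo/net.graphml --building-blocks demo/blocks.smi \
          --mw 100:2000 --logp -6:14 --out demo/srp.tsv
rxnsa curate --srp-table demo/srp.tsv --cutoff 2 --out demo/dataset.csv
rxnsa train --model rf_pcd --data demo/dataset.csv --seed 0 --out demo/rf.json
```

## Layout

```
src/rxnsa/        the library (io, templates, roles, graph, curation,
                  featurize, models, mpnn, metrics, autodiff, fixtures, cli)
examples/         one short narrative script per capability
tests/            pytest suite, including end-to-end property checks
scripts/          acceptance.py (see above)
docs/methods.md   the model, its assumptions, defaults and limitations
```
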