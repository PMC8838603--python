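# Methods

## The model

`rxnsa` estimates compound synthetic accessibility (SA) from historical
reaction evidence rather than from structural complexity. The corpus of
atom-mapped reaction records is turned into a directed substance network:
nodes are substances (identified by canonical isomeric SMILES with atom maps
stripped), and each reaction contributes an edge from every *true reactant*
to every product. Substances that appear only on the reactant side (terminal
nodes) and match a purchasable building-block list are *starting materials*.
The **shortest reaction path (SRP)** of a compound is the minimum number of
directed edges from any starting material to it, computed by a multi-source
breadth-first traversal. Thresholding SRP at a cut-off labels compounds
easy-to-synthesize (ES, `SRP <= cutoff`, boundary inclusive) or
hard-to-synthesize (HS), and three classifier families are trained to
predict the label from structure alone.

Assumptions worth keeping in view:

* **SRP is single-lineage.** A path counts one reactant chain; co-reactants
  that join along the way are assumed available. SRP is therefore a lower
  bound on true route length, not a route cost.
* **Reachability is evidence-bound.** A compound no starting material
  reaches in the network gets no SRP and is excluded from labeling rather
  than assigned a fabricated value.
* **Stereochemistry is part of substance identity** (it affects how hard a
  compound is to make); atom-map numbers are not.

## Template extraction and role designation

Reaction records frequently misfile solvents, catalysts and counter-ions in
the reactant field. Roles are recovered in three steps:

1. All reactant-side species (reactants + agents) are pooled into the
   original reactants (ORs).
2. A reaction template is extracted from the atom mapping: the reaction
   center is every mapped atom whose bonding, hydrogen count or charge
   changes between the two sides, plus atoms appearing on only one side.
   The pattern is extended by the environment within `radius` bonds
   (default 1) and closed over multiply-bonded or charged neighbours so
   adjacent functional groups (carbonyls, nitro groups) are never cut in
   half. Both rewrite directions are emitted as reaction SMARTS; pattern
   atoms carry element, aromaticity, H-count, degree and charge constraints.
3. The inverse template applied to the product yields predicted reactants
   (PRs). Each PR consumes, in order, an exact canonical-key match among the
   unconsumed ORs, else the unconsumed OR with the highest ECFP4 Tanimoto
   similarity. Leftover ORs are reagents and never enter the network.

Design choices where the procedure was genuinely open:

* When the inverse template matches the product several ways, the PR-set
  with the most exact OR matches wins; ties break by total Tanimoto of the
  matched pairs, then by lexicographic order of the PR canonical keys, so
  the assignment is deterministic.
* Each OR can be consumed by at most one PR. Similarity ties prefer the
  earliest OR in record order.
* There is no minimum-similarity floor; a best match below Tanimoto 0.2 is
  logged as dubious but still taken, because reactant/reagent similarity is
  typically low and an argmax suffices.
* Multi-product records are role-designated against the largest product by
  heavy-atom count, so salts and byproducts do not drive the template.
* The template extractor is an in-repo implementation on RDKit
  (`MolFragmentToSmiles` with per-atom SMARTS symbols); the extended
  special-group closure covers multiple bonds and charged neighbours rather
  than a curated functional-group catalogue.

Validity filtering rejects records with no products, an empty reactant
side, a product repeating a reactant (self-loop), a product with no atom-map
overlap with the reactant side, or a failed template extraction. Duplicate
detection compares the sorted key multisets of (reactants, agents,
products) after map stripping, so component order never matters. Records
whose role designation fails are kept in the network with their as-parsed
roles and a warning flag, rather than dropped.

## Curation

Candidate compounds for labeling are product (normal) nodes with molecular
weight in [200, 500] and Crippen LogP in [0, 5], bounds inclusive; the
filter restricts labels only — filtered-out substances still serve as path
intermediates. Because reaction corpora are bottom-heavy in SRP, the ES
surplus is reduced to roughly the HS class size by leader (sphere-exclusion)
clustering on ECFP4/Tanimoto, keeping one representative per cluster and
uniformly subsampling leaders when they exceed the target. Default
similarity thresholds per SRP cut-off are 0.35 (cut-off 2), 0.615 (3) and
0.655 (4). Splitting is a seeded, label-stratified 8:1:1 with per-class
flooring and the remainder going to the test set; stratification is added so
validation/test stay balanced at small n. An unbalanced test set is the
balanced test set plus every ES compound dropped by balancing, with a
leakage guard against train/validation.

## Classifiers

* **RF-PCD** — scikit-learn random forest (200 trees, seeded) on six
  physicochemical descriptors: MW, TPSA, rotatable bonds, H-bond donors,
  H-bond acceptors and Crippen LogP. LogP is taken as the sixth descriptor
  alongside the five named ones.
* **DNN-ECFP** — feed-forward network on 2048-bit ECFP4 (Morgan radius 2).
  Default architecture: hidden layers (1024, 256), ReLU, dropout 0.2;
  RMSprop on binary cross-entropy; learning rate halved when validation AUC
  plateaus (patience 3); the best-validation checkpoint is restored.
* **Graph classifier** — a communicative message-passing network: hidden
  states live on directed edges; node states are refreshed each step from
  incoming edge states through a sum*max pooling booster; edge states are
  updated from the source node state minus the reverse edge state, keeping
  node and edge representations in conversation; message depth 3; sum
  readout over a final node representation feeds a logistic head. Trained
  with Adam on binary cross-entropy, best checkpoint by validation AUC.
  Molecules without bonds fall back to an atom-only readout.

Both neural models run on a small in-repo reverse-mode autodiff engine over
numpy (`rxnsa.autodiff`) with RMSprop and Adam implemented directly; its
gradients are verified against central finite differences in the test suite,
including end-to-end through the message-passing layers. Training is
CPU-only and deterministic per seed.

Atom features are 133-dimensional: atomic-number one-hot (100), degree
one-hot (6), formal-charge one-hot (5), H-count one-hot (5), hybridization
one-hot (5), chiral-tag one-hot (4), aromaticity (1), ring membership (1),
scaled mass (1) and 5 always-zero padding flags. Bond features are 7-dim:
bond-type one-hot (4), conjugation, ring membership and a constant flag.

## Metrics

ES is the positive class: TP counts true ES, TN true HS.
`ACC = (TP+TN)/(TP+TN+FP+FN)`;
`MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))`, defined as 0
whenever a denominator factor vanishes. ROC-AUC uses the Mann-Whitney rank
statistic with ties counted half; the classification threshold for ACC/MCC
is fixed at 0.5. The implementations are cross-checked in tests against
direct formula substitution on fuzzed confusion matrices, against
scikit-learn's MCC, and against an explicit threshold-sweep trapezoid AUC.

## Synthetic fixtures: what they emulate, and what they do not

The fixture generator emits layered, atom-mapped reaction corpora from a
closed chemistry: bifunctional monomers (amino and hydroxy acids, ~90
distinct) coupled by two reliable condensation motifs (amide and ester
formation). Every layer-`l` product couples two layer-`l-1` substances, so
its planted SRP is exactly `l` and equals 1 + the minimum planted SRP of its
true reactants. Reagents drawn from the classic corpus flaw classes (alkali
metals, halide ions, Pd, solvents, mineral acids/bases, salt pairs) are
injected into the reactant field at a configurable rate, and duplicate
records at another. Generation is byte-identical per (spec, seed).

The same grammar machinery provides molecule sets with planted classifier
signal (a molecular-weight gap at 300/400, a near-balanced ECFP4 bit, or a
nitro substructure), planted analog-series clusters for curation tests
(within-cluster ECFP4 Tanimoto above ~0.58, cross-cluster below ~0.47, so
leader clustering at 0.5 recovers them exactly), and abstract random layered
DAGs for shortest-path oracle tests.

What passing fixture tests does **not** show: the fixture chemistry is two
condensation motifs on friendly substrates, so it cannot probe template
extraction across reaction-class breadth, stereochemistry-changing
reactions, ring formations, or the long-tail parsing pathologies of real
patent extracts; planted signals are far cleaner than the diffuse structure/
SA relationship in real reaction corpora, so model AUCs on fixtures say the
training machinery works, not that SA prediction is solved at these scores.

## Numerical and scale choices

Degenerate inputs: empty graphs type to empty partitions; single-class label
sets are rejected at training time and return MCC 0 with undefined AUC at
evaluation; molecules failing property computation are excluded from
candidacy and logged; inverse-template application failures return an empty
PR-set rather than raising inside batch runs.

Problem sizes in the test suite and acceptance script are desk-scale by
design: corpora of ~170 (clean) and ~1100 (noisy) reactions at depth 3,
shortest-path oracle graphs up to 500 nodes, and planted-signal model runs
at n = 2000 with reduced architectures (DNN 256/64, message-passing hidden
48, 6-8 epochs). These sizes are where the properties under test are already
fully expressed; the defaults in the library remain the full-size settings.

## Known limitations

* SRP ignores co-reactant cost, yields and protection/deprotection detours.
* The template extractor handles the chemistry the atom mapping expresses;
  it does not infer mappings and does not generalize templates across
  records.
* Leader clustering is order-dependent (first compound founds the first
  cluster); determinism comes from fixed input order, not from an
  order-free objective.
* Model persistence is limited to in-process objects; the CLI trains and
  evaluates in one invocation and emits metrics JSON rather than a
  versioned weight store.
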