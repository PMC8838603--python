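"""Balance an ES surplus by diversity clustering and split 8:1:1.

Reaction corpora are bottom-heavy: far more compounds sit within a short
reaction path than beyond it. Leader clustering on ECFP4/Tanimoto picks a
structurally diverse ES subset of about the HS class size before splitting.
"""
from rxnsa import build_unbalanced_test, diversity_downsample, split_dataset
from rxnsa.curation import ES, HS, LabeledCompound
from rxnsa.fixtures import molecule_pool

pool = molecule_pool(440, seed=3)
es = [LabeledCompound(key=s, smiles=s, srp=2, label=ES) for s in pool[:400]]
hs = [LabeledCompound(key=s, smiles=s, srp=5, label=HS) for s in pool[400:440]]
print(f"raw classes      : {len(es)} ES / {len(hs)} HS")

balanced_es = diversity_downsample(es, similarity_threshold=0.615,
                                   target_size=len(hs), seed=0)
print(f"after balancing  : {len(balanced_es)} ES / {len(hs)} HS")

split = split_dataset(balanced_es + hs, seed=0)
kept = {c.key for c in balanced_es}
split = build_unbalanced_test(split, [c for c in es if c.key not in kept])
print(f"splits           : {len(split.train)} train / "
      f"{len(split.validation)} validation / {len(split.test)} test")
print(f"unbalanced test  : {len(split.unbalanced_test)} "
      f"(balanced test + every ES compound dropped by balancing)")
# The balanced splits drive training and threshold-dependent metrics; the
# unbalanced test probes ranking quality under the corpus's real class skew.
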