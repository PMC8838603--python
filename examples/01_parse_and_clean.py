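"""Parse, deduplicate and validity-filter a small reaction corpus.

Generates a 2-layer synthetic corpus with planted duplicates, then runs the
cleaning stage and prints what survived and why records were dropped.
"""
from rxnsa import deduplicate, filter_valid, parse_reaction_smiles
from rxnsa.fixtures import FixtureSpec, generate_reaction_corpus, records_from_lines
from rxnsa.templates import template_check

spec = FixtureSpec(n_building_blocks=8, depth=2, branching=2,
                   duplicate_rate=0.4, seed=1)
lines, truth = generate_reaction_corpus(spec)
records = records_from_lines(lines)
records.append(parse_reaction_smiles("CCO>>CCO", "bad-self-loop"))

deduped = deduplicate(records)
kept, rejected = filter_valid(deduped, template_check=template_check)

print(f"parsed   : {len(records)} records "
      f"({truth.n_duplicates} planted duplicates + 1 planted self-loop)")
print(f"deduped  : {len(deduped)} records")
print(f"kept     : {len(kept)} records")
for record, reason in rejected:
    print(f"rejected : {record.id} -> {reason}")
# The kept count equals the number of distinct planted reactions: duplicate
# records collapse on their (reactants, agents, products) key multiset and
# the self-loop is caught by the validity contract.
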