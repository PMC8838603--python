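"""Extract a radius-1 reaction template and separate reactants from reagents.

A deliberately flawed esterification record carries sodium and THF misfiled
in the reactant field. The inverse template predicts the true reactants from
the product; exact/similarity matching against the pooled reactant-side
species then isolates the reagents.
"""
from rxnsa import designate_roles, extract_template, parse_reaction_smiles

record = parse_reaction_smiles(
    "[CH3:1][C:2](=[O:3])[OH:4].[Na].[OH:5][CH2:6][CH3:7].C1CCOC1"
    ">>[CH3:1][C:2](=[O:3])[O:5][CH2:6][CH3:7]",
    id="flawed-esterification")

template = extract_template(record, radius=1)
print("forward template :", template.forward_pattern)
print("inverse template :", template.inverse_pattern)

assignment = designate_roles(record, template)
print("true reactants   :", sorted(s.key for s in assignment.true_reactants))
print("reagents         :", sorted(s.key for s in assignment.reagents))
for pr, orig, mode, score in assignment.match_trace:
    print(f"  PR {pr.key:12s} matched OR {orig.key:12s} ({mode}, {score:.2f})")
# Acetic acid and ethanol are recovered as the reaction's true reactants;
# sodium and tetrahydrofuran contribute no atoms to the ester and fall out
# as reagents, so they will never become nodes of the reaction network.
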