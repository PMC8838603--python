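"""Reactant/reagent role designation by inverse-template matching.

Reaction records frequently misfile solvents, catalysts and counter-ions in
the reactant field. Role designation pools everything on the reactant side
into the original reactants (ORs), applies the record's inverse template to
its product to obtain predicted reactants (PRs), and matches PRs against
ORs: an exact canonical-key match wins, otherwise the most Tanimoto-similar
unconsumed OR does. ORs left unmatched are reagents.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem import Substance, ecfp4, tanimoto, mol_from_smiles
from .reaction_io import ReactionRecord
from .templates import ReactionTemplate, apply_inverse

log = logging.getLogger(__name__)

#: below this best-match Tanimoto a similarity match is logged as dubious
LOW_SIMILARITY_WARNING = 0.2


class RoleDesignationError(ValueError):
    pass


@dataclass
class RoleAssignment:
    """Partition of a record's reactant-side species into reactants/reagents."""

    true_reactants: list[Substance]
    reagents: list[Substance]
    #: (predicted reactant, matched OR, "exact"|"similarity", score)
    match_trace: list[tuple] = field(default_factory=list)


def _largest_product(record: ReactionRecord) -> Substance:
    def heavy_atoms(sub: Substance) -> int:
        return mol_from_smiles(sub.smiles).GetNumHeavyAtoms()

    return max(record.products, key=lambda s: (heavy_atoms(s), s.key))


def _score_pr_set(pr_set, or_subs, fp_cache):
    """(n exact matches, total Tanimoto of matched pairs) under greedy matching."""
    unconsumed = list(range(len(or_subs)))
    n_exact, total_sim = 0, 0.0
    for pr in pr_set:
        exact = [i for i in unconsumed if or_subs[i].key == pr.key]
        if exact:
            unconsumed.remove(exact[0])
            n_exact += 1
            total_sim += 1.0
        elif unconsumed:
            sims = [(tanimoto(fp_cache[pr.key], fp_cache[or_subs[i].key]), -i)
                    for i in unconsumed]
            best_sim, neg_i = max(sims)
            unconsumed.remove(-neg_i)
            total_sim += best_sim
    return n_exact, total_sim


def designate_roles(record: ReactionRecord, template: ReactionTemplate
                    ) -> RoleAssignment:
    """Split the record's pooled reactant-side species into reactants/reagents.

    Raises :class:`RoleDesignationError` when the inverse template yields no
    PR-set for the record's largest product; callers should then keep the
    as-parsed roles and flag the record (``record.role_warning``).
    """
    ors: list[Substance] = list(record.reactants) + list(record.agents)
    product = _largest_product(record)
    pr_sets = apply_inverse(template, product)
    if not pr_sets:
        raise RoleDesignationError(
            f"record {record.id}: no PR-set obtainable for {product.key}")

    fp_cache = {}
    for sub in ors + [s for prs in pr_sets for s in prs]:
        if sub.key not in fp_cache:
            fp_cache[sub.key] = ecfp4(sub.smiles)

    # choose the PR-set with the most exact OR matches; ties by total
    # similarity, then lexicographic keys for determinism
    def rank(pr_set):
        n_exact, total = _score_pr_set(pr_set, ors, fp_cache)
        return (n_exact, total, tuple(sorted(s.key for s in pr_set)))

    best = max(pr_sets, key=rank)

    unconsumed = list(range(len(ors)))
    trace = []
    for pr in best:
        exact = [i for i in unconsumed if ors[i].key == pr.key]
        if exact:
            unconsumed.remove(exact[0])
            trace.append((pr, ors[exact[0]], "exact", 1.0))
            continue
        if not unconsumed:
            break
        sims = [(tanimoto(fp_cache[pr.key], fp_cache[ors[i].key]), -i)
                for i in unconsumed]
        best_sim, neg_i = max(sims)
        i = -neg_i
        if best_sim < LOW_SIMILARITY_WARNING:
            log.warning("record %s: PR %s matched OR %s at low similarity %.3f",
                        record.id, pr.key, ors[i].key, best_sim)
        unconsumed.remove(i)
        trace.append((pr, ors[i], "similarity", best_sim))

    true_reactants = [ors[i] for i in range(len(ors)) if i not in unconsumed]
    reagents = [ors[i] for i in unconsumed]
    assert len(true_reactants) + len(reagents) == len(ors)
    return RoleAssignment(true_reactants=true_reactants, reagents=reagents,
                          match_trace=trace)
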