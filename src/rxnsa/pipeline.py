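"""End-to-end orchestration: records -> roles -> network -> SRP -> labels."""
from __future__ import annotations

import logging

from .curation import label_compounds
from .graph import build_graph, classify_nodes, compute_srp, filter_candidates
from .reaction_io import ReactionRecord, deduplicate, filter_valid
from .roles import RoleAssignment, RoleDesignationError, designate_roles
from .templates import TemplateError, extract_template, template_check

log = logging.getLogger(__name__)


def prepare_records(records: list[ReactionRecord], radius: int = 1):
    """Deduplicate then validity-filter, including the template-extraction check."""
    deduped = deduplicate(records)
    return filter_valid(deduped, template_check=lambda r: template_check(r, radius))


def designate_all_roles(records: list[ReactionRecord], radius: int = 1):
    """Role-designate every record; failures keep as-parsed roles, flagged.

    Returns ([(record, RoleAssignment)], n_failures). A failed record gets a
    fallback assignment treating all pooled species as reactants, with
    ``record.role_warning`` set, so the network stage can still use it.
    """
    out, n_failures = [], 0
    for record in records:
        try:
            template = extract_template(record, radius)
            roles = designate_roles(record, template)
        except (TemplateError, RoleDesignationError) as exc:
            log.warning("role designation failed: %s", exc)
            record.role_warning = True
            roles = RoleAssignment(
                true_reactants=list(record.reactants) + list(record.agents),
                reagents=[], match_trace=[])
            n_failures += 1
        out.append((record, roles))
    return out, n_failures


def run_pipeline(records: list[ReactionRecord], building_blocks: set[str],
                 cutoff: int = 3, mw_range=(200.0, 500.0),
                 logp_range=(0.0, 5.0), radius: int = 1) -> dict:
    """Full run; returns graph, typing, SRP table and labeled candidates."""
    kept, rejected = prepare_records(records, radius)
    with_roles, n_failures = designate_all_roles(kept, radius)
    graph = build_graph(with_roles)
    typing = classify_nodes(graph, building_blocks)
    candidates = filter_candidates(graph, typing, mw_range, logp_range)
    srp = compute_srp(graph, typing)
    smiles_of = {k: graph.nodes[k].get("smiles", k) for k in srp}
    labeled = label_compounds({k: srp[k] for k in candidates if k in srp},
                              cutoff, smiles_of)
    return {
        "kept": kept, "rejected": rejected, "n_role_failures": n_failures,
        "graph": graph, "typing": typing, "srp": srp,
        "candidates": candidates, "labeled": labeled,
    }
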