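"""ES/HS labeling, diversity balancing and dataset splitting.

Compounds reachable in at most ``cutoff`` reaction steps from a purchasable
building block are easy-to-synthesize (ES); the rest are hard-to-synthesize
(HS). Because shallow compounds dominate reaction corpora, the surplus ES
class is reduced to a structurally diverse subset of roughly the HS class
size by leader (sphere-exclusion) clustering on ECFP4/Tanimoto before the
8:1:1 train/validation/test split.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit.DataStructs import BulkTanimotoSimilarity

from .chem import ecfp4

log = logging.getLogger(__name__)

ES, HS = "ES", "HS"

#: leader-clustering Tanimoto thresholds per SRP cut-off
DEFAULT_CLUSTER_THRESHOLDS = {2: 0.35, 3: 0.615, 4: 0.655}


@dataclass(frozen=True)
class LabeledCompound:
    key: str
    smiles: str
    srp: int
    label: str


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)
    seed: int = 0
    ratios: tuple = (8, 1, 1)
    unbalanced_test: list | None = None


def label_compounds(srp_table: dict[str, float], cutoff: int,
                    smiles_of: dict[str, str] | None = None
                    ) -> list[LabeledCompound]:
    """Label reachable compounds ES (srp <= cutoff) or HS (srp > cutoff).

    Unreachable entries are dropped (their count is logged): the network
    offers no evidence of a synthesis route, so no path length exists to
    threshold.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    out, n_unreachable = [], 0
    for key in sorted(srp_table):
        srp = srp_table[key]
        if math.isinf(srp):
            n_unreachable += 1
            continue
        smiles = (smiles_of or {}).get(key, key)
        out.append(LabeledCompound(key=key, smiles=smiles, srp=int(srp),
                                   label=ES if srp <= cutoff else HS))
    if n_unreachable:
        log.info("dropped %d unreachable compounds", n_unreachable)
    return out


def leader_clusters(smiles_list: list[str], threshold: float) -> list[int]:
    """Greedy sphere-exclusion clustering; returns a cluster id per input.

    The first compound founds cluster 0; each subsequent compound joins the
    first-founded cluster whose leader is at Tanimoto >= threshold, else
    founds a new cluster. Deterministic in input order.
    """
    leader_fps: list = []
    assignment = []
    for smi in smiles_list:
        fp = ecfp4(smi)
        if leader_fps:
            sims = BulkTanimotoSimilarity(fp, leader_fps)
            best = int(np.argmax(sims))
            if sims[best] >= threshold:
                assignment.append(best)
                continue
        leader_fps.append(fp)
        assignment.append(len(leader_fps) - 1)
    return assignment


def diversity_downsample(compounds: list[LabeledCompound],
                         similarity_threshold: float,
                         target_size: int, seed: int) -> list[LabeledCompound]:
    """Pick a structurally diverse subset of about ``target_size`` compounds.

    Leader clustering at the given Tanimoto threshold keeps one
    representative (the leader) per cluster; when more clusters than
    ``target_size`` exist, a seeded uniform subsample of leaders is returned.
    """
    if not 0.0 < similarity_threshold < 1.0:
        raise ValueError("similarity_threshold must be in (0, 1)")
    if target_size > len(compounds):
        log.warning("target_size %d > %d compounds; returning all",
                    target_size, len(compounds))
        return list(compounds)
    assignment = leader_clusters([c.smiles for c in compounds],
                                 similarity_threshold)
    leaders = []
    seen = set()
    for compound, cid in zip(compounds, assignment):
        if cid not in seen:
            seen.add(cid)
            leaders.append(compound)
    if len(leaders) <= target_size:
        if len(leaders) < target_size:
            log.warning("only %d clusters for target %d", len(leaders), target_size)
        return leaders
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(leaders), size=target_size, replace=False)
    return [leaders[i] for i in sorted(idx)]


def split_dataset(compounds: list[LabeledCompound], seed: int,
                  ratios: tuple = (8, 1, 1)) -> DatasetSplit:
    """Seeded, label-stratified 8:1:1 split (remainder goes to test)."""
    if len(compounds) < 10:
        raise ValueError("need at least 10 compounds to honor an 8:1:1 split")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    split = DatasetSplit(seed=seed, ratios=tuple(ratios))
    for label in (ES, HS):
        group = [c for c in compounds if c.label == label]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        n = len(group)
        n_train = int(n * ratios[0] / total)
        n_val = int(n * ratios[1] / total)
        split.train.extend(group[:n_train])
        split.validation.extend(group[n_train:n_train + n_val])
        split.test.extend(group[n_train + n_val:])
    for part in (split.train, split.validation, split.test):
        order = rng.permutation(len(part))
        part[:] = [part[i] for i in order]
    _check_leakage(split)
    return split


def build_unbalanced_test(split: DatasetSplit,
                          remaining_es: list[LabeledCompound]) -> DatasetSplit:
    """Extend the balanced test set with the ES compounds dropped by balancing."""
    held = {c.key for c in split.train} | {c.key for c in split.validation}
    offending = sorted({c.key for c in remaining_es} & held)
    if offending:
        raise ValueError(
            f"remaining ES overlap train/validation: {offending[:10]}")
    test_keys = {c.key for c in split.test}
    extra = [c for c in remaining_es if c.key not in test_keys]
    split.unbalanced_test = list(split.test) + extra
    return split


def _check_leakage(split: DatasetSplit) -> None:
    keys = [{c.key for c in part}
            for part in (split.train, split.validation, split.test)]
    for i in range(3):
        for j in range(i + 1, 3):
            overlap = keys[i] & keys[j]
            if overlap:
                raise ValueError(f"split leakage: {sorted(overlap)[:10]}")


def write_dataset_csv(split: DatasetSplit, path) -> None:
    """CSV of (key, smiles, srp, label, split) incl. unbalanced-test extras."""
    import pandas as pd

    rows = []
    parts = [("train", split.train), ("validation", split.validation),
             ("test", split.test)]
    for name, part in parts:
        rows += [(c.key, c.smiles, c.srp, c.label, name) for c in part]
    if split.unbalanced_test is not None:
        test_keys = {c.key for c in split.test}
        rows += [(c.key, c.smiles, c.srp, c.label, "unbalanced_test_extra")
                 for c in split.unbalanced_test if c.key not in test_keys]
    pd.DataFrame(rows, columns=["key", "smiles", "srp", "label", "split"]
                 ).to_csv(path, index=False)
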