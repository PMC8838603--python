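"""Communicative message-passing classifier on molecular graphs.

A desk-scale reimplementation of the communicative message-passing scheme
(CMPNN): hidden states live on directed edges, node states are refreshed
each step from the incoming edge states through a sum*max pooling booster,
and edge states are updated from the source node's state minus the reverse
edge's state, keeping node and edge representations in conversation. After
``depth`` steps a final node representation is pooled per molecule and a
feed-forward head emits an ES logit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .featurize import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolGraph, mol_graph
from .metrics import roc_auc


@dataclass
class MPNNConfig:
    hidden: int = 64
    depth: int = 3
    lr: float = 1e-3
    batch_size: int = 50
    epochs: int = 12
    seed: int = 0


@dataclass
class BatchedGraph:
    """Several molecular graphs packed into one disjoint union."""

    atom_features: np.ndarray
    bond_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_rev: np.ndarray
    mol_index: np.ndarray  # (n_atoms,) molecule id per atom
    n_mols: int


def batch_graphs(graphs: list[MolGraph]) -> BatchedGraph:
    atoms, bonds, src, dst, rev, mol_idx = [], [], [], [], [], []
    atom_off = edge_off = 0
    for i, g in enumerate(graphs):
        n, e = len(g.atom_features), len(g.edge_src)
        atoms.append(g.atom_features)
        bonds.append(g.bond_features)
        src.append(g.edge_src + atom_off)
        dst.append(g.edge_dst + atom_off)
        rev.append(g.edge_rev + edge_off)
        mol_idx.append(np.full(n, i))
        atom_off += n
        edge_off += e
    return BatchedGraph(
        atom_features=np.concatenate(atoms) if atoms else np.zeros((0, ATOM_FEATURE_DIM)),
        bond_features=(np.concatenate(bonds) if bonds
                       else np.zeros((0, BOND_FEATURE_DIM))),
        edge_src=np.concatenate(src) if src else np.zeros(0, dtype=int),
        edge_dst=np.concatenate(dst) if dst else np.zeros(0, dtype=int),
        edge_rev=np.concatenate(rev) if rev else np.zeros(0, dtype=int),
        mol_index=np.concatenate(mol_idx) if mol_idx else np.zeros(0, dtype=int),
        n_mols=len(graphs),
    )


class GraphClassifier:
    def __init__(self, config: MPNNConfig | None = None):
        self.config = config or MPNNConfig()
        h = self.config.hidden
        rng = np.random.default_rng(self.config.seed)
        self.w_atom = ad.glorot(rng, ATOM_FEATURE_DIM, h)
        self.w_edge = ad.glorot(rng, ATOM_FEATURE_DIM + BOND_FEATURE_DIM, h)
        self.w_comm = ad.glorot(rng, 2 * h, h)     # node <- (node, pooled edges)
        self.w_update = ad.glorot(rng, h, h)       # edge refresh
        self.w_out = ad.glorot(rng, ATOM_FEATURE_DIM + h, h)
        self.w_head = ad.glorot(rng, h, 1)
        self.b_head = ad.Parameter(np.zeros((1, 1)))

    @property
    def parameters(self):
        return [self.w_atom, self.w_edge, self.w_comm, self.w_update,
                self.w_out, self.w_head, self.b_head]

    def logits(self, batch: BatchedGraph):
        n_atoms = len(batch.atom_features)
        x_atoms = ad.Tensor(batch.atom_features)
        h_node = ad.relu(ad.matmul(x_atoms, self.w_atom))
        has_edges = len(batch.edge_src) > 0
        if has_edges:
            edge_in = np.concatenate(
                [batch.atom_features[batch.edge_src], batch.bond_features], axis=1)
            h0_edge = ad.relu(ad.matmul(ad.Tensor(edge_in), self.w_edge))
            h_edge = h0_edge
            for _step in range(self.config.depth):
                pooled = ad.mul(
                    ad.segment_sum(h_edge, batch.edge_dst, n_atoms),
                    ad.segment_max(h_edge, batch.edge_dst, n_atoms))
                h_node = ad.relu(ad.matmul(
                    ad.concat_cols(h_node, pooled), self.w_comm))
                msg = ad.gather_rows(h_node, batch.edge_src) - \
                    ad.gather_rows(h_edge, batch.edge_rev)
                h_edge = ad.relu(h0_edge + ad.matmul(msg, self.w_update))
        z = ad.relu(ad.matmul(ad.concat_cols(x_atoms, h_node), self.w_out))
        pooled_mol = ad.segment_sum(z, batch.mol_index, batch.n_mols)
        return ad.add(ad.matmul(pooled_mol, self.w_head), self.b_head)

    def predict_proba(self, graphs: list[MolGraph]) -> np.ndarray:
        out = self.logits(batch_graphs(graphs))
        return (0.5 * (1.0 + np.tanh(0.5 * out.data))).ravel()

    def state(self):
        return [p.data.copy() for p in self.parameters]

    def load_state(self, state):
        for p, s in zip(self.parameters, state):
            p.data = s.copy()


def graphs_from_smiles(smiles_list: list[str]) -> list[MolGraph]:
    return [mol_graph(s) for s in smiles_list]


def train_graph_classifier(graphs: list[MolGraph], labels01,
                           val_graphs: list[MolGraph], val_labels01,
                           config: MPNNConfig | None = None) -> GraphClassifier:
    """Adam on binary cross-entropy; best checkpoint by validation AUC."""
    config = config or MPNNConfig()
    y = np.asarray(labels01, dtype=np.float64)
    if config.epochs > 0 and len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = GraphClassifier(config)
    opt = ad.Adam(model.parameters, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    best_auc, best_state = -np.inf, model.state()
    for _epoch in range(config.epochs):
        order = rng.permutation(len(graphs))
        for start in range(0, len(graphs), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            loss = ad.bce_with_logits(model.logits(batch), y[idx])
            loss.backward()
            opt.step()
        val_auc = roc_auc(model.predict_proba(val_graphs),
                          np.asarray(val_labels01, dtype=bool))
        if val_auc > best_auc + 1e-6:
            best_auc, best_state = val_auc, model.state()
    model.load_state(best_state)
    return model
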