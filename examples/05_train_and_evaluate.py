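"""Train the three classifier families on a planted-signal set and score them.

Molecules carry a planted nitro-group signal: the graph model sees the
substructure directly, the fingerprint network sees it through ECFP4 bits,
and the physicochemical random forest sees it only indirectly.
"""
import numpy as np

from rxnsa import evaluate, generate_model_fixture
from rxnsa.chem import ecfp4_bits, physchem
from rxnsa.curation import ES, HS
from rxnsa.models import DNNConfig, rf_predict_proba, train_dnn_ecfp, train_rf_pcd
from rxnsa.mpnn import MPNNConfig, graphs_from_smiles, train_graph_classifier

smiles, y, desc = generate_model_fixture(600, "substructure", seed=4)
labels = [ES if v else HS for v in y]
n = 480  # 80% train, 20% held out

X = np.stack([physchem(s) for s in smiles])
rf = train_rf_pcd(X[:n], y[:n], seed=0)
rf_report = evaluate(rf_predict_proba(rf, X[n:]), labels[n:])

F = np.stack([ecfp4_bits(s) for s in smiles])
dnn = train_dnn_ecfp(F[:n], y[:n], F[n:], y[n:],
                     DNNConfig(hidden=(256, 64), epochs=6, seed=0))
dnn_report = evaluate(dnn.predict_proba(F[n:]), labels[n:])

graphs = graphs_from_smiles(smiles)
gnn = train_graph_classifier(graphs[:n], y[:n], graphs[n:], y[n:],
                             MPNNConfig(hidden=32, depth=3, epochs=8, seed=0))
gnn_report = evaluate(gnn.predict_proba(graphs[n:]), labels[n:])

print(f"planted signal : nitro group {desc['pattern']}")
for name, rep in (("RF-PCD", rf_report), ("DNN-ECFP", dnn_report),
                  ("GraphNN", gnn_report)):
    print(f"{name:9s}: AUC {rep.auc:.3f}  ACC {rep.acc:.3f}  MCC {rep.mcc:.3f}")
# Expect the structure-aware models (DNN-ECFP, GraphNN) near-perfect on this
# substructure task and the descriptor-based forest clearly weaker: MW/TPSA
# shift only slightly when a nitro group is present.
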