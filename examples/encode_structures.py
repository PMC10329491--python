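"""Featurize a molecule and a protein sequence and encode both.

Shows the fixed 39/11-wide graph featurization, byte-pair subword
tokenization, and the two structural encoders producing fixed-size vectors.
"""

import numpy as np

from mdtips.chem_graph import smiles_to_graph
from mdtips.drug_encoder import AttentiveFPConfig, AttentiveFPEncoder
from mdtips.target_encoder import (TargetTransformer, TransformerConfig,
                                   learn_subword_vocab, tokenize)

aspirin = smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")
print(f"aspirin: {aspirin.n_atoms} heavy atoms, "
      f"{len(aspirin.edges)} directed edges")
print(f"atom feature matrix {aspirin.atom_features.shape}, "
      f"bond feature matrix {aspirin.edge_features.shape}")

encoder = AttentiveFPEncoder(AttentiveFPConfig(hidden_dim=32, seed=0)).eval()
vec = encoder.encode_drug(aspirin).data
print(f"drug embedding: shape {vec.shape}, norm {np.linalg.norm(vec):.3f}")

corpus = ["MKVLAWGGMKVLAW", "GGLLKKMMAWMKV", "MKVMKVGG"]
vocab = learn_subword_vocab(corpus, n_merges=10)
tok = tokenize("MKVLAWGGMKV", vocab, m=32)
print(f"subword vocabulary: {vocab.size} tokens, "
      f"first merges {vocab.merges[:3]}")
print(f"tokenized: {tok.tokens} (stored length {tok.true_length})")

model = TargetTransformer(vocab.size,
                          TransformerConfig(d=32, m=32, n_heads=2, seed=0))
model.eval()
emb = model.encode(tok).data
print(f"target embedding: shape {emb.shape}, norm {np.linalg.norm(emb):.3f}")
# Both embeddings feed the per-modality projections of the fusion classifier.
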