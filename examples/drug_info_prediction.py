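"""Predict drug-related knowledge-graph links (indications, side effects).

The pretrained K model ranks candidate tail entities for a (drug, relation)
query by the ConvE score, filtering links already present in the graph.
"""

from mdtips import workflows
from mdtips.kge import train_conve
from mdtips.router import predict_drug_info
from mdtips.synthetic import SimConfig, simulate_world

world = simulate_world(SimConfig(n_drugs=30, n_targets=40, seed=7))
result = train_conve(world.kg, workflows.desk_kge_config(seed=0))
print(f"ConvE trained: loss {result.losses[0]:.3f} -> "
      f"{result.losses[-1]:.3f}")

drug = world.drugs[0].drug_id
for relation in ("treats", "causes"):
    ranked = predict_drug_info(result.model, drug, relation, top_k=5)
    print(f"\ntop-5 predicted '{relation}' links for {drug}:")
    for entity, score in ranked:
        print(f"  {entity}\t{score:.3f}")
# Higher scores mean the embedding geometry places the entity where the
# drug's existing community links predict a missing edge.
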