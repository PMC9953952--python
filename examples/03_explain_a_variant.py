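"""Ranked natural-language explanation sentences for one variant.

Trains the explanation-mode model (ClinVar visible, but masked on a random
half of the training variants so the model cannot parrot ClinVar alone),
then explains one pathogenic variant: each sentence is rendered by a
declarative rule from the evidence subgraph, and ranked by
X-Factor = sigmoid(X-Contribution x X-Impact), where X-Contribution is the
classifier's perturbation attribution for the supporting nodes and X-Impact
is the physician-assigned weight of their node type.
"""

from kgxplain import pipeline
from kgxplain.classifier import classify, predict
from kgxplain.explain import explain
from kgxplain.features import build_feature_graph
from kgxplain.simulate import SimulationConfig, simulate

ds = simulate(SimulationConfig(seed=2, n_chromosomes=6, genes_per_chromosome=3,
                               variants_per_gene=30))
model, answers = pipeline.train_explanation_model(ds, seed=2)
kg, index, _ = pipeline.dataset_to_kg(ds)

target = next(v for v in answers if v.label == "pathogenic").key
fg = build_feature_graph(target, kg, "explanation", index)
score = predict(model, fg)
print(f"variant {target}: score={score:.3f} -> {classify(score)}")
print("top explanation sentences (x_factor | rule):")
for s in explain(model, target, kg, index, top_n=6, seed=2):
    print(f"  {s.x_factor:.4f} | {s.rule}: {s.text}")
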