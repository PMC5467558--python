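"""MeSH tree-number hypernymy and the two filtering stages.

The task asks for the most *specific* chemical-disease relations, so
concepts that merely generalize a concept already in a positive relation
are filtered — from the negative training instances and from the predicted
document-level pairs.
"""

from cidre import MeshOntology, hypernym_filter_predict, is_hypernym

ontology = MeshOntology({
    "D_cardiovascular_agents": {"D02.100"},
    "D_dipyridamole": {"D02.100.200"},
    "D_aspirin": {"D02.300"},
})

a, b = "D_cardiovascular_agents", "D_dipyridamole"
print(f"is_hypernym({a}, {b}) = {is_hypernym(ontology, a, b)}")
print(f"is_hypernym({b}, {a}) = {is_hypernym(ontology, b, a)}")
print("Hypernymy = proper, segment-aligned tree-number prefix: D02.100 is an")
print("ancestor of D02.100.200, but D02.10 would not be (segment boundary).\n")

predicted = {
    ("D_dipyridamole", "D_hyperemia"),
    ("D_cardiovascular_agents", "D_hyperemia"),
    ("D_aspirin", "D_nausea"),
}
kept = hypernym_filter_predict(predicted, ontology)
print("predicted pairs:", sorted(predicted))
print("after filtering:", sorted(kept))
print("\nThe drug-class pair is dropped because a more specific member of the")
print("class is already predicted for the same document.")
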