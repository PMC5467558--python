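"""Extract the three directed dependency paths for a mention pair.

Builds the parse of "The dipyridamole induced his hyperemia." by hand and
prints the root-to-chemical (R2C), root-to-disease (R2D) and
chemical-to-disease (C2D) paths, plus the 3-token windows the CNN convolves.
"""

from cidre import DependencyTree, Token, extract_dependency_paths, path_windows

rows = [
    ("The", "the", "DT", 2, "det"),
    ("dipyridamole", "dipyridamole", "NN", 3, "nsubj"),
    ("induced", "induce", "VBD", 0, "root"),
    ("his", "his", "PRP$", 5, "poss"),
    ("hyperemia", "hyperemia", "NN", 3, "dobj"),
    (".", ".", ".", 3, "punct"),
]
tokens, offset = [], 0
for i, (form, lemma, pos, head, deprel) in enumerate(rows):
    tokens.append(Token(i + 1, form, lemma, pos, head, deprel, offset,
                        offset + len(form)))
    offset += len(form) + 1
tree = DependencyTree(0, tokens)

r2c, r2d, c2d = extract_dependency_paths(tree, chem_head=2, dis_head=5)
print("R2C:", "".join(r2c))
print("R2D:", "".join(r2d))
print("C2D:", "".join(c2d))
print()
print("v=3 windows over C2D (the convolution input, one column per window):")
for win in path_windows(c2d, 3):
    print("  ", win)
print()
print("Each path interleaves words, dependency labels and traversal arrows;")
print("the windows are embedded, stacked and max-pooled into a fixed-size")
print("dependency feature vector regardless of path length.")
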