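"""Run the two-stage Fitch method on a small tree.

Builds a five-leaf tree with a DNA-like 4-state character, runs the
leaf-to-root set stage and the randomized root-to-leaf choice stage, and
prints each node's state set, the chosen states, and the parsimony score
(the minimum number of substitutions needed to explain the leaf states).
"""

import numpy as np

from fitchacc import ModelParams, fitch_bottom_up, fitch_top_down, parse_newick

newick = "(((A:0.1,B:0.1):0.1,C:0.1):0.1,(D:0.1,E:0.1):0.1);"
states = {"A": 1, "B": 2, "C": 1, "D": 3, "E": 1}

tree = parse_newick(newick, "probability", ModelParams(N=4))
ann = fitch_bottom_up(tree, N=4, leaf_states=states)
ann = fitch_top_down(ann, tree, np.random.default_rng(seed=1))

print(f"leaf states: {states}")
print(f"parsimony score (union events): {ann.union_count}")
for k, node in enumerate(tree.preorder()):
    label = node.name or f"internal-{k}"
    members = "{" + ",".join(map(str, sorted(ann.node_set(node)))) + "}"
    print(f"  {label:12s} set={members:10s} chosen={ann.node_state(node)}")
print("The root set lists every state an optimal labeling can place at the")
print("root; the chosen column is one uniformly drawn optimal labeling.")
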