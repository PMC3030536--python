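"""When do fewer taxa reconstruct the root better?

On a strongly unbalanced (comb-shaped) tree the leaf nearest the root can
beat the full taxon set: restricting the tree to that single leaf gives
accuracy q (its one-branch conservation probability), while the full comb's
accuracies stay below it.  On a balanced tree with conserved characters the
full taxon set wins instead.
"""

from fitchacc import (
    build_comb,
    build_complete_binary,
    path_accuracy,
    restrict_to_leafset,
    tree_accuracy,
)

N, q = 4, 0.9
p = (1 - q) / (N - 1)

comb = build_comb(30, p)
nearest = comb.root.children[0].name or comb.root.children[1].name
all_taxa = tree_accuracy(comb, N)
only_nearest = tree_accuracy(restrict_to_leafset(comb, {nearest}, N), N)

print(f"comb, 30 leaves, q={q}, N={N}:")
print(f"  all 30 taxa   : UA={all_taxa.ua:.4f}  AA={all_taxa.aa:.4f}")
print(f"  nearest leaf  : UA=AA={only_nearest.ua:.4f}  (equals q={q})")

balanced = build_complete_binary(6, p)  # 64 leaves
all_b = tree_accuracy(balanced, N)
path = path_accuracy(6, p, N)
print(f"complete binary, 64 leaves, q={q}, N={N}:")
print(f"  all 64 taxa   : UA={all_b.ua:.4f}  AA={all_b.aa:.4f}")
print(f"  one 6-branch root-to-leaf path: UA=AA={path:.4f}")
print("Unbalanced tree: copy the nearest taxon. Balanced tree with high q:")
print("use everything.")
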