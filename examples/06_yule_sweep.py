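"""Accuracy on random birth-process (Yule) trees vs the balanced reference.

Generates Yule topologies, assigns one common conservation probability q to
every branch, sweeps q, and compares against the equal-branch complete
binary tree with the same leaf count.  Yule trees behave like the balanced
tree: below the threshold b the ambiguous accuracy sits at random-guessing
1/N, above it accuracy climbs quickly — and individual Yule trees can even
beat the balanced reference.
"""

from fitchacc import yule_experiment

df = yule_experiment(n_trees=20, n_leaves=256, q_grid=[0.5, 0.7, 0.85, 0.95],
                     N=4, seed=7)
yule = df[df.tree != "complete-binary"]
ref = df[df.tree == "complete-binary"].set_index("q")

print("q     AA(complete)  AA(yule median)  AA(yule max)")
for q in sorted(ref.index):
    sub = yule[yule.q == q]
    print(f"{q:.2f}  {ref.loc[q, 'aa']:12.4f}  {sub.aa.median():15.4f}"
          f"  {sub.aa.max():12.4f}")
print("At q=0.5 (below b≈0.82 for N=4) every tree is near 1/N = 0.25; at")
print("q=0.95 all are informative, and the best Yule tree can edge past the")
print("balanced tree.")
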