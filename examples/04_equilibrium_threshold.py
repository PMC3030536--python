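"""The equilibrium threshold b of balanced trees.

On ever-larger equal-branch complete binary trees, the ambiguous accuracy
converges to random guessing 1/N whenever the per-branch conservation
probability q stays below a threshold b, and only above b does the tree's
information survive to the root.  This locates b by bisection for several
state counts; b shrinks slowly as the number of states grows.
"""

from fitchacc import estimate_threshold_b

for N in (2, 4, 10):
    res = estimate_threshold_b(N)
    print(f"N={N:2d}: equilibrium interval of q = [{res.a:.4f}, {res.b:.4f}]")

print("Inside [a, b] the Fitch method on the full balanced tree is no better")
print("than picking one of the N states at random; for N=2 there is also a")
print("divergent regime below a where even and odd tree depths disagree.")
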