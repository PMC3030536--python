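"""Limiting accuracy on ultrametric caterpillars (Hennigian combs).

As a Hennigian comb grows, ambiguous accuracy degenerates to random
guessing 1/N, while unambiguous accuracy converges to a closed-form limit
that does not depend on the edge length.  The closed form (exact integer
arithmetic) is compared with the recurrence run at 2000 leaves.
"""

from fitchacc import hennigian_accuracy, hennigian_limiting_ua, hennigian_limiting_ua_exact

for N in (2, 4, 5, 20):
    limit = hennigian_limiting_ua(N)
    frac = hennigian_limiting_ua_exact(N)
    rec = hennigian_accuracy(2000, l=0.1, rate=1.0, N=N)
    print(f"N={N:2d}: UA limit = {limit:.6f} (= {frac.numerator}/{frac.denominator})"
          f"   recurrence at n=2000: UA={rec.ua:.6f}  AA={rec.aa:.6f}")

print("AA equals 1/N in the limit for every N: on very unbalanced ultrametric")
print("trees the Fitch root set carries almost no usable signal.")
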