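"""Differential tag counts, rarefaction and OTU sharing.

The Audic-Claverie test asks: given x counts of a tag in a library of size
N1, is the observed count y in a library of size N2 compatible with equal
underlying abundance? The expected range is the equal-tail interval of the
conditional distribution p(y|x) at the chosen significance level.
"""

from ampliscreen.stats import ac_test, rarefaction, venn_sharing

# one species: 12 reads in a 50,000-read V4 sample vs 3,100 reads in a
# 1,500,000-read V9 sample of the same water
r = ac_test(x=12, y=3100, N1=50_000, N2=1_500_000, alpha=0.05)
print(f"observed y = {r.y}, expected range at alpha 0.05 = {r.expected_range}")
print(f"two-sided p = {r.p_two_sided:.3g}, significant = {r.significant}")

r0 = ac_test(x=12, y=380, N1=50_000, N2=1_500_000)
print(f"\ny = 380 inside {r0.expected_range}? significant = {r0.significant}")

print("\nRarefaction of an OTU size spectrum (how fast richness saturates):")
sizes = [500, 120, 40, 9, 5, 3, 3]
grid = [10, 50, 100, 300, 680]
print(rarefaction(sizes, grid).to_string(index=False))

print("\nOTU sharing between three sites (Venn regions):")
regions = venn_sharing({
    "Naples": {"o1", "o2", "o3", "o5"},
    "Oslo": {"o2", "o3", "o4"},
    "Varna": {"o3"},
})
for combo, count in regions.items():
    print(f"  only {'+'.join(combo)}: {count}")
print(
    "\nA significant count test means the library-size difference alone cannot\n"
    "explain the abundance difference; the rarefaction column 'expected_otus'\n"
    "is the expected richness in a random subsample of n reads."
)
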