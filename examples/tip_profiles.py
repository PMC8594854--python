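"""Long-term TE insertion polymorphism (TIP) profiles across populations.

Builds a 9-genotype, 3-population panel with shared, population-private and
singleton insertion sites, then summarizes site classes, embeds genotypes
by PCA, scores k-means cluster purity against population of origin, and
runs the goodness-of-fit G-test on the per-population singleton counts.
"""

import temara as tm

tip = tm.make_population_panel(
    n_populations=3, genotypes_per_pop=3,
    n_shared=8, n_pop_private=12, n_singleton=9, seed=3,
)

summary = tm.polymorphism_summary(tip)
print(f"total sites: {summary.total_sites}")
print(f"polymorphic: {summary.polymorphic_sites} "
      f"({100 * summary.polymorphic_fraction:.0f}%)")
print(f"singletons: {summary.singletons}  by population: "
      f"{summary.singletons_by_population}")
print(f"population-specific: {summary.population_specific}, "
      f"shared: {summary.shared}")

coords, variance = tm.pca_embed(tip)
print(f"\nPCA variance explained: PC1 {variance[0]:.2f}, PC2 {variance[1]:.2f}")
purity = tm.kmeans_purity(tip, k=3, seed=0)
print(f"k-means (k=3) purity vs population labels: {purity:.2f}")

counts = list(summary.singletons_by_population.values())
g, df = tm.g_test(counts)
print(f"\nG-test on singleton counts {counts}: G = {g:.2f}, df = {df}")
print(
    "\nPurity 1.0 reproduces the qualitative observation that insertion-site"
    "\npolymorphism separates genotypes into non-overlapping population "
    "clusters;\nthe G-test asks whether singletons are unevenly distributed "
    "among populations."
)
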