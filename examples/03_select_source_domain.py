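"""Select the optimal source-domain species from a multi-species collection.

The three feature distance matrices are scale-normalized so their ranges
coincide, embedded in 2-D by classical MDS, fused by PCA into one plane
(x = shape, y = color + texture), clustered with DBSCAN, and each
cluster's medoid — the species with the smallest mean distance to its
co-members — is recommended as the source domain for the whole cluster.
"""

from phenosynth import commonality as cm
from phenosynth import fixtures as fx

specs = fx.demo_species(3, seed=0)
sprites = fx.generate_species_collection(specs, n_per_species=8)

selection = cm.select_optimal_sources(
    sprites, level="image", min_samples=4, seed=0,
    out_json="selection.json", plot_path="selection.png",
)
ids = selection.clusters.cluster_ids
print(f"eps (auto): {selection.clusters.eps:.3f}")
print(f"clusters found: {sorted(set(ids) - {-1})}, noise points: {(ids == -1).sum()}")
for cid, ranked in sorted(selection.recommendations.items()):
    print(f"cluster {cid}: optimal source = {ranked[0]} (then {ranked[1:3]})")
# The medoid species is the one whose phenotype is most central in its
# cluster — translating it reaches the other members with least change.
print("wrote selection.json and selection.png")
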