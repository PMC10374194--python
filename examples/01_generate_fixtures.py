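"""Generate a small multi-species sprite collection and an orchard background.

Each species is defined by a superellipse shape (exponent + aspect), a
CIELAB color center, and a texture-noise contrast; the background is a
layered sky/tree/ground image with a ground-truth region mask.
"""

import numpy as np

from phenosynth import fixtures as fx

specs = fx.demo_species(3, seed=0)
sprites = fx.generate_species_collection(specs, n_per_species=4)
print(f"generated {len(sprites)} sprites across {len(specs)} species")
for spec in specs:
    print(
        f"  {spec.species_id}: superellipse n={spec.shape_exponent}, "
        f"aspect={spec.aspect}, Lab center={spec.lab_center}"
    )

leaf = fx.generate_leaf_sprite(seed=0, index=0)
print(f"leaf sprite foreground area: {leaf.mask.sum()} px")

image, mask = fx.generate_background(512, 512, seed=0)
fractions = {name: float((mask == k).mean()) for k, name in
             enumerate(["sky", "tree", "ground"])}
print("background band fractions:", {k: round(v, 3) for k, v in fractions.items()})
# The tree band is the only region where fruits may later be placed.
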