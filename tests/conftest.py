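"""Shared fixtures: all test inputs are generated procedurally."""

from __future__ import annotations

import numpy as np
import pytest

from phenosynth import fixtures as fx
from phenosynth import synthesis
from phenosynth._rng import stream


@pytest.fixture(scope="session")
def disc_spec():
    """A species whose outline is an exact disc (single-harmonic boundary)."""
    return fx.SpeciesSpec(
        species_id="disc",
        shape_exponent=2.0,
        aspect=1.0,
        wobble=0.0,
        lab_center=(70.0, 40.0, 50.0),
        lab_spread=(0.0, 0.0, 0.0),
        texture_contrast=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def disc_sprite(disc_spec):
    return fx.generate_fruit_sprite(disc_spec, 0)


@pytest.fixture(scope="session")
def demo_sprites():
    """3 well-separated species x 4 sprites, for descriptor-level tests."""
    specs = fx.demo_species(3, seed=5)
    return fx.generate_species_collection(specs, 4)


@pytest.fixture(scope="session")
def leaf_sprites():
    return [fx.generate_leaf_sprite(3, i) for i in range(5)]


@pytest.fixture(scope="session")
def background():
    return fx.generate_background(512, 512, seed=21)


@pytest.fixture(scope="session")
def scene_inputs():
    """Sprites, leaves, and backgrounds for scene synthesis tests."""
    specs = fx.demo_species(3, seed=0)
    sprites = fx.generate_species_collection(specs, 6)
    leaves = [fx.generate_leaf_sprite(0, i) for i in range(10)]
    backgrounds = [fx.generate_background(512, 512, b)[0] for b in range(4)]
    return sprites, leaves, backgrounds


@pytest.fixture(scope="session")
def scene_batch(scene_inputs):
    """100 scenes, 10-30 fruits each, fixed seed — shared by the
    occlusion-bound and label-fidelity checks."""
    sprites, leaves, backgrounds = scene_inputs
    config = synthesis.SceneConfig(n_fruits=(10, 30), max_occlusion=0.5, seed=1234)
    scenes = []
    for s in range(100):
        rng = stream(config.seed, 100, s)
        bg = backgrounds[int(rng.integers(len(backgrounds)))]
        scenes.append(
            synthesis.build_scene(bg, sprites, leaves, config, rng)
        )
    return scenes
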