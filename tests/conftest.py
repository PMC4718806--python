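"""Shared fixtures: small phantoms, simulated stacks, and tmp I/O paths."""

import numpy as np
import pytest

from cryofocus import VolumeGrid
from cryofocus.masks import make_soft_mask, pseudo_atoms_to_map
from cryofocus.simulation import (
    SimRecipe,
    build_two_class_phantom,
    calibrate_two_class_noise,
    simulate_particles,
)
from cryofocus.subtraction import subtract_signal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def smooth_volume():
    """A compact, band-limited 32-cube test volume (sum of Gaussian blobs)."""
    n = 32
    g = np.arange(n) - n // 2
    z, y, x = np.meshgrid(g, g, g, indexing="ij")
    data = (
        np.exp(-((x - 3) ** 2 + (y + 2) ** 2 + z**2) / (2 * 2.0**2))
        + 0.7 * np.exp(-((x + 4) ** 2 + (y - 1) ** 2 + (z + 3) ** 2) / (2 * 1.8**2))
        + 0.5 * np.exp(-(x**2 + (y + 5) ** 2 + (z - 4) ** 2) / (2 * 1.5**2))
    )
    return VolumeGrid(data, 1.0)


@pytest.fixture(scope="session")
def two_class_setup():
    """Phantoms A (body+rod) and B (body), focus spec and focus mask, box 32."""
    a, b, focus = build_two_class_phantom(
        box=32, pixel_size=2.8, rod_length=30.0, rod_offset=(19.0, 4.0, 0.0)
    )
    focus_map = pseudo_atoms_to_map(a.parts["rod"], 32, 2.8)
    mask = make_soft_mask(
        focus_map, threshold=0.1 * focus_map.data.max(), extend_px=2, soft_edge_px=3
    )
    return {"a": a, "b": b, "focus": focus, "mask": mask}


@pytest.fixture(scope="session")
def clean_sim(two_class_setup):
    """Noise-free simulation of 2 x 100 particles from the two phantoms."""
    recipe = SimRecipe(n_per_class=100, pixel_size=2.8, seed=11)
    return simulate_particles([two_class_setup["a"], two_class_setup["b"]], recipe)


@pytest.fixture(scope="session")
def noisy_sim(two_class_setup):
    """Calibrated-noise simulation of 2 x 250 particles, plus its spectrum."""
    base = SimRecipe(n_per_class=250, pixel_size=2.8, seed=11)
    spec = calibrate_two_class_noise(two_class_setup["a"], two_class_setup["b"], base)
    recipe = SimRecipe(n_per_class=250, pixel_size=2.8, seed=11, noise=spec)
    sim = simulate_particles([two_class_setup["a"], two_class_setup["b"]], recipe)
    return {"sim": sim, "spectrum": spec, "recipe": recipe}


@pytest.fixture(scope="session")
def subtracted_noisy(two_class_setup, noisy_sim):
    sim = noisy_sim["sim"]
    images, particles = subtract_signal(
        sim.particles, sim.images, two_class_setup["b"].volume
    )
    return {"images": images, "particles": particles}
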