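"""Shared fixtures: standard synthetic scenes for the imaging tests."""

import dataclasses

import numpy as np
import pytest

from guvpurify import synthetic as syn


@pytest.fixture(scope="session")
def default_optics():
    """In-focus imaging conditions used across detection tests."""
    return syn.OpticsSpec(noise_sd=15.0, out_of_focus_fraction=0.0)


@pytest.fixture(scope="session")
def ring_scene(default_optics):
    """Ten non-overlapping membrane-labeled GUVs with ground truth (SNR ~ 200)."""
    pop = syn.ola_population(10)
    diam = syn.sample_population(pop, 11)
    objects = syn.place_objects(
        diam["diameter_um"].to_numpy(),
        default_optics,
        intensities={"m": 3000.0},
        appearance={"m": "ring"},
        seed=12,
    )
    image, truth = syn.render_micrograph(objects, default_optics, ["m"], 13)
    return objects, image, truth


@pytest.fixture(scope="session")
def noiseless_optics(default_optics):
    """Noise-free, unquantized, zero-background variant for exactness checks."""
    return dataclasses.replace(
        default_optics,
        noise_sd=0.0,
        background_mean=0.0,
        quantize=False,
    )
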