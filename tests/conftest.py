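"""Shared fixtures: simulated screens reused across test modules.

Screens are generated once per session; tests treat them as read-only.
"""

import numpy as np
import pytest

from ndscreen import (
    ScreenAnalysis,
    SimConfig,
    default_surfaces,
    generate_library,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """20-fragment screen, default noise: fast end-to-end fixture."""
    library = generate_library(n=20, seed=11)
    return simulate_screen(library, default_surfaces(), SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_results(small_screen):
    model = ScreenAnalysis(
        small_screen.sample_sheet, small_screen.sensorgrams,
        small_screen.surfaces,
    )
    return model.fit()


@pytest.fixture(scope="session")
def full_screen():
    """Full-size screen: 140 fragments, 10% planted binders, 5% pathologies."""
    library = generate_library(n=140, seed=7)
    return simulate_screen(library, default_surfaces(), SimConfig(seed=7))


@pytest.fixture(scope="session")
def full_results(full_screen):
    model = ScreenAnalysis(
        full_screen.sample_sheet, full_screen.sensorgrams,
        full_screen.surfaces,
    )
    return model.fit()


@pytest.fixture(scope="session")
def noiseless_screen():
    """Noise-free full screen for bias (not variance) checks."""
    library = generate_library(n=140, seed=3)
    return simulate_screen(library, default_surfaces(),
                           SimConfig(seed=3, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_results(noiseless_screen):
    model = ScreenAnalysis(
        noiseless_screen.sample_sheet, noiseless_screen.sensorgrams,
        noiseless_screen.surfaces,
    )
    return model.fit()
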