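"""Shared fixtures: session-scoped synthetic sections (generation is the
expensive step, measurement is cheap, so sections are built once)."""

import numpy as np
import pytest

from myophen.synth import SectionParams, make_section


@pytest.fixture(scope="session")
def section_default():
    """Default-parameter section (150 fibers, default noise), seed 3."""
    return make_section(SectionParams(seed=3))


@pytest.fixture(scope="session")
def section_clean():
    """Noise-free default section, seed 6 (for segmentation/intensity)."""
    return make_section(SectionParams(seed=6, noise_sd=0.0))


@pytest.fixture(scope="session")
def section_small():
    """Small, fast section (40 fibers) for structural tests."""
    return make_section(SectionParams(seed=11, n_fibers=40))


@pytest.fixture(scope="session")
def section_500():
    """Large section (500 fibers) for size-law convergence checks."""
    return make_section(SectionParams(seed=17, n_fibers=500))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
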