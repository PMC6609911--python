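"""Shared fixtures: seeded RNGs and a small simulated study."""

import numpy as np
import pytest

import amplipop as ap


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-population study used by several IO/summary tests."""
    rng = np.random.default_rng(42)
    design = ap.SampleDesign(sites=(
        ap.SampleSite("M1", 1, 4), ap.SampleSite("M2", 1, 4),
        ap.SampleSite("L1", 2, 4), ap.SampleSite("L2", 2, 4)))
    params = ap.IMParams(theta_pop1=5.0, theta_pop2=5.0, theta_anc=5.0,
                         t_split=0.5, m_1to2=0.3, m_2to1=0.05)
    return ap.generate_study(design, params, n_loci=6, locus_length=200,
                             coverage=30, read_length=170,
                             error_rate=0.002, chimera_rate=0.1, rng=rng)
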