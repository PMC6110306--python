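"""Shared fixtures.

The heavier Monte Carlo products (planar bar-phantom studies for both
collimators, the tomographic spectrum run and the SPECT acquisition)
are session-scoped so the acceptance tests and unit tests share one
simulation each.  Sizes are desk-scale: large enough for the quadrant
modulation fits and window fractions to be stable, small enough to keep
the whole suite within minutes.
"""

import math

import numpy as np
import pytest

from hgspect import engine, geometry, nuclide, tomo, workflow


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def lehr_report():
    cfg = workflow.RunConfig(
        collimator="lehr", activity_ratio=5.92,
        histories_per_channel={70.0: 4_000_000, 77.0: 3_000_000,
                               134.0: 2_000_000, 279.0: 1_000_000},
        seed=101)
    return workflow.run_planar_study(cfg)


@pytest.fixture(scope="session")
def hegp_report():
    cfg = workflow.RunConfig(
        collimator="hegp", activity_ratio=10.6,
        histories_per_channel={70.0: 5_000_000, 77.0: 2_000_000,
                               134.0: 1_000_000, 279.0: 500_000},
        seed=102)
    return workflow.run_planar_study(cfg)


@pytest.fixture(scope="session")
def tomo_isotropic_events():
    """Isotropic-emission tomographic run for scatter-origin analysis."""
    scene = geometry.abdominal_scene()
    iso = {E: math.pi for E in (70.0, 77.0, 134.0, 279.0)}
    return engine.run_channels(scene, n_per_channel=1_200_000, seed=103,
                               cones=iso)


@pytest.fixture(scope="session")
def spect_volume():
    """Reduced abdominal SPECT acquisition and OSEM reconstruction."""
    scene = geometry.abdominal_scene()
    mix = nuclide.default_mixture(3.7)
    ant, post = tomo.acquire_projections(scene, mix,
                                         n_per_channel=200_000,
                                         seed=104, n_positions=45)
    vol = tomo.osem_reconstruct(ant.combined_with(post), 2, 8)
    return ant, post, vol


@pytest.fixture(scope="session")
def small_planar_events():
    """One small mono-energetic planar run reused by unit tests."""
    scene = geometry.planar_bar_scene("lehr")
    return engine.run_monoenergetic(scene, 134.0, 400_000, seed=7)
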