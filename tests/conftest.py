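import numpy as np
import pytest

from xyloscan import RingTruth, SeasonTruth, TreeSigmoid

PITCH = 2.49


@pytest.fixture
def ring_truth():
    """A mid-season ring: cambium 150 μm, transition 550 μm, boundary 1150 μm."""
    return RingTruth(cambium_pos=150.0, transition_pos=550.0,
                     prev_boundary_pos=1150.0)


@pytest.fixture
def noisy_ring_truth():
    return RingTruth(cambium_pos=150.0, transition_pos=550.0,
                     prev_boundary_pos=1150.0, noise_sd=300.0, seed=11)


@pytest.fixture
def valley_truth():
    """Ring with a phloem-side rise so the cambium sits in a density valley."""
    return RingTruth(cambium_pos=150.0, transition_pos=550.0,
                     prev_boundary_pos=1150.0, phloem_gray=30000.0,
                     cambium_flat_halfwidth=30.0, cambium_gray=8000.0,
                     ramp="smoothstep")


def make_season(n_trees=4, noise_sd=25.0, seed=7, w_prev_cv=0.15, biomass_lag=10.0):
    rng = np.random.default_rng(seed)
    doys = tuple(range(90, 90 + 14 * 18, 14))
    return SeasonTruth(
        incr=tuple(TreeSigmoid(1000 + 120 * rng.standard_normal(),
                               170 + 8 * rng.standard_normal(), 18.0)
                   for _ in range(n_trees)),
        mat=tuple(TreeSigmoid(700 + 80 * rng.standard_normal(),
                              195 + 8 * rng.standard_normal(), 20.0)
                  for _ in range(n_trees)),
        doys=doys,
        w_prev=tuple(1200.0 for _ in range(n_trees)),
        noise_sd=noise_sd, w_prev_cv=w_prev_cv, biomass_lag=biomass_lag,
        seed=seed)


@pytest.fixture
def season_truth():
    return make_season()


@pytest.fixture
def quiet_season_truth():
    return make_season(noise_sd=0.0, w_prev_cv=0.0)
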