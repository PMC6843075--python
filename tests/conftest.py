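import numpy as np
import pytest

from spheromotion.synthgen import (
    SceneConfig,
    ShellSpec,
    SpheroidSpec,
    make_rotating_movie,
    make_shell_stack,
)


@pytest.fixture(scope="session")
def clean_short_movie():
    """Noise/drift-free 1-h movie rotating CCW at 0.26 rev/h (7.8 deg/step)."""
    scene = SceneConfig(duration_h=1.0, noise_sigma=0.0, drift_um_per_h=0.0, seed=101)
    return make_rotating_movie(scene, SpheroidSpec(omega_rev_h=0.26))


@pytest.fixture(scope="session")
def default_noise_movie():
    """Default-noise, default-drift 15-h movie at the untreated rate."""
    scene = SceneConfig(seed=202)
    return make_rotating_movie(scene, SpheroidSpec(omega_rev_h=0.28))


@pytest.fixture(scope="session")
def full_shell_stack():
    """Continuous thin shell, radius 10 um, thickness 2 um, no noise."""
    scene = SceneConfig(seed=303, noise_sigma=0.0)
    return make_shell_stack(
        scene, ShellSpec(radius_um=10.0, shell_thickness_um=2.0, coverage_fraction=1.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(9)
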