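import numpy as np
import pytest

from ceusvv import (
    KineticsParams,
    PhantomGeometry,
    default_cohort_config,
    render_cine_loop,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fixture_geometry():
    return PhantomGeometry(
        image_height=16,
        image_width=16,
        lumen_band=(6, 10),
        adventitia_bands=((3, 5), (11, 13)),
    )


@pytest.fixture(scope="session")
def noiseless_loop(fixture_geometry):
    """Noiseless 16x16 loop: lumen baseline 10, A=40, beta=0.5, pulse at 2 s."""
    lum = KineticsParams(baseline=10.0, amplitude=40.0, rate=0.5, onset_time=2.0)
    adv = KineticsParams(baseline=10.0, amplitude=16.0, rate=0.5, onset_time=2.0)
    return render_cine_loop(
        fixture_geometry,
        lum,
        adv,
        noise_sd=0.0,
        frame_rate=5.0,
        duration=22.0,
        background_level=10.0,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Tiny cached-TIC cohort (2 animals per group, all six groups)."""
    cfg = default_cohort_config(n_per_group=2, seed=3, duration=10.0)
    return simulate_cohort(cfg, render="tics")
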