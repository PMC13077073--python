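import numpy as np
import pytest

from mesokit.synthetic import (
    CalciumSceneSpec,
    PhantomSpec,
    generate_ao_sample,
    generate_calcium_traces,
    generate_vascular_phantom,
)


@pytest.fixture(scope="session")
def straight_tube():
    """Axis-aligned tube, radius 5 um, spanning the whole x extent, 1 um grid."""
    spec = PhantomSpec(
        shape_voxels=(40, 60, 120),
        spacing_um=(1.0, 1.0, 1.0),
        segments=[((20.0, 30.3, -50.0), (20.0, 30.3, 170.0), 5.0)],
    )
    stack, truth = generate_vascular_phantom(spec, seed=0)
    return spec, stack, truth


@pytest.fixture(scope="session")
def y_phantom():
    """Three tubes meeting at one junction on an isotropic 1 um grid."""
    c = (30.0, 50.0, 50.0)
    spec = PhantomSpec(
        shape_voxels=(60, 100, 100),
        spacing_um=(1.0, 1.0, 1.0),
        segments=[
            (c, (58.0, 50.0, 50.0), 4.0),
            (c, (5.0, 80.0, 50.0), 4.0),
            (c, (5.0, 20.0, 50.0), 4.0),
        ],
    )
    stack, truth = generate_vascular_phantom(spec, seed=0)
    return spec, stack, truth


@pytest.fixture(scope="session")
def coupled_scene():
    """Region-coupled calcium scene with locomotion gain (the Fig.-5-like
    condition: strong intra-region coupling, weak inter, moving gain 3)."""
    spec = CalciumSceneSpec(
        n_neurons=60,
        n_regions=3,
        duration_s=600.0,
        frame_rate_hz=7.0,
        intra_region_coupling=0.8,
        inter_region_coupling=0.1,
        moving_gain=3.0,
        seed=0,
    )
    f, f_np, truth, loco = generate_calcium_traces(spec)
    return spec, f, f_np, truth, loco


@pytest.fixture(scope="session")
def ao_sample():
    return generate_ao_sample(128, 8, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
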