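import numpy as np
import pytest

from autocascade.phantom import (
    CanalSpec,
    CochleaSpec,
    ConfounderSpec,
    IntensitySpec,
    PhantomSpec,
    VestibuleSpec,
    generate_phantom,
)


def tiny_phantom_spec(**kwargs) -> PhantomSpec:
    """32³ phantom with proportionally scaled geometry — fast unit-test prop."""
    defaults = dict(
        grid_size=32,
        cochlea=CochleaSpec(base_radius_vox=5.0, tube_radius_vox=1.5),
        canals=[
            CanalSpec(normal=(1.0, 0.15, -0.1), arc_radius_vox=4.5, tube_radius_vox=1.2),
            CanalSpec(normal=(-0.1, 1.0, 0.15), arc_radius_vox=4.5, tube_radius_vox=1.2),
            CanalSpec(normal=(0.15, -0.1, 1.0), arc_radius_vox=4.5, tube_radius_vox=1.2),
        ],
        vestibule=VestibuleSpec(semi_axes_vox=(2.5, 2.0, 2.0)),
        confounders=ConfounderSpec(count=0),
        intensity=IntensitySpec(noise_sigma=0.02, blur_sigma_vox=0.5),
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return tiny_phantom_spec()


@pytest.fixture(scope="session")
def tiny_sample(tiny_spec):
    return generate_phantom(tiny_spec, seed=7)


@pytest.fixture(scope="session")
def default_sample():
    return generate_phantom(PhantomSpec(), seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
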