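import numpy as np
import pytest

from adreseg.phantom import OrganSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def small_spec(**overrides) -> PhantomSpec:
    """A 32^3 phantom spec with one centred tumor, cheap to render."""
    kwargs = dict(
        grid_size=(32, 32, 32),
        spacing=(2.0, 2.0, 2.0),
        n_tumors=1,
        tumor_centers_mm=((32.0, 32.0, 32.0),),
        tumor_axes_mm=((12.0, 9.0, 7.0),),
        seed=42,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_case():
    return make_phantom(small_spec())


@pytest.fixture(scope="session")
def bilateral_case():
    spec = small_spec(
        n_tumors=2,
        tumor_centers_mm=((16.0, 32.0, 32.0), (48.0, 32.0, 32.0)),
        tumor_axes_mm=((8.0, 6.0, 6.0), (8.0, 6.0, 6.0)),
        organs=(
            OrganSpec((16.0, 44.0, 32.0), (10.0, 8.0, 10.0)),
            OrganSpec((48.0, 44.0, 32.0), (10.0, 8.0, 10.0)),
        ),
    )
    return make_phantom(spec)
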