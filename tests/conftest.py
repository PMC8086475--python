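import numpy as np
import pytest
from hypothesis import settings

from fastraman.library import WAVENUMBERS, spectral_library
from fastraman.phantom import PhantomSpec, RegionSpec, Spectrum
from fastraman.runner import default_model

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    """Default multiclass model trained on library-drawn spectra."""
    return default_model(11)


@pytest.fixture(scope="session")
def library():
    return spectral_library()


@pytest.fixture()
def make_spectrum():
    def _make(intensities, exposure=2.0, position=(0.0, 0.0)):
        return Spectrum(
            wavenumbers=WAVENUMBERS,
            intensities=np.asarray(intensities, float),
            position=position,
            exposure=exposure,
        )

    return _make


@pytest.fixture()
def mixed_layer_spec():
    """Dermis background with one BCC disc plus benign structures."""
    return PhantomSpec(
        width_mm=6.0,
        height_mm=6.0,
        regions=[
            RegionSpec("fat", (1.5, 1.5), diameter_um=800),
            RegionSpec("bcc", (4.5, 1.5), diameter_um=500),
            RegionSpec("epidermis", (4.5, 4.5), diameter_um=800),
            RegionSpec("inflamed_dermis", (1.5, 4.5), diameter_um=700),
        ],
    )
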