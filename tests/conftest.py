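import numpy as np
import pytest

from cxplaque.colocalization import PARENCHYMAL, VASCULAR
from cxplaque.scene import (AstrocyteSpec, NoiseSpec, PlaqueSpec, SceneConfig,
                            TubeSpec)
from cxplaque.spectral import default_reference_spectra


@pytest.fixture(scope="session")
def refs():
    """Default six-dye model fingerprints on the 32-bin 411-754 nm grid."""
    return default_reference_spectra()


def make_scene_config(field=(2, 96, 96), seed=0, noise=None, class_means=None,
                      vessels="default", **kwargs):
    """Small, fast scene configuration for tests."""
    if vessels == "default":
        vessels = [TubeSpec((4.1, 2.0, 2.0), (4.1, 22.0, 22.0), 2.0)]
    if class_means is None:
        class_means = {"Cx30": {PARENCHYMAL: 5.0, VASCULAR: 2.0},
                       "Cx43": {PARENCHYMAL: 4.0, VASCULAR: 2.0},
                       "Cx26/Cx45": {PARENCHYMAL: 2.0, VASCULAR: 1.0}}
    return SceneConfig(
        field_shape=field,
        voxel_size=(8.2, 0.25, 0.25),
        vessels=vessels or [],
        astrocytes=AstrocyteSpec(count=2, process_count=3, process_length_um=8.0),
        plaques=PlaqueSpec(class_means=class_means),
        noise=noise or NoiseSpec(background=0.0, autofluorescence=0.0),
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def scene_config():
    return make_scene_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
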