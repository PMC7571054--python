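import numpy as np
import pytest

from texsep.textures import TextureImage, TextureLibrary, generate_procedural_texture


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def constant_texture(value, size=(64, 64), tag="const"):
    px = np.full((*size, 3), value, dtype=np.float32)
    return TextureImage(pixels=px, source_id=f"{tag}:{value}")


@pytest.fixture
def two_color_library():
    """Two constant-color textures; mosaics assembled from them are piecewise constant."""
    return TextureLibrary(
        [constant_texture(0.2, tag="dark"), constant_texture(0.9, tag="light")],
        name="two-color",
    )


@pytest.fixture
def procedural_library():
    return TextureLibrary(
        [
            generate_procedural_texture("stripes", size=(96, 96), seed=0),
            generate_procedural_texture("blob_noise", size=(96, 96), seed=1),
        ],
        name="procedural-pair",
    )
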