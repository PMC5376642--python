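import pytest

from ferrofossil import load_mineral_table
from ferrofossil.synthetic import SceneParams, generate_section_scene


@pytest.fixture(scope="session")
def minerals():
    return load_mineral_table()


@pytest.fixture(scope="session")
def default_scene():
    """One mid-cell section of the default thick-walled spheroid scene."""
    params = SceneParams(seed=1, section_offset_um=0.0)
    return generate_section_scene(params)


@pytest.fixture(scope="session")
def noisefree_scene():
    """Noise-free section for exact segmentation checks."""
    params = SceneParams(
        seed=2, section_offset_um=0.5, noise_gaussian_sd=0.0,
        pixel_size_nm=15.0, frame_margin_um=1.0,
    )
    return generate_section_scene(params)
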