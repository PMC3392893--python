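from dataclasses import replace

import pytest

from odfind.kernels import build_bank
from odfind.pipeline import detect
from odfind.synthetic import default_scene, generate

REFERENCE_SCALES = ((1.5, 9), (1.8, 9), (2.0, 13), (2.4, 13))


@pytest.fixture(scope="session")
def default_render():
    """The reference synthetic scene (seed 0): spec, rendered RGB, ground truth."""
    spec = default_scene(0)
    rgb, truth = generate(spec)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def default_result(default_render):
    """Full detector output on the reference scene."""
    _, rgb, _ = default_render
    return detect(rgb)


@pytest.fixture(scope="session")
def no_exudate_result():
    """Detector output on the reference scene without the exudate blob."""
    spec = replace(default_scene(0), exudate_center=None)
    rgb, truth = generate(spec)
    return spec, truth, detect(rgb)


@pytest.fixture(scope="session")
def reference_bank():
    """The standard 4-scale x 8-orientation kernel bank."""
    return build_bank(REFERENCE_SCALES, 8)
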