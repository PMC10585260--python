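import numpy as np
import pytest

from fruitpheno.synthetic import default_scene, render_scene, scene_analysis_config


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def hard_scene():
    """Speck-free hard-edged scene: truth is pixel-exact."""
    spec = default_scene(seed=11, reverted_fraction=0.3, n_specks=0, anti_alias=False)
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def hard_cfg(hard_scene):
    spec, _, _ = hard_scene
    return scene_analysis_config(spec, exact=True)


# --- independent colorimetry oracle (closed-form sRGB -> CIELAB, D65/2deg) ---

_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])


def srgb_to_lab_reference(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Textbook sRGB->linear->XYZ(D65)->CIELAB, written independently of
    the package (and of scikit-image) as the colorimetry oracle."""
    c = np.array([r, g, b], dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = _M_RGB2XYZ @ lin
    t = xyz / _WHITE_D65
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    bb = 200 * (f[1] - f[2])
    return float(L), float(a), float(bb)
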