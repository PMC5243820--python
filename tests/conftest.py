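import numpy as np
import pytest

from canopyefd.synthetic import CanopyShapeParams, generate_canopy_image


def analytic_circle(radius=10.0, n=256, center=(0.0, 0.0)):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(phi),
                            center[1] + radius * np.sin(phi)])


def analytic_ellipse(a=40.0, b=20.0, n=512, rotation=0.0, center=(0.0, 0.0)):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(phi), b * np.sin(phi)
    c, s = np.cos(rotation), np.sin(rotation)
    return np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y])


def analytic_star(radius=10.0, lobes=12, amplitude=0.25, n=256, extra=None):
    """Simple lobed closed curve; `extra` adds an asymmetric term."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + amplitude * np.cos(lobes * phi))
    if extra is not None:
        r = r + radius * extra(phi)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


@pytest.fixture(scope="session")
def canopy_sample():
    """One mid-complexity rendered canopy with debris and holes (seed 1)."""
    params = CanopyShapeParams(
        semi_axes=(80, 60), lobe_count=6, lobe_amplitude=0.15,
        debris_count=5, hole_count=2, image_size=(256, 256), seed=1,
    )
    return generate_canopy_image(params)


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory):
    """Small generated fixture suite shared by pipeline/CLI tests."""
    from canopyefd.synthetic import generate_fixture_suite

    out = tmp_path_factory.mktemp("suite")
    generate_fixture_suite(out, n=8, seed=11, image_size=(192, 192))
    return out
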