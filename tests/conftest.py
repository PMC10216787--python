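import numpy as np
import pytest

from organodeath import AcquisitionGeometry, ImageStack, make_scene, render_scene


def small_geometry(side_px: int = 384, n_planes: int = 2) -> AcquisitionGeometry:
    """Scaled-down acquisition geometry (same pixel size / z-step as the
    full-size default) so rendering and segmentation stay fast."""
    return AcquisitionGeometry(
        field_area=(side_px * 0.3) ** 2, n_planes=n_planes, z_step=25.0, pixel_size=0.3
    )


@pytest.fixture(scope="session")
def geometry():
    return small_geometry()


@pytest.fixture(scope="session")
def simple_scene(geometry):
    """Two well-separated organoids, all-viable nuclei, some debris."""
    return make_scene(
        geometry,
        n_organoids=2,
        nuclei_per_organoid=10,
        organoid_radius=(18.0, 25.0),
        debris_count=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def rendered_simple(simple_scene):
    return render_scene(simple_scene)


@pytest.fixture(scope="session")
def simple_stack(rendered_simple):
    return ImageStack.from_rendered(rendered_simple, well_id="A1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
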