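import numpy as np
import pytest

from protoview.multiview import ViewImage, render_all_views
from protoview.structure_io import normalize_model
from protoview.synthetic import generate_model


@pytest.fixture(scope="session")
def helix_model():
    return normalize_model(generate_model("helix_bundle", 5))


@pytest.fixture(scope="session")
def rendered_view(helix_model) -> ViewImage:
    """One real rendered range image with plenty of gray-level structure."""
    return render_all_views(helix_model)[0]


@pytest.fixture(scope="session")
def gaussian_blob() -> np.ndarray:
    """A single bright Gaussian blob (sigma=3) at (50, 50) on black."""
    yy, xx = np.mgrid[0:100, 0:100]
    return np.exp(-((xx - 50.0) ** 2 + (yy - 50.0) ** 2) / (2 * 3.0**2))
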