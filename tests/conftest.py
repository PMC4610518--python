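import numpy as np
import pytest

from vesselcam.calibration import load_calibration_table
from vesselcam.synthetic import CameraSpec, render_scene, table_glass


@pytest.fixture(scope="session")
def glass():
    return table_glass()


@pytest.fixture(scope="session")
def camera():
    return CameraSpec()


@pytest.fixture(scope="session")
def scene40(glass):
    """Noise-free mid-fill scene with ground truth."""
    return render_scene(glass, 40.0, seed=3)


@pytest.fixture(scope="session")
def table2():
    return load_calibration_table()


@pytest.fixture(scope="session")
def table2_pairs(table2):
    """The 14 complete non-outlier calibration rows."""
    usable = table2.loc[~table2["outlier"]].dropna(subset=["level_px", "area_px2"])
    assert len(usable) == 14
    return usable


def sample_ellipse_points(cx, cy, a, b, tilt, n=17):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = cx + a * np.cos(th) * np.cos(tilt) - b * np.sin(th) * np.sin(tilt)
    y = cy + a * np.cos(th) * np.sin(tilt) + b * np.sin(th) * np.cos(tilt)
    return np.column_stack([x, y])
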