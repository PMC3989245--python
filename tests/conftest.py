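import numpy as np
import pytest

from persistlen import SkeletonImage


@pytest.fixture
def make_image():
    """Build a SkeletonImage from a list of on-pixel (row, col) coords."""

    def _make(coords, shape=(30, 30), pixel_size=0.1):
        grid = np.zeros(shape, dtype=bool)
        for p in coords:
            grid[p] = True
        return SkeletonImage(grid=grid, pixel_size=pixel_size)

    return _make


@pytest.fixture
def quarter_circle_pixels():
    """Minimal 8-connected raster of a quarter circle of radius 50 px."""
    import math

    raw = []
    for a in np.linspace(0.0, math.pi / 2, 600):
        p = (int(round(50 * math.sin(a))) + 3, int(round(50 * math.cos(a))) + 3)
        if not raw or p != raw[-1]:
            raw.append(p)
    out = [raw[0]]
    for i in range(1, len(raw) - 1):
        if max(abs(out[-1][0] - raw[i + 1][0]),
               abs(out[-1][1] - raw[i + 1][1])) <= 1:
            continue
        out.append(raw[i])
    out.append(raw[-1])
    return out
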