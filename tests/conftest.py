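import numpy as np
import pytest

from cordmotion.phase_image_io import EllipseROI, PhaseSeries, default_cord_roi


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def centre_roi():
    # 30.52 mm^2 cord ROI centred on the 32x32 default grid
    return default_cord_roi((15.5, 15.5))


@pytest.fixture
def make_series():
    """Factory for small valid PhaseSeries with overridable fields."""

    def _make(frames=None, t=20, h=32, w=32, fill=0, **kwargs):
        if frames is None:
            frames = np.full((t, h, w), fill, dtype=np.int32)
        defaults = dict(subject_id="S01", scan_id="scan1", segment="C5",
                        venc=2.0, grey_full_scale=4096, rr_interval=1000.0,
                        pixel_spacing=(0.5, 0.5))
        defaults.update(kwargs)
        return PhaseSeries(frames=frames, **defaults)

    return _make


@pytest.fixture
def small_roi():
    # tight ellipse (5 x 3 pixel extent at 0.5 mm spacing) for enumeration tests
    return EllipseROI(center=(10.0, 10.0), semi_axis_row=1.25,
                      semi_axis_col=0.75, label="cord")
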