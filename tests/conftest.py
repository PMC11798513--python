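import numpy as np
import pytest

from braggsieve import (
    DetectorGeometry,
    SimulationSpec,
    build_bin_assignment,
    build_radius_map,
    generate,
    preprocess,
)


@pytest.fixture
def geom64() -> DetectorGeometry:
    return DetectorGeometry(n_rows=64, n_cols=64, beam_center_row=31.5, beam_center_col=31.5)


@pytest.fixture
def geom256() -> DetectorGeometry:
    return DetectorGeometry(n_rows=256, n_cols=256, beam_center_row=127.5, beam_center_col=127.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(geom256):
    """One 256x256 synthetic frame with 30 peaks and a masked gap."""
    spec = SimulationSpec(
        geometry=geom256, n_frames=1, n_peaks=30, seed=7, gap_rows=(120, 123)
    )
    return generate(spec)


@pytest.fixture
def small_pipeline(geom256, small_stack):
    """(frame, bins, stack) ready for clipping/picking tests."""
    frame = preprocess(small_stack.frames[0], mask=small_stack.mask)
    bins = build_bin_assignment(build_radius_map(geom256), small_stack.mask, n_bins=64)
    return frame, bins, small_stack
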