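import numpy as np
import pytest

from ycnv.regions import Interval, RegionSet


@pytest.fixture
def small_regions() -> RegionSet:
    """Compact region layout for fast synthetic profiles.

    Survey 1..100_000; two gene regions, one reference interval, all
    window-aligned at 1 kb except region "2" which deliberately straddles
    window boundaries.
    """
    return RegionSet(
        regions={
            "1": Interval(30_001, 34_000),
            "2": Interval(50_501, 53_700),
        },
        reference_interval=Interval(10_001, 20_000),
        survey_interval=Interval(1, 100_000),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_profile(depths, window_size=1000, start=1, sample_id="s1"):
    """Build a DepthProfile from a plain list of window depths."""
    from ycnv.depth import DepthProfile

    depths = np.asarray(depths, dtype=float)
    starts = start + window_size * np.arange(len(depths))
    span = Interval(start, int(starts[-1]) + window_size - 1)
    return DepthProfile(
        sample_id=sample_id,
        window_size=window_size,
        starts=starts,
        depths=depths,
        span=span,
    )
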