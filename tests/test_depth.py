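import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from oracles import per_base_interval_mean
from ycnv.depth import (
    CopyModelConfig,
    DepthError,
    DepthRatioSet,
    flag_curated,
    load_depth_windows,
    region_depth_ratio,
    rough_copy_number,
)
from ycnv.regions import Interval, RegionSet
from ycnv.simulate import emulate_depth


class TestLoadDepthWindows:
    def test_constant_depth_three_windows(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chrY\t0\t15000\t10\n")
        profile = load_depth_windows(path, Interval(1, 15000), 5000)
        assert len(profile) == 3
        assert np.allclose(profile.depths, 10.0)

    def test_half_covered_window_mean(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chrY\t0\t2500\t10\n")
        profile = load_depth_windows(path, Interval(1, 5000), 5000)
        assert profile.depths[0] == pytest.approx(5.0)

    def test_per_base_format_poisson_against_summation_oracle(self, tmp_path, rng):
        depths = rng.poisson(8, size=5000)
        path = tmp_path / "d.tsv"
        path.write_text(
            "".join(f"chrY\t{i + 1}\t{d}\n" for i, d in enumerate(depths))
        )
        profile = load_depth_windows(path, Interval(1, 5000), 5000)
        # one-line independent oracle: plain sum over the block
        assert profile.depths[0] == pytest.approx(sum(depths) / 5000)

    def test_last_window_truncated(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chrY\t0\t12000\t4\n")
        profile = load_depth_windows(path, Interval(1, 12000), 5000)
        assert len(profile) == 3
        assert profile.window_widths().tolist() == [5000, 5000, 2000]
        assert np.allclose(profile.depths, 4.0)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chrY\t0\t100\t4\nchrY\tnot-a-number\t200\t4\n")
        with pytest.raises(DepthError, match=":2"):
            load_depth_windows(path, Interval(1, 5000), 5000)

    def test_empty_source_errors(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("# only a comment\n")
        with pytest.raises(DepthError, match="no depth records"):
            load_depth_windows(path, Interval(1, 5000), 5000)

    def test_gzip_supported(self, tmp_path):
        import gzip

        path = tmp_path / "d.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chrY\t0\t5000\t7\n")
        profile = load_depth_windows(path, Interval(1, 5000), 5000)
        assert profile.depths[0] == pytest.approx(7.0)


class TestRegionDepthRatio:
    def test_uniform_depth_gives_unit_ratios(self, small_regions):
        profile = make_profile([13.0] * 100)
        ratios = region_depth_ratio(profile, small_regions)
        assert all(
            r == pytest.approx(1.0) for r in ratios.per_region_ratio.values()
        )
        assert ratios.combined_ratio == pytest.approx(1.0)

    def test_doubled_regions_give_combined_two(self, small_regions):
        depths = np.full(100, 5.0)
        profile = make_profile(depths)
        for iv in small_regions.regions.values():
            w = profile.overlap_weights(iv)
            depths[w > 0] = 10.0
        # region "2" straddles windows; restrict to fully-contained windows
        # by rebuilding region bounds on the window grid for this test
        aligned = RegionSet(
            regions={"1": Interval(30_001, 34_000), "2": Interval(50_001, 54_000)},
            reference_interval=small_regions.reference_interval,
            survey_interval=small_regions.survey_interval,
        )
        depths = np.full(100, 5.0)
        profile = make_profile(depths)
        for iv in aligned.regions.values():
            depths[profile.overlap_weights(iv) > 0] = 10.0
        ratios = region_depth_ratio(make_profile(depths), aligned)
        assert ratios.combined_ratio == pytest.approx(2.0)

    def test_synthetic_nine_copies_near_ten_sevenths(self):
        profile = emulate_depth(9, base_depth=20.0, noise="poisson", seed=7)
        ratios = region_depth_ratio(profile, RegionSet())
        assert ratios.combined_ratio == pytest.approx(10 / 7, rel=0.02)

    def test_matches_per_base_oracle(self, small_regions, rng):
        profile = make_profile(rng.uniform(1, 20, size=100).round(3))
        ratios = region_depth_ratio(profile, small_regions)
        ref = per_base_interval_mean(
            profile.starts, profile.depths, profile.window_size,
            profile.span.end, small_regions.reference_interval,
        )
        for name, iv in small_regions.regions.items():
            expected = per_base_interval_mean(
                profile.starts, profile.depths, profile.window_size,
                profile.span.end, iv,
            )
            assert ratios.per_region_ratio[name] == pytest.approx(expected / ref)

    def test_zero_reference_is_uninformative(self, small_regions):
        depths = np.full(100, 5.0)
        profile = make_profile(depths)
        depths[profile.overlap_weights(small_regions.reference_interval) > 0] = 0.0
        with pytest.raises(DepthError, match="uninformative"):
            region_depth_ratio(make_profile(depths), small_regions)

    def test_region_outside_span_names_region(self, small_regions):
        profile = make_profile([5.0] * 40)  # span ends at 40 000
        with pytest.raises(DepthError, match="'2'"):
            region_depth_ratio(profile, small_regions)

    @settings(max_examples=25, deadline=None)
    @given(factor=st.floats(min_value=0.01, max_value=100.0))
    def test_ratio_invariant_to_uniform_scaling(self, factor):
        regions = RegionSet(
            regions={"1": Interval(30_001, 34_000)},
            reference_interval=Interval(10_001, 20_000),
            survey_interval=Interval(1, 50_000),
        )
        depths = np.linspace(3, 9, 50)
        base = region_depth_ratio(make_profile(depths), regions)
        scaled = region_depth_ratio(make_profile(depths * factor), regions)
        assert scaled.combined_ratio == pytest.approx(base.combined_ratio)
        for name in regions.regions:
            assert scaled.per_region_ratio[name] == pytest.approx(
                base.per_region_ratio[name]
            )


class TestRoughCopyNumber:
    def _ratio(self, value):
        return DepthRatioSet("s", {}, value, 1.0)

    def test_reference_identity(self):
        assert rough_copy_number(self._ratio(1.0)) == 6

    @pytest.mark.parametrize("ratio,cn", [(0.62, 3), (1.89, 12)])
    def test_printed_ratio_extremes(self, ratio, cn):
        assert rough_copy_number(self._ratio(ratio)) == cn

    def test_ratio_two_gives_thirteen(self):
        assert rough_copy_number(self._ratio(2.0)) == 13

    def test_floored_at_zero(self):
        assert rough_copy_number(self._ratio(0.0)) == 0

    def test_half_rounds_away_from_zero(self):
        # 1.5/7 copies-equivalents: value = 0.5 exactly
        assert rough_copy_number(self._ratio(1.5 / 7)) == 1

    def test_custom_model(self):
        model = CopyModelConfig(copy_equivalents_reference=4, pseudogene_equivalents=0)
        assert rough_copy_number(self._ratio(1.0), model) == 4

    def test_round_trip_identity_noise_free(self):
        for cn in range(0, 21):
            profile = emulate_depth(cn, base_depth=10.0, noise="none")
            ratios = region_depth_ratio(profile, RegionSet())
            assert rough_copy_number(ratios) == cn


class TestFlagCurated:
    def test_constant_flanks_pass(self):
        profile = emulate_depth(9, base_depth=10.0, noise="none")
        result = flag_curated(profile, RegionSet())
        assert result.passed
        assert result.offending_windows == ()

    def test_doubled_flank_window_fails_and_is_reported(self):
        regions = RegionSet()
        profile = emulate_depth(9, base_depth=10.0, noise="none")
        target = 23_600_000  # inside the left flank
        idx = int(np.searchsorted(profile.starts, target) - 1)
        profile.depths[idx] *= 2
        result = flag_curated(profile, regions, max_rel_dev=0.25)
        assert not result.passed
        assert any(w[0] == profile.starts[idx] for w in result.offending_windows)

    def test_no_flank_windows_errors(self, small_regions):
        profile = make_profile([5.0] * 100)
        # regions fill the whole survey -> no flanks
        tight = RegionSet(
            regions={"1": Interval(1, 100_000)},
            reference_interval=Interval(150_001, 160_000),
            survey_interval=Interval(1, 200_000),
        )
        with pytest.raises(DepthError, match="no flank windows"):
            flag_curated(profile, tight)

    def test_recovers_planted_flank_duplications(self):
        regions = RegionSet()
        rng = np.random.default_rng(99)
        flagged = []
        planted = set(rng.choice(100, size=10, replace=False).tolist())
        for i in range(100):
            profile = emulate_depth(
                8, base_depth=30.0, noise="poisson", seed=1000 + i,
                sample_id=f"s{i}",
            )
            if i in planted:
                lo = np.searchsorted(profile.starts, 23_580_000)
                profile.depths[lo : lo + 10] *= 2.0
            result = flag_curated(profile, regions)
            if not result.passed:
                flagged.append(i)
        assert sorted(flagged) == sorted(planted)
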