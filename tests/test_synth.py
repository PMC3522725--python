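import numpy as np
import pytest

from mtquant.errors import ParameterError
from mtquant.synth import (
    NOISE_OFF,
    CellImageParams,
    GrowthConeParams,
    LaneParams,
    NoiseModel,
    PlateParams,
    make_cell_image,
    make_growthcone_image,
    make_lane_profiles,
    make_plate_table,
    make_zstack,
    subseed,
)
from mtquant.types import GroundTruth


class TestParams:
    def test_image_too_small(self):
        with pytest.raises(ParameterError):
            CellImageParams(image_size=(32, 32))

    def test_partition_out_of_range(self):
        with pytest.raises(ParameterError):
            CellImageParams(tyr_glu_partition=1.5)

    def test_negative_intensity(self):
        with pytest.raises(ParameterError):
            CellImageParams(filament_intensity=-1.0)

    def test_bad_peripheral_width(self):
        with pytest.raises(ParameterError):
            GrowthConeParams(peripheral_width=0.0)

    def test_invasion_out_of_range(self):
        with pytest.raises(ParameterError):
            GrowthConeParams(true_invasion_fraction=1.2)

    def test_band_outside_profile(self):
        with pytest.raises(ParameterError):
            LaneParams(band_center=5, band_width=25)

    def test_lane_fraction_out_of_range(self):
        with pytest.raises(ParameterError):
            LaneParams(fractions={"x": 1.5})

    def test_too_few_wells(self):
        with pytest.raises(ParameterError):
            PlateParams(wells_per_condition=1)

    def test_nonincreasing_concentrations(self):
        with pytest.raises(ParameterError):
            PlateParams(concentrations=(1e-9, 1e-9), shape="null")


class TestSeeds:
    def test_subseed_is_pure(self):
        assert subseed(1, 5) == subseed(1, 5)
        assert subseed(1, 5) != subseed(1, 6)
        assert subseed(1, 5) != subseed(2, 5)


class TestCellImages:
    def test_deterministic(self):
        a, ta = make_cell_image(CellImageParams(), seed=3)
        b, tb = make_cell_image(CellImageParams(), seed=3)
        for ch in a.channels:
            assert np.array_equal(a[ch], b[ch])
        assert ta.values == tb.values

    def test_equal_partition_symmetry(self):
        img, truth = make_cell_image(
            CellImageParams(tyr_glu_partition=0.5, noise=NOISE_OFF, background_level=0.0),
            seed=1,
        )
        assert truth["true_tyr_signal"] == truth["true_glu_signal"]
        assert np.array_equal(img["tyr"], img["glu"])

    def test_below_detection_construction(self):
        params = CellImageParams(below_detection=True)
        img, truth = make_cell_image(params, seed=2)
        fmap = img.meta["filament_map"]
        assert fmap.max() < params.background_level + params.detection_margin
        assert truth["below_detection"] == "true"

    def test_true_signals_sum_to_rendered_total(self):
        img, truth = make_cell_image(CellImageParams(tyr_glu_partition=0.3), seed=4)
        total = img.meta["filament_map"].sum()
        assert truth["true_tyr_signal"] + truth["true_glu_signal"] == pytest.approx(total)

    def test_channels_nonnegative_and_registered(self):
        img, _ = make_cell_image(CellImageParams(), seed=5)
        shapes = {c.shape for c in img.channels.values()}
        assert shapes == {img.shape}
        for c in img.channels.values():
            assert (c >= 0).all()


class TestZStack:
    def test_single_plane_selects_zero(self):
        stack, truth = make_zstack(1, 0, CellImageParams(), seed=0)
        assert len(stack) == 1

    def test_declared_plane_has_max_extent(self):
        _, truth = make_zstack(7, 3, CellImageParams(noise=NOISE_OFF), seed=1)
        extents = [truth[f"extent_z{k}"] for k in range(7)]
        assert int(np.argmax(extents)) == 3
        assert extents[3] > max(e for k, e in enumerate(extents) if k != 3)

    def test_out_of_range(self):
        with pytest.raises(ParameterError):
            make_zstack(5, 7, CellImageParams(), seed=0)


class TestGrowthCones:
    def test_deterministic(self):
        a, ta = make_growthcone_image(GrowthConeParams(), seed=8)
        b, tb = make_growthcone_image(GrowthConeParams(), seed=8)
        assert np.array_equal(a.tyr, b.tyr)
        assert ta.values == tb.values

    def test_zero_invasion_no_tyr_in_band(self):
        img, truth = make_growthcone_image(
            GrowthConeParams(true_invasion_fraction=0.0), seed=1
        )
        assert not (img.meta["tyr_mask"] & img.meta["ROI"]).any()
        assert truth["rendered_invasion_fraction"] == 0.0

    def test_full_invasion_covers_band(self):
        img, truth = make_growthcone_image(
            GrowthConeParams(true_invasion_fraction=1.0), seed=1
        )
        assert (img.meta["tyr_mask"] & img.meta["ROI"]).sum() == img.meta["ROI"].sum()
        assert truth["rendered_invasion_fraction"] == 1.0

    def test_glu_confined_to_central_disc(self):
        img, _ = make_growthcone_image(GrowthConeParams(true_invasion_fraction=0.3), seed=2)
        assert not (img.meta["glu_mask"] & img.meta["ROI"]).any()

    def test_rendered_fraction_tracks_request(self):
        for f in (0.1, 0.25, 0.4):
            _, truth = make_growthcone_image(
                GrowthConeParams(true_invasion_fraction=f), seed=3
            )
            assert truth["rendered_invasion_fraction"] == pytest.approx(f, abs=0.01)


class TestLanes:
    def test_noise_free_band_integrals(self):
        lanes, truth = make_lane_profiles(
            LaneParams(fractions={"tubulin": 0.5}, noise_sigma=0.0), seed=0
        )
        # symmetric split: P and S profiles identical
        assert np.allclose(lanes[0].profile, lanes[1].profile)

    def test_conservation(self):
        params = LaneParams(fractions={"x": 0.35}, noise_sigma=0.0)
        lanes, truth = make_lane_profiles(params, seed=0)
        background = params.background_offset + params.background_slope * np.arange(
            params.profile_length
        )
        total = sum((lane.profile - background).sum() for lane in lanes)
        assert total == pytest.approx(params.total_amount, rel=1e-9)

    def test_deterministic(self):
        a, _ = make_lane_profiles(LaneParams(), seed=5)
        b, _ = make_lane_profiles(LaneParams(), seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.profile, y.profile)


class TestPlates:
    def test_null_shape_equal_effects(self):
        from mtquant.synth.plates import effect_profile

        effects = effect_profile(PlateParams(shape="null"))
        assert set(effects.values()) == {1.0}

    def test_no_variation_sources(self):
        table, _ = make_plate_table(
            PlateParams(shape="null", cell_count_cv=0.0, noise_sigma=0.0), seed=0
        )
        norm = table["signal_afu"] / table["hoechst_afu"]
        assert norm.nunique() == 1

    def test_bimodal_truth_set(self):
        _, truth = make_plate_table(PlateParams(shape="bimodal"), seed=0)
        assert truth["affected_set"] == "1.000e-15;1.000e-09"

    def test_deterministic(self):
        a, _ = make_plate_table(PlateParams(), seed=9)
        b, _ = make_plate_table(PlateParams(), seed=9)
        assert a.equals(b)


class TestGroundTruthRoundTrip:
    def test_csv_roundtrip(self, tmp_path):
        truth = GroundTruth(
            fixture_id="fx1", seed=77,
            values={"a": 1.5, "b": 0.25, "label": "bimodal"},
        )
        path = tmp_path / "gt.csv"
        truth.write_csv(path)
        loaded = GroundTruth.read_csv(path)
        assert len(loaded) == 1
        assert loaded[0].fixture_id == "fx1"
        assert loaded[0].seed == 77
        assert loaded[0].values == truth.values

    def test_generator_truths_roundtrip(self, tmp_path, cell_fixture):
        _, truth = cell_fixture
        path = tmp_path / "gt.csv"
        truth.write_csv(path)
        assert GroundTruth.read_csv(path)[0].values == truth.values
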