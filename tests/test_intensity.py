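import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtquant.errors import (
    DegenerateHistogramError,
    EmptyROIError,
    EmptyTableError,
    PairingError,
    ParameterError,
)
from mtquant.intensity import (
    AIDMeasurement,
    aid_measure,
    icw_normalize,
    integrated_density,
    mt_network_area,
    positive_cutoff,
    select_focal_plane,
    tyr_glu_ratio,
)
from mtquant.synth import CellImageParams, make_cell_image, make_zstack
from mtquant.types import ImageStack, MultiChannelImage, ROIMask


def loop_sum(image, mask):
    """Independent per-pixel oracle for integrated density."""
    total = 0.0
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                total += image[i, j]
    return total


class TestIntegratedDensity:
    def test_uniform(self):
        img = np.full((8, 8), 5.0)
        mask = np.zeros((8, 8), bool)
        mask.flat[:10] = True
        assert integrated_density(img, mask) == 50.0

    def test_full_frame_equals_total(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        assert integrated_density(img, np.ones((16, 16), bool)) == pytest.approx(
            img.sum(), rel=1e-12
        )

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            img = rng.uniform(0, 255, (32, 32))
            mask = rng.random((32, 32)) < 0.4
            if not mask.any():
                continue
            assert integrated_density(img, mask) == pytest.approx(
                loop_sum(img, mask), rel=1e-12
            )

    def test_empty_roi(self):
        with pytest.raises(EmptyROIError):
            integrated_density(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            integrated_density(np.ones((4, 4)), np.ones((5, 5), bool))


def brute_force_otsu(values):
    """Exhaustive between-class-variance maximization over integer thresholds."""
    values = np.asarray(values)
    best_t, best_var = None, -1.0
    for t in range(int(values.min()), int(values.max())):
        lo = values[values <= t]
        hi = values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestPositiveCutoff:
    def test_two_valued_separable(self):
        img = np.full((10, 10), 10.0)
        img[5:, :] = 200.0
        cut = positive_cutoff(img, np.ones((10, 10), bool))
        assert 10.0 < cut < 200.0

    def test_control_background_floor(self):
        img = np.clip(np.random.default_rng(0).normal(100, 30, (20, 20)), 0, 240)
        cut = positive_cutoff(img, np.ones((20, 20), bool), control_background=250.0)
        assert cut >= 250.0
        m = aid_measure(img, np.ones((20, 20), bool), cut)
        assert m.positive_area_px == 0

    def test_otsu_matches_brute_force(self):
        # bimodal integer-valued mixture
        local = np.random.default_rng(7)
        vals = np.concatenate(
            [local.normal(40, 6, 600), local.normal(180, 12, 400)]
        ).round()
        vals = np.clip(vals, 0, 255)
        img = vals.reshape(25, 40)
        cut = positive_cutoff(img, np.ones(img.shape, bool), method="otsu")
        oracle = brute_force_otsu(vals)
        # the sweep is over integer thresholds, the library over 256 float
        # bins: they must land within one intensity unit of each other
        assert abs(cut - oracle) <= 1.0

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError) as exc:
            positive_cutoff(np.full((8, 8), 7.0), np.ones((8, 8), bool))
        assert exc.value.constant_value == 7.0

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            positive_cutoff(np.eye(8), np.ones((8, 8), bool), method="nope")

    def test_background_k_mad_above_mode(self, rng):
        img = rng.normal(50, 3, (32, 32)).clip(0)
        cut = positive_cutoff(img, np.ones((32, 32), bool), method="background_k_mad")
        assert cut > 50.0


class TestAIDMeasure:
    def test_all_below_cutoff(self):
        img = np.full((8, 8), 3.0)
        m = aid_measure(img, np.ones((8, 8), bool), cutoff=5.0)
        assert m.aid == 0.0 and m.below_detection

    def test_zero_cutoff_identity(self, rng):
        img = rng.uniform(1, 10, (12, 12))
        mask = np.ones((12, 12), bool)
        m = aid_measure(img, mask, cutoff=0.0)
        assert m.aid == pytest.approx(integrated_density(img, mask), rel=1e-12)

    def test_area_times_mean_gray_identity(self, rng):
        for _ in range(20):
            img = rng.uniform(0, 255, (16, 16))
            m = aid_measure(img, np.ones((16, 16), bool), cutoff=100.0)
            assert m.aid == pytest.approx(m.positive_area_px * m.mean_gray, rel=1e-12)

    def test_recovers_generator_signal(self, cell_fixture):
        img, truth = cell_fixture
        roi = ROIMask(np.ones(img.shape, bool), "cell")
        for ch, key in (("tyr", "true_tyr_signal"), ("glu", "true_glu_signal")):
            cut = positive_cutoff(
                img[ch], roi, method="background_k_mad",
                control_background=truth["background_level"] + truth["detection_margin"],
            )
            m = aid_measure(img[ch], roi, cut, channel=ch)
            assert m.aid == pytest.approx(truth[key], rel=0.10)


@given(
    values=st.lists(st.floats(0, 1000, allow_nan=False), min_size=4, max_size=64),
    cutoff=st.floats(0, 1000, allow_nan=False),
)
@settings(max_examples=60, deadline=None)
def test_aid_identity_property(values, cutoff):
    n = len(values)
    side = int(np.ceil(np.sqrt(n)))
    img = np.zeros((side, side))
    img.flat[:n] = values
    mask = np.zeros((side, side), bool)
    mask.flat[:n] = True
    m = aid_measure(img, mask, cutoff)
    assert m.aid >= 0
    assert m.aid == pytest.approx(m.positive_area_px * m.mean_gray, rel=1e-9, abs=1e-9)


class TestTyrGluRatio:
    def _measure(self, aid, below=False, roi="r"):
        return AIDMeasurement(
            channel="x", cutoff=1.0, positive_area_px=10, positive_area_um2=10.0,
            aid=aid, mean_gray=aid / 10, below_detection=below, roi_label=roi,
        )

    def test_equal_aids(self):
        r = tyr_glu_ratio(self._measure(50.0), self._measure(50.0))
        assert r.defined and r.ratio == 1.0

    def test_below_detection_undefined(self):
        r = tyr_glu_ratio(self._measure(50.0, below=True), self._measure(50.0, below=True))
        assert not r.defined and r.ratio is None

    def test_zero_glu_undefined(self):
        r = tyr_glu_ratio(self._measure(50.0), self._measure(0.0))
        assert not r.defined and r.ratio is None

    def test_roi_mismatch(self):
        with pytest.raises(PairingError):
            tyr_glu_ratio(self._measure(1.0, roi="a"), self._measure(1.0, roi="b"))

    def test_recovers_partition_ratio(self, cell_fixture):
        img, truth = cell_fixture
        roi = ROIMask(np.ones(img.shape, bool), "cell")
        ms = {}
        for ch in ("tyr", "glu"):
            cut = positive_cutoff(img[ch], roi, method="otsu")
            ms[ch] = aid_measure(img[ch], roi, cut, channel=ch)
        r = tyr_glu_ratio(ms["tyr"], ms["glu"])
        assert r.defined
        assert r.ratio == pytest.approx(3.0 / 7.0, rel=0.10)


class TestFocalPlane:
    def test_single_plane(self):
        img = MultiChannelImage({"tyr": np.random.default_rng(0).uniform(0, 9, (64, 64))})
        assert select_focal_plane(ImageStack([img]), "tyr") == 0

    def test_declared_plane_noise_free(self):
        from mtquant.synth import NOISE_OFF

        stack, truth = make_zstack(
            7, 3, CellImageParams(noise=NOISE_OFF), seed=5
        )
        assert select_focal_plane(stack, "tyr") == 3

    def test_out_of_range_plane(self):
        with pytest.raises(ParameterError):
            make_zstack(3, 5, CellImageParams(), seed=0)


class TestNetworkArea:
    def test_solid_disc_geometry(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 15**2
        img = np.where(disc, 100.0, 0.0)
        res = mt_network_area(img, cutoff=50.0, closing_radius_px=0, pixel_size=0.5)
        assert res.area_px == disc.sum()
        assert res.area_um2 == pytest.approx(disc.sum() * 0.25)

    def test_closing_is_extensive(self):
        rng = np.random.default_rng(3)
        img = (rng.random((64, 64)) < 0.1) * 100.0
        base = mt_network_area(img, 50.0, closing_radius_px=0).area_px
        for r in (1, 3, 5, 8):
            assert mt_network_area(img, 50.0, closing_radius_px=r).area_px >= base

    def test_no_pixels_above_cutoff(self):
        res = mt_network_area(np.ones((32, 32)), cutoff=10.0)
        assert res.below_detection and res.area_px == 0

    def test_recovers_rendered_network(self):
        from mtquant.intensity import network_mask

        img, truth = make_cell_image(
            CellImageParams(network_extent=0.4, tyr_glu_partition=1.0), seed=2
        )
        cut = positive_cutoff(
            img["tyr"], np.ones(img.shape, bool), method="background_k_mad",
            control_background=truth["background_level"] + truth["detection_margin"],
        )
        res = mt_network_area(img["tyr"], cut, closing_radius_px=5)
        oracle = network_mask(img.meta["footprint"], 5).sum()
        assert res.area_px == pytest.approx(oracle, rel=0.10)


class TestICWNormalize:
    def _table(self, signal, hoechst):
        import pandas as pd

        return pd.DataFrame(
            {
                "well": [f"W{i}" for i in range(len(signal))],
                "condition": ["c"] * len(signal),
                "concentration_M": [0.0] * len(signal),
                "signal_afu": signal,
                "hoechst_afu": hoechst,
            }
        )

    def test_simple_division(self):
        out = icw_normalize(self._table([200.0], [100.0]))
        assert out["normalized_fau"].iloc[0] == 2.0

    def test_scale_invariance(self):
        a = icw_normalize(self._table([200.0], [100.0]))
        b = icw_normalize(self._table([400.0], [200.0]))
        assert a["normalized_fau"].iloc[0] == b["normalized_fau"].iloc[0]

    def test_excludes_bad_wells(self):
        out = icw_normalize(self._table([10.0, 20.0], [0.0, 5.0]))
        assert list(out["well"]) == ["W1"]

    def test_all_excluded(self):
        with pytest.raises(EmptyTableError):
            icw_normalize(self._table([10.0], [0.0]))
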