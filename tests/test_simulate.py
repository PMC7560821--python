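"""Synthetic scene generator: phenology curve, band construction, parcels,
splits, and the planted statistical structure downstream analyses rely on."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import phenolstm as pl
from phenolstm.profiles import BAND_NAMES, PhenologyProfile, SceneConfig
from tests.conftest import summer_signal_profiles


def profile(**kw):
    base = dict(class_name="X", ndvi_base=0.2, ndvi_amplitude=0.6,
                greenup_day=230, senescence_day=330,
                greenup_rate=0.15, senescence_rate=0.15)
    base.update(kw)
    return PhenologyProfile(**base)


class TestPhenologyProfile:
    @pytest.mark.parametrize("bad", [
        dict(ndvi_base=0.5),                      # base out of range
        dict(ndvi_amplitude=0.9),                 # amplitude out of range
        dict(ndvi_base=0.3, ndvi_amplitude=0.8),  # base+amp > 1
        dict(greenup_day=340),                    # greenup after senescence
        dict(greenup_rate=-0.1),                  # non-positive rate
        dict(informative_bands=frozenset({"B99"})),
    ])
    def test_invariants_rejected(self, bad):
        with pytest.raises(ValueError):
            profile(**bad)

    def test_scene_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SceneConfig(profiles=summer_signal_profiles(),
                        class_proportions=np.array([0.5, 0.2, 0.2, 0.2]))
        with pytest.raises(ValueError, match="n_dates"):
            SceneConfig(n_dates=10, date_list=np.arange(5.0))


class TestDoubleLogistic:
    def test_far_before_greenup_is_baseline(self):
        p = profile()
        assert pl.double_logistic_ndvi(10, p) == pytest.approx(0.2, abs=1e-3)

    def test_midseason_with_steep_rates_is_base_plus_amplitude(self):
        p = profile(greenup_day=100, senescence_day=300, greenup_rate=1.0,
                    senescence_rate=1.0)
        assert pl.double_logistic_ndvi(200, p) == pytest.approx(0.8, abs=1e-3)

    def test_matches_direct_scalar_evaluation(self):
        p = profile()
        day = 280
        up = 1.0 / (1.0 + math.exp(-0.15 * (day - 230)))
        down = 1.0 / (1.0 + math.exp(-0.15 * (day - 330)))
        expected = 0.2 + 0.6 * (up - down)
        assert pl.double_logistic_ndvi(day, p) == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= pl.double_logistic_ndvi(day, p) <= 1.0


class TestNdviToReflectance:
    def test_zero_ndvi_splits_band_sum_evenly(self):
        p = profile(band_sum=0.4, band_noise_sd=0.0)
        vec = pl.ndvi_to_reflectance(0.0, p)
        assert vec[BAND_NAMES.index("B4")] == pytest.approx(0.2)
        assert vec[BAND_NAMES.index("B8")] == pytest.approx(0.2)

    def test_b4_b8_solve_the_ndvi_identity(self):
        # (B8-B4)/(B8+B4)=0.6 with B8+B4=0.5 has the unique solution (0.4, 0.1)
        p = profile(band_sum=0.5, band_noise_sd=0.0)
        vec = pl.ndvi_to_reflectance(0.6, p)
        assert vec[BAND_NAMES.index("B8")] == pytest.approx(0.4)
        assert vec[BAND_NAMES.index("B4")] == pytest.approx(0.1)

    def test_output_clipped_to_unit_interval(self):
        p = profile(band_noise_sd=0.5)
        rng = np.random.default_rng(0)
        vec = pl.ndvi_to_reflectance(np.linspace(-1, 1, 50), p, rng)
        assert vec.min() >= 0.0 and vec.max() <= 1.0

    def test_rejects_out_of_range_ndvi(self):
        with pytest.raises(ValueError, match="ndvi"):
            pl.ndvi_to_reflectance(1.5, profile())

    def test_noninformative_bands_carry_no_ndvi_signal(self):
        p = profile(informative_bands=frozenset(), band_noise_sd=0.0)
        lo = pl.ndvi_to_reflectance(0.0, p)
        hi = pl.ndvi_to_reflectance(0.8, p)
        for j, b in enumerate(BAND_NAMES):
            if b in ("B4", "B8"):
                assert lo[j] != hi[j]
            else:
                assert lo[j] == hi[j]


class TestGenerateScene:
    def test_single_class_gives_constant_label_map(self):
        cfg = SceneConfig(grid_height=8, grid_width=8, parcel_size=4,
                          profiles=[profile()], class_proportions=np.array([1.0]),
                          seed=0)
        scene = pl.generate_scene(cfg)
        assert (scene.labels == 0).all()

    def test_deterministic_given_seed(self):
        cfg = dict(grid_height=16, grid_width=16, parcel_size=4,
                   profiles=summer_signal_profiles(),
                   class_proportions=np.full(4, 0.25), seed=42)
        a = pl.generate_scene(SceneConfig(**cfg))
        b = pl.generate_scene(SceneConfig(**cfg))
        assert (a.reflectance == b.reflectance).all()
        assert (a.labels == b.labels).all()
        assert (a.parcel_ids == b.parcel_ids).all()

    def test_equal_proportions_give_exact_class_counts(self):
        cfg = SceneConfig(grid_height=64, grid_width=64, parcel_size=8,
                          profiles=summer_signal_profiles(),
                          class_proportions=np.full(4, 0.25), seed=7)
        scene = pl.generate_scene(cfg)
        counts = np.bincount(scene.labels.ravel(), minlength=4)
        # 64 parcels apportioned 16/16/16/16, 64 pixels each
        assert (counts == 1024).all()

    def test_reflectance_in_unit_interval_and_parcels_share_labels(self, tiny_scene):
        assert tiny_scene.reflectance.min() >= 0.0
        assert tiny_scene.reflectance.max() <= 1.0
        labels, parcels = tiny_scene.labels.ravel(), tiny_scene.parcel_ids.ravel()
        for pid in np.unique(parcels):
            assert len(np.unique(labels[parcels == pid])) == 1

    def test_grid_not_divisible_by_parcel_size_is_an_error(self):
        cfg = SceneConfig(grid_height=10, grid_width=16, parcel_size=4,
                          profiles=[profile()], class_proportions=np.array([1.0]))
        with pytest.raises(ValueError, match="divisible"):
            pl.generate_scene(cfg)

    def test_more_classes_than_parcels_is_an_error(self):
        cfg = SceneConfig(grid_height=4, grid_width=4, parcel_size=4,
                          profiles=summer_signal_profiles(),
                          class_proportions=np.full(4, 0.25))
        with pytest.raises(ValueError, match="parcels"):
            pl.generate_scene(cfg)

    def test_ndvi_recoverable_exactly_without_noise(self):
        profs = summer_signal_profiles(noise_sd=0.0)
        cfg = SceneConfig(grid_height=8, grid_width=8, parcel_size=4,
                          profiles=profs[:2], class_proportions=np.full(2, 0.5),
                          seed=3)
        scene = pl.generate_scene(cfg)
        b8 = scene.reflectance[..., BAND_NAMES.index("B8")]
        b4 = scene.reflectance[..., BAND_NAMES.index("B4")]
        ndvi = pl.compute_ndvi(b8, b4)
        for k, p in enumerate(profs[:2]):
            expected = pl.double_logistic_ndvi(scene.date_list, p)
            got = ndvi[scene.labels == k]  # (n_px, T)
            assert np.abs(got - expected).max() < 1e-9

    def test_class_signal_confined_to_planted_window(self):
        # profiles differ only in amplitude of a summer cycle: outside the
        # window the between-class mean NDVI difference vanishes within noise
        profs = summer_signal_profiles(noise_sd=0.0)
        days = np.array([50.0, 150.0])  # winter dates, far from the window
        curves = [pl.double_logistic_ndvi(days, p) for p in profs]
        spread = np.ptp(np.array(curves), axis=0)
        assert spread.max() < 1e-3

    def test_noninformative_band_distribution_identical_across_classes(self):
        cfg = SceneConfig(grid_height=32, grid_width=32, parcel_size=8,
                          profiles=summer_signal_profiles(0.03)[:2],
                          class_proportions=np.full(2, 0.5), seed=9)
        scene = pl.generate_scene(cfg)
        b1 = scene.reflectance[..., BAND_NAMES.index("B1")]
        a = b1[scene.labels == 0].ravel()
        b = b1[scene.labels == 1].ravel()
        _, pvalue = stats.mannwhitneyu(a, b)
        assert pvalue > 0.01  # fails to reject identical distributions


class TestSplitTrainTest:
    def test_pixel_split_is_stratified_70_30(self, tiny_scene):
        tr, te = pl.split_train_test(tiny_scene, 0.7, "pixel", 1)
        assert len(tr) + len(te) == tiny_scene.n_pixels
        labels = tiny_scene.labels.ravel()
        for k in np.unique(labels):
            n_class = (labels == k).sum()
            n_train = np.isin(tr, np.flatnonzero(labels == k)).sum()
            assert abs(n_train - 0.7 * n_class) <= 1

    def test_split_is_disjoint_and_exhaustive(self, tiny_scene):
        tr, te = pl.split_train_test(tiny_scene, 0.7, "pixel", 2)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == tiny_scene.n_pixels

    def test_parcel_split_keeps_parcels_on_one_side(self, tiny_scene):
        tr, te = pl.split_train_test(tiny_scene, 0.7, "parcel", 4)
        parcels = tiny_scene.parcel_ids.ravel()
        assert len(np.intersect1d(parcels[tr], parcels[te])) == 0
        assert len(tr) + len(te) == tiny_scene.n_pixels

    def test_single_parcel_class_warns(self):
        cfg = SceneConfig(grid_height=8, grid_width=8, parcel_size=4,
                          profiles=summer_signal_profiles()[:4],
                          class_proportions=np.full(4, 0.25), seed=0)
        scene = pl.generate_scene(cfg)  # 4 parcels, one per class
        with pytest.warns(UserWarning, match="single parcel"):
            pl.split_train_test(scene, 0.7, "parcel", 0)

    def test_invalid_fraction_and_mode_rejected(self, tiny_scene):
        with pytest.raises(ValueError):
            pl.split_train_test(tiny_scene, 1.5, "pixel", 0)
        with pytest.raises(ValueError):
            pl.split_train_test(tiny_scene, 0.7, "block", 0)
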