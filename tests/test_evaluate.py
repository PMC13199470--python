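"""Segmentation, per-image features, aggregation, and the correlation protocol."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from pdiff.evaluate import (
    FEATURE_NAMES,
    aggregate,
    correlate,
    features,
    feature_table,
    segment,
    split_half_upper_bound,
    to_grayscale,
)


def disk_image(centers, radius=10, size=64, value=0.8):
    img = np.zeros((size, size, 3))
    for c in centers:
        rr, cc = disk(c, radius, shape=(size, size))
        img[rr, cc, :] = value
    return img


class TestGrayscale:
    def test_zero_image_stays_zero(self):
        assert np.all(to_grayscale(np.zeros((4, 4, 3))) == 0)

    def test_constant_channels_average(self):
        img = np.stack([np.full((4, 4), v) for v in (0.3, 0.6, 0.9)], axis=2)
        np.testing.assert_allclose(to_grayscale(img), 0.6)

    def test_idempotent_on_replicated_image(self):
        g = np.random.default_rng(0).random((4, 4))
        img = np.stack([g, g, g], axis=2)
        np.testing.assert_allclose(to_grayscale(np.stack([to_grayscale(img)] * 3, axis=2)),
                                   to_grayscale(img))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="H, W, 3"):
            to_grayscale(np.zeros((4, 4, 2)))


class TestSegment:
    def test_blank_image_yields_empty_mask(self):
        mask = segment(np.zeros((64, 64, 3)))
        assert mask.max() == 0 and mask.shape == (64, 64)

    def test_noise_only_image_yields_empty_mask(self):
        img = np.clip(np.random.default_rng(0).normal(0.02, 0.01, (64, 64, 3)), 0, 1)
        assert segment(img).max() == 0

    def test_single_disk_area_matches_geometry(self):
        mask = segment(disk_image([(32, 32)], radius=10))
        assert mask.max() == 1
        area = np.count_nonzero(mask)
        assert area == pytest.approx(np.pi * 100, rel=0.2)

    def test_two_separated_disks_give_two_labels(self):
        mask = segment(disk_image([(16, 16), (48, 48)], radius=8))
        assert mask.max() == 2

    def test_custom_segmenter_callable_is_used(self):
        fixed = np.zeros((8, 8), dtype=int)
        fixed[2:4, 2:4] = 1
        mask = segment(np.zeros((8, 8, 3)), method=lambda img: fixed)
        assert np.array_equal(mask, fixed)


class TestFeatures:
    def test_empty_mask_gives_zeros(self):
        f = features(np.zeros((10, 10), dtype=int))
        assert f.as_tuple() == (0.0, 0, 0.0)

    def test_single_cell_arithmetic(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[:5, :5] = 1
        f = features(mask)
        assert f.as_tuple() == (0.25, 1, 25.0)

    def test_matches_brute_force_pixel_counts(self):
        rng = np.random.default_rng(4)
        mask = rng.integers(0, 4, (20, 20))
        f = features(mask)
        cells = [np.count_nonzero(mask == k) for k in range(1, mask.max() + 1)]
        assert f.cell_count == mask.max()
        assert f.coverage == pytest.approx(sum(cells) / 400)
        assert f.mean_cell_size * f.cell_count == pytest.approx(sum(cells))


class TestAggregate:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["compound_id", *FEATURE_NAMES])

    def test_single_image_is_identity(self):
        df = self._df([("a", 0.2, 5, 10.0)])
        agg = aggregate(df)
        assert agg.loc["a"].tolist() == [0.2, 5, 10.0]

    def test_mean_of_two_images(self):
        df = self._df([("a", 0.1, 2, 8.0), ("a", 0.3, 4, 12.0)])
        assert aggregate(df).loc["a", "cell_count"] == 3

    def test_invariant_to_image_order(self):
        rows = [("a", 0.1, 2, 8.0), ("a", 0.3, 4, 12.0), ("b", 0.5, 7, 20.0)]
        assert aggregate(self._df(rows)).equals(aggregate(self._df(rows[::-1])))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no features"):
            aggregate(self._df([]))


class TestCorrelate:
    def _agg(self, values):
        return pd.DataFrame(
            {name: values for name in FEATURE_NAMES},
            index=pd.Index([f"c{i}" for i in range(len(values))], name="compound_id"),
        )

    def test_identical_tables_give_rho_one(self):
        a = self._agg([1.0, 2.0, 3.0, 4.0])
        rho = correlate(a, a.copy())
        assert all(v == pytest.approx(1.0) for v in rho.values())

    def test_reversed_ranks_give_rho_minus_one(self):
        a = self._agg([1.0, 2.0, 3.0, 4.0])
        b = self._agg([4.0, 3.0, 2.0, 1.0])
        assert all(v == pytest.approx(-1.0) for v in correlate(a, b).values())

    def test_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(6)
        x = rng.permutation(9).astype(float)
        y = rng.permutation(9).astype(float)
        rho = correlate(self._agg(x), self._agg(y))["coverage"]
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        d2 = ((rx - ry) ** 2).sum()
        assert rho == pytest.approx(1 - 6 * d2 / (9 * 80))

    def test_constant_vector_warns_and_reports_nan(self):
        a = self._agg([1.0, 2.0, 3.0])
        b = self._agg([5.0, 5.0, 5.0])
        with pytest.warns(UserWarning, match="constant"):
            rho = correlate(a, b)
        assert np.isnan(rho["coverage"])

    def test_mismatched_compounds_rejected(self):
        a = self._agg([1.0, 2.0, 3.0])
        b = self._agg([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="different compounds"):
            correlate(a, b)


def _noisy_feats(noise_sd, seed=0, n_compounds=12, n_images=8):
    rng = np.random.default_rng(seed)
    truth = np.linspace(1, 10, n_compounds)
    rows = []
    for i, t in enumerate(truth):
        for _ in range(n_images):
            v = t + rng.normal(0, noise_sd)
            rows.append({"compound_id": f"c{i:02d}", "coverage": v,
                         "cell_count": v, "mean_cell_size": v})
    return pd.DataFrame(rows)


class TestSplitHalf:
    def test_noise_free_replicates_give_rho_one(self):
        rho = split_half_upper_bound(_noisy_feats(0.0), seed=1)
        assert all(v == pytest.approx(1.0) for v in rho.values())

    def test_fixed_seed_reproducible(self):
        f = _noisy_feats(2.0, seed=3)
        assert split_half_upper_bound(f, seed=7) == split_half_upper_bound(f, seed=7)

    def test_rho_decreases_with_replicate_noise(self):
        rhos = [split_half_upper_bound(_noisy_feats(sd, seed=5), seed=2)["coverage"]
                for sd in (0.5, 4.0, 20.0)]
        assert rhos[0] > rhos[1] > rhos[2]

    def test_single_image_compound_rejected(self):
        f = _noisy_feats(1.0).iloc[:1]
        with pytest.raises(ValueError, match="fewer than 2"):
            split_half_upper_bound(f, seed=0)


class TestOnSimulator:
    def test_feature_table_covers_all_images(self, toy_images):
        tab = feature_table(toy_images)
        assert len(tab) == sum(len(v) for v in toy_images.values())
        assert set(tab["compound_id"]) == set(toy_images)

    def test_phenotype_ordering_recovered(self, toy_images):
        agg = aggregate(feature_table(toy_images))
        assert agg.loc["dense", "cell_count"] > agg.loc["sparse", "cell_count"]
        assert agg.loc["toxic", "coverage"] < agg.loc["sparse", "coverage"]
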