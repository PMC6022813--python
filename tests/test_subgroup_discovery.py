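"""Subset enumeration, test accounting, cell scoring and discovery."""

import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

import aidlog as al
from aidlog.subgroup_discovery import (
    AUDIOGRAM_MODALITY,
    GAIN_REDUCTION_MODALITY,
    INPUT_SPL_MODALITY,
    STYLE_MODALITY,
    Modality,
)
from conftest import make_dataset


class TestEnumeration:
    @pytest.mark.parametrize(
        "modality,expected",
        [
            (INPUT_SPL_MODALITY, 4095),
            (AUDIOGRAM_MODALITY, 255),
            (Modality("one", ("a",)), 1),
            (STYLE_MODALITY, 1),
        ],
    )
    def test_subset_counts(self, modality, expected):
        subsets = al.enumerate_dimension_subsets(modality)
        assert len(subsets) == expected
        assert len(set(subsets)) == expected
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes)  # ordered by size first

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (INPUT_SPL_MODALITY, STYLE_MODALITY, 122_850),
            (AUDIOGRAM_MODALITY, INPUT_SPL_MODALITY, 26_105_625),
            (GAIN_REDUCTION_MODALITY, INPUT_SPL_MODALITY, 307_125),
        ],
    )
    def test_total_test_counts(self, a, b, expected):
        assert al.total_test_count(a, b) == expected


class TestClusterSubset:
    def test_categorical_style(self):
        styles = [al.STYLES[i % 6] for i in range(60)]
        ds = make_dataset(60, style=styles)
        labels, centers = al.cluster_subset(ds, STYLE_MODALITY, ("style",))
        assert len(centers) == 6
        assert [centers[l] for l in labels[:6]] == styles[:6]

    def test_planted_mixture_recovery(self):
        rng = np.random.default_rng(0)
        n = 1000
        comps = rng.integers(0, 5, n)
        vals = comps * 0.2 + rng.normal(0, 0.01, n)
        ds = make_dataset(n, gain_reduction_noise=np.clip(vals, 0, None))
        labels, _ = al.cluster_subset(
            ds, GAIN_REDUCTION_MODALITY, ("gain_reduction_noise",), k=5, seed=1, n_starts=5
        )
        assert adjusted_rand_score(comps, labels) >= 0.9

    def test_constant_column_degenerate(self):
        ds = make_dataset(50)
        with pytest.raises(al.DegenerateDataError):
            al.cluster_subset(ds, GAIN_REDUCTION_MODALITY, ("gain_reduction_noise",))


class TestScoreCell:
    def test_independence_gives_unit_effect(self):
        effect, p = al.score_cell(10, 100, 100, 1000)
        assert effect == pytest.approx(1.0)
        assert 0 < p < 1

    def test_double_expected(self):
        effect, p = al.score_cell(20, 100, 100, 1000)
        assert effect == pytest.approx(2.0)
        # exact enumeration oracle for the binomial tail P(X >= 20)
        p0 = 0.01
        oracle = sum(binom.pmf(k, 1000, p0) for k in range(20, 1001))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_zero_observed(self):
        effect, p = al.score_cell(0, 100, 100, 1000)
        assert effect == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            al.score_cell(0, 0, 100, 1000)


def two_categorical_dataset(labels_a, labels_b):
    """Dataset with style carrying A-labels and a fake categorical via gains."""
    n = len(labels_a)
    return make_dataset(
        n,
        style=[al.STYLES[i] for i in labels_a],
        gain_reduction_noise=np.asarray(labels_b, dtype=float),
    )


class TestDiscovery:
    def test_independent_uniform_labels_effects_near_one(self):
        rng = np.random.default_rng(1)
        n = 6000
        la = rng.integers(0, 6, n)
        lb = rng.integers(0, 3, n).astype(float)
        ds = two_categorical_dataset(la, lb)
        modB = Modality("fake", ("gain_reduction_noise",), "categorical", 3)
        res = al.discover_subgroups(ds, STYLE_MODALITY, modB, seed=0)
        # no subgroup should survive Bonferroni under independence
        assert res.subgroups == []
        assert res.tests_performed == res.total_tests == 18

    def test_cell_counts_partition_n(self):
        rng = np.random.default_rng(2)
        n = 500
        ds = make_dataset(
            n,
            style=[al.STYLES[i] for i in rng.integers(0, 6, n)],
            gain_reduction_noise=rng.uniform(0, 4, n),
            gain_reduction_quiet=rng.uniform(0, 4, n),
        )
        labels, centers = al.cluster_subset(
            ds, GAIN_REDUCTION_MODALITY, GAIN_REDUCTION_MODALITY.dims, k=5, seed=0
        )
        assert np.bincount(labels, minlength=5).sum() == n

    def test_planted_association_recovered_small(self):
        # one style over-represented in one categorical partner cluster
        rng = np.random.default_rng(3)
        n = 8000
        lb = rng.integers(0, 3, n)
        la = np.where(
            (lb == 0) & (rng.random(n) < 0.45), 0, rng.integers(1, 6, n)
        )
        ds = two_categorical_dataset(la, lb.astype(float))
        modB = Modality("fake", ("gain_reduction_noise",), "categorical", 3)
        res = al.discover_subgroups(ds, STYLE_MODALITY, modB, seed=1)
        assert res.best is not None
        assert res.best.center_a == "CIC"  # style index 0
        # observed lift matches the construction's contingency directly
        obs_lift = res.best.observed * n / (
            (la == 0).sum() * (lb == res.best.cluster_b).sum()
        )
        assert res.best.effect == pytest.approx(obs_lift)

    def test_min_effect_monotone(self):
        rng = np.random.default_rng(4)
        n = 4000
        lb = rng.integers(0, 3, n)
        la = np.where((lb == 0) & (rng.random(n) < 0.3), 0, rng.integers(1, 6, n))
        ds = two_categorical_dataset(la, lb.astype(float))
        modB = Modality("fake", ("gain_reduction_noise",), "categorical", 3)
        low = al.discover_subgroups(ds, STYLE_MODALITY, modB, min_effect=1.05, seed=1)
        high = al.discover_subgroups(ds, STYLE_MODALITY, modB, min_effect=1.3, seed=1)
        assert len(high.subgroups) <= len(low.subgroups)
        kept = {(s.cluster_a, s.cluster_b) for s in high.subgroups}
        assert kept <= {(s.cluster_a, s.cluster_b) for s in low.subgroups}

    def test_share_flags(self):
        rng = np.random.default_rng(5)
        n = 8000
        lb = rng.integers(0, 2, n)
        la = np.where((lb == 0) & (rng.random(n) < 0.6), 0, rng.integers(1, 3, n))
        ds = two_categorical_dataset(la, lb.astype(float))
        modB = Modality("fake", ("gain_reduction_noise",), "categorical", 2)
        res = al.discover_subgroups(ds, STYLE_MODALITY, modB, seed=2)
        for s in res.subgroups:
            assert s.flags.startswith("*" if s.share < 0.1 else "#")
            assert ("+" in s.flags) == (s.effect > 1.1)
            assert s.expected == pytest.approx(s.observed / s.effect)

    def test_oversize_pair_requires_sampling(self):
        ds = make_dataset(30)
        with pytest.raises(ValueError):
            al.discover_subgroups(ds, AUDIOGRAM_MODALITY, INPUT_SPL_MODALITY, max_cells=1000)
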