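"""Loan-device detection: rule boundaries, brute-force oracle, Fisher tests."""

import numpy as np
import pytest
from scipy.stats import hypergeom

import aidlog as al
from aidlog.datalog_model import AUDIOGRAM_COLUMNS
from conftest import make_dataset


class TestImprovement:
    def test_identical_is_zero(self):
        a = al.Audiogram((10, 20, 30, 40, 50, 60, 70, 80))
        assert al.audiogram_improvement(a, a).tolist() == [0] * 8

    def test_flat_drop(self):
        prev = al.Audiogram(tuple([60.0] * 8))
        curr = al.Audiogram(tuple([40.0] * 8))
        assert al.audiogram_improvement(prev, curr).tolist() == [20] * 8

    def test_matches_subtraction_oracle(self):
        rng = np.random.default_rng(0)
        p, c = rng.integers(0, 90, 8).astype(float), rng.integers(0, 90, 8).astype(float)
        assert np.array_equal(al.audiogram_improvement(p, c), p - c)

    def test_missing_rejected(self):
        a = al.Audiogram((10, 20, 30, 40, 50, 60, 70, np.nan))
        with pytest.raises(ValueError):
            al.audiogram_improvement(a, a)


def pair_dataset(prev, curr, days):
    """Two-visit single-device dataset with the given audiograms."""
    return make_dataset(
        2,
        device_ids=["D1", "D1"],
        session_seq=[1, 2],
        days=[100, days],
        audiogram=np.array([prev, curr], dtype=float),
    )


class TestFlagRule:
    def test_three_frequencies_at_threshold_flagged(self):
        prev = [60] * 8
        curr = [45, 45, 45] + [60] * 5  # exactly +15 at exactly 3 freqs
        res = al.flag_loan_devices(pair_dataset(prev, curr, days=30))
        assert res.devices["flagged"].all()

    def test_two_frequencies_not_flagged(self):
        curr = [45, 45] + [60] * 6
        res = al.flag_loan_devices(pair_dataset([60] * 8, curr, days=30))
        assert not res.devices["flagged"].any()

    def test_day_window_strict(self):
        curr = [40] * 8
        for days, expect in [(7, False), (8, True), (59, True), (60, False)]:
            res = al.flag_loan_devices(pair_dataset([60] * 8, curr, days=days))
            assert bool(res.devices["flagged"].iloc[0]) is expect, days

    def test_monotone_in_thresholds(self, sim_multi_visit):
        dataset, _ = sim_multi_visit
        complete, _ = al.require_complete_audiogram(dataset)
        base = al.flag_loan_devices(complete)
        stricter_db = al.flag_loan_devices(complete, improve_dB=20)
        stricter_nf = al.flag_loan_devices(complete, min_freqs=5)
        assert stricter_db.devices["flagged"].sum() <= base.devices["flagged"].sum()
        assert stricter_nf.devices["flagged"].sum() <= base.devices["flagged"].sum()

    def test_percentages_recompute(self, sim_multi_visit):
        dataset, _ = sim_multi_visit
        complete, _ = al.require_complete_audiogram(dataset)
        t = al.flag_loan_devices(complete).by_style
        assert np.allclose(t["percentage"], 100 * t["flagged"] / t["total"])


def brute_force_flags(dataset):
    """Independent oracle: direct loop over all consecutive pairs per device."""
    f = dataset.frame.sort_values(["device_id", "session_seq"])
    aud = f[list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
    flagged = {}
    ids = f["device_id"].to_numpy()
    days = f["days_since_last_visit"].to_numpy(dtype=float)
    for dev in np.unique(ids):
        idx = np.flatnonzero(ids == dev)
        hit = False
        for a, b in zip(idx[:-1], idx[1:]):
            if ((aud[a] - aud[b]) >= 15).sum() >= 3 and 7 < days[b] < 60:
                hit = True
        flagged[dev] = hit
    return flagged


def test_brute_force_oracle_agreement(sim_multi_visit):
    dataset, _ = sim_multi_visit
    complete, _ = al.require_complete_audiogram(dataset)
    res = al.flag_loan_devices(complete)
    oracle = brute_force_flags(complete)
    got = dict(zip(res.devices["device_id"], res.devices["flagged"]))
    assert got == oracle


def test_planted_rates_recovered(sim_multi_visit):
    dataset, truth = sim_multi_visit
    complete, _ = al.require_complete_audiogram(dataset)
    res = al.flag_loan_devices(complete)
    merged = res.devices.merge(truth.devices[["device_id", "loan"]], on="device_id")
    bte = merged[merged["style"].isin(["BTEa", "BTEb"])]
    p = bte["loan"].mean()
    sd = np.sqrt(p * (1 - p) / len(bte))
    assert abs(bte["flagged"].mean() - p) < 3 * sd + 1e-9
    custom = merged[~merged["style"].isin(["BTEa", "BTEb"])]
    assert custom["flagged"].mean() < 0.01


class TestStyleComparison:
    def test_identical_margins_p_one(self):
        res = al.flag_loan_devices(
            make_dataset(
                4,
                device_ids=["A", "A", "B", "B"],
                session_seq=[1, 2, 3, 4],
                style=["BTEa", "BTEa", "BTEb", "BTEb"],
                days=[100, 30, 100, 30],
                audiogram=np.array([[60] * 8, [40] * 8, [60] * 8, [40] * 8], dtype=float),
            )
        )
        p = al.compare_style_rates(res)
        assert p.loc["BTEa", "BTEb"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_sum(self):
        # 2x2 table [[10, 990], [80, 920]]: two-sided Fisher p equals the sum
        # of hypergeometric point masses not exceeding the observed one.
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[10, 990], [80, 920]], alternative="two-sided")
        M, nA, K = 2000, 1000, 90
        rv = hypergeom(M, K, nA)
        support = np.arange(max(0, K - (M - nA)), min(K, nA) + 1)
        pmf = rv.pmf(support)
        oracle = pmf[pmf <= rv.pmf(10) * (1 + 1e-7)].sum()
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_type_I_error_rate(self):
        # equal-rate styles: Fisher rejections at alpha=0.05 occur at <= alpha
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(4)
        n, p0, reps = 400, 0.05, 500
        rejections = 0
        for _ in range(reps):
            a, b = rng.binomial(n, p0), rng.binomial(n, p0)
            _, p = fisher_exact([[a, n - a], [b, n - b]])
            rejections += p < 0.05
        rate = rejections / reps
        # Fisher is conservative for discrete margins: rate should not exceed
        # alpha by more than binomial noise
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_total_style_excluded(self):
        res = al.flag_loan_devices(
            make_dataset(
                2,
                device_ids=["A", "A"],
                session_seq=[1, 2],
                style="BTEa",
                days=[100, 30],
                audiogram=np.array([[60] * 8, [40] * 8], dtype=float),
            )
        )
        with pytest.raises(ValueError):
            al.compare_style_rates(res)
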