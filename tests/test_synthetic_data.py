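"""Generator: determinism, planted structure, and elementary draws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aidlog as al
from aidlog.datalog_model import AUDIOGRAM_COLUMNS, SPL_COLUMNS
from aidlog.synthetic_data import ArchetypeSpec, round_2sf, _style_profile_matrix


class TestRound2sf:
    @given(st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_two_significant_figures(self, x):
        r = float(round_2sf(x))
        mag = np.floor(np.log10(abs(r))) if r != 0 else 0
        step = 10.0 ** (mag - 1)
        assert abs(r / step - round(r / step)) < 1e-6  # on the 2-s.f. grid
        assert abs(r - x) <= 0.5 * 10.0 ** (np.floor(np.log10(x)) - 1) * (1 + 1e-9)

    def test_half_even(self):
        assert float(round_2sf(0.125)) == pytest.approx(0.12)
        assert float(round_2sf(0.135)) == pytest.approx(0.14)
        assert float(round_2sf(0.0)) == 0.0


class TestElementaryDraws:
    def test_zero_covariance_returns_rounded_mean(self):
        arch = ArchetypeSpec("x", (20, 25, 35, 45, 50, 55, 60, 65), 0.0, 1.0)
        a = al.simulate_audiogram(arch, np.random.default_rng(0))
        assert a.values.tolist() == list(arch.mean)

    def test_audiogram_on_5dB_grid_and_clipped(self):
        arch = ArchetypeSpec("x", (0, 0, 0, 0, 0, 0, 0, 0), 30.0, 1.0)
        rng = np.random.default_rng(1)
        vals = np.array([al.simulate_audiogram(arch, rng).values for _ in range(200)])
        assert np.all(vals % 5 == 0)
        assert vals.min() >= -10 and vals.max() <= 120

    def test_notch_archetype_cohort_mean_peaks_at_4k(self):
        arch = ArchetypeSpec("nihl", (5, 10, 15, 25, 45, 50, 35, 15), 5.0, 1.0)
        rng = np.random.default_rng(2)
        m = np.array([al.simulate_audiogram(arch, rng).values for _ in range(500)]).mean(axis=0)
        i4k = AUDIOGRAM_COLUMNS.index("ac4000")
        assert m[i4k] == max(m)  # local (here global) maximum of loss at 4 kHz

    def test_degenerate_concentration_concentrates(self):
        prof = np.full(12, 1e-6)
        prof[3] = 1.0
        h = al.simulate_spl_histogram(prof * 1e6, np.random.default_rng(0), concentration=1.0)
        assert h.values[3] > 0.999

    def test_symmetric_concentration_equal_means(self):
        rng = np.random.default_rng(3)
        draws = np.array(
            [al.simulate_spl_histogram(np.ones(12) / 12, rng).values for _ in range(2000)]
        )
        m = draws.mean(axis=0)
        assert np.allclose(m, 1 / 12, atol=3 * draws.std(axis=0).max() / np.sqrt(2000))

    def test_quantized_sums_within_slack(self, sim_small):
        dataset, truth = sim_small
        sums = dataset.frame[list(SPL_COLUMNS)].sum(axis=1).to_numpy()
        rep = truth.snapshots["representative"].to_numpy()
        assert (sums[rep] >= 0.94).all() and (sums[rep] <= 1.06).all()


class TestDatasetSimulation:
    def test_empty(self):
        ds, gt = al.simulate_dataset(al.default_config(n_devices=0))
        assert len(ds) == 0 and len(gt.snapshots) == 0

    def test_determinism(self):
        cfg = al.default_config(n_devices=150, seed=77)
        d1, t1 = al.simulate_dataset(cfg)
        d2, t2 = al.simulate_dataset(cfg)
        assert d1.equals(d2)
        assert t1.devices.equals(t2.devices) and t1.snapshots.equals(t2.snapshots)

    def test_infeasible_configs_rejected(self):
        probs = {"CIC": 0.4, "HalfShell": 0.2, "ITE": 0.2, "ITC": 0.2, "BTEa": 0.0, "BTEb": 0.0}
        with pytest.raises(al.ConfigError):
            al.default_config(n_devices=10, style_probs=probs).validate()
        with pytest.raises(al.ConfigError):
            al.default_config(n_devices=10, loan_rate=1.5).validate()

    def test_loan_count_binomial(self):
        cfg = al.default_config(n_devices=1500, visits_min=2, visits_max=4, seed=9)
        ds, gt = al.simulate_dataset(cfg)
        bte = gt.devices[gt.devices["style"].isin(["BTEa", "BTEb"])]
        n, p = len(bte), cfg.loan_rate
        assert abs(bte["loan"].sum() - n * p) < 3 * np.sqrt(n * p * (1 - p))
        custom = gt.devices[~gt.devices["style"].isin(["BTEa", "BTEb"])]
        assert custom["loan"].sum() == 0

    def test_loan_devices_satisfy_detection_rule(self, sim_multi_visit):
        dataset, truth = sim_multi_visit
        f = dataset.frame.set_index(["device_id", "session_seq"])
        loans = truth.devices[truth.devices["loan"]]
        assert len(loans) > 10
        for _, d in loans.iterrows():
            sw = int(d["switch_session_seq"])
            dev_rows = dataset.frame[dataset.frame["device_id"] == d["device_id"]].sort_values("session_seq")
            seqs = dev_rows["session_seq"].to_list()
            i = seqs.index(sw)
            prev = dev_rows.iloc[i - 1][list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
            curr = dev_rows.iloc[i][list(AUDIOGRAM_COLUMNS)].to_numpy(dtype=float)
            days = int(dev_rows.iloc[i]["days_since_last_visit"])
            assert ((prev - curr) >= 15).sum() >= 3
            assert 7 < days < 60

    def test_planted_outliers_violate_link_by_5_sd(self, sim_small):
        dataset, truth = sim_small
        slope, intercept, noise_sd = al.default_config().directionality_link
        out = truth.snapshots["outlier"].to_numpy()
        assert out.sum() > 0
        f = dataset.frame.loc[out]
        from aidlog.directionality_anomaly import SPL_BIN_REPRESENTATIVES

        p = f[list(SPL_COLUMNS)].to_numpy(dtype=float)
        y = (p @ SPL_BIN_REPRESENTATIVES) / p.sum(axis=1)
        x = f["fraction_directional"].to_numpy(dtype=float)
        implied_y = 65.0 + (x - intercept) / slope
        sd_y = noise_sd / slope
        # stored histograms are quantized, so allow a small tolerance on 5 sd
        assert (np.abs(y - implied_y) >= 5 * sd_y - 1.0).all()

    def test_directionality_link_ols_recovery(self):
        cfg = al.default_config(n_devices=3000, visits_min=1, visits_max=2, seed=31)
        ds, gt = al.simulate_dataset(cfg)
        slope, intercept, noise_sd = cfg.directionality_link
        f = ds.frame
        bte = f["style"].isin(["BTEa", "BTEb"]).to_numpy()
        ok = bte & ~gt.snapshots["outlier"].to_numpy()
        x = f.loc[ok, "fraction_directional"].to_numpy(dtype=float)
        y = f.loc[ok, "mean_input_spl"].to_numpy(dtype=float) - 65.0
        A = np.column_stack([y, np.ones_like(y)])
        coef, res_, *_ = np.linalg.lstsq(A, x, rcond=None)
        resid = x - A @ coef
        cov = np.linalg.inv(A.T @ A) * resid.var(ddof=2)
        se = np.sqrt(np.diag(cov))
        assert abs(coef[0] - slope) < 2 * se[0] + 1e-4
        assert abs(coef[1] - intercept) < 2 * se[1] + 1e-3

    def test_style_frequencies_goodness_of_fit(self):
        from scipy.stats import chisquare

        cfg = al.default_config(n_devices=5000, visits_min=1, visits_max=1, seed=13)
        ds, gt = al.simulate_dataset(cfg)
        counts = gt.devices["style"].value_counts()
        obs = np.array([counts.get(s, 0) for s in al.STYLES])
        exp = np.array([cfg.style_probs[s] for s in al.STYLES]) * len(gt.devices)
        assert chisquare(obs, exp).pvalue > 0.01

    def test_planted_lift_solver(self):
        cfg = al.default_config()
        P, lifts = _style_profile_matrix(cfg)
        assert np.allclose(P.sum(axis=1), 1)
        assert lifts[0]["realized_lift"] == pytest.approx(1.5, abs=1e-6)

    def test_representative_marks_primary_cleaning(self, sim_small):
        dataset, truth = sim_small
        cleaned, _ = al.apply_primary_rules(dataset)
        kept = set(zip(cleaned.frame["device_id"], cleaned.frame["session_seq"]))
        marked = set(
            zip(
                truth.snapshots.loc[truth.snapshots["representative"], "device_id"],
                truth.snapshots.loc[truth.snapshots["representative"], "session_seq"],
            )
        )
        assert kept == marked
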