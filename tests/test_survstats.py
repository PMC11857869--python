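"""KM, median, log-rank, Cox and RMST against hand calculations and oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

import km2ipd as k
from tests.oracles import cox_grid_oracle, logrank_oracle


# ------------------------------------------------------------- KM / median


class TestKaplanMeier:
    def test_hand_product_limit(self, worked_ipd):
        km = k.kaplan_meier(worked_ipd)
        np.testing.assert_allclose(km.event_times, [1, 2, 4])
        np.testing.assert_allclose(km.surv, [0.75, 0.5, 0.0])

    def test_hand_greenwood(self, worked_ipd):
        km = k.kaplan_meier(worked_ipd)
        # at t=2: 0.25 * (1/(4*3) + 1/(3*2))
        assert km.var_greenwood[1] == pytest.approx(0.0625)

    def test_all_censored_is_flat(self):
        km = k.kaplan_meier(k.make_ipd([1, 2, 3], [0, 0, 0]))
        assert len(km.event_times) == 0
        assert km.survival_at([0, 1, 5]).tolist() == [1, 1, 1]

    def test_no_censoring_equals_empirical_survival(self, sim_arm):
        ipd, _ = sim_arm
        ipd = ipd.assign(event=1)
        km = k.kaplan_meier(ipd)
        t = ipd["time"].to_numpy()
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines(self, sim_arm):
        ipd, _ = sim_arm
        kmf = KaplanMeierFitter().fit(ipd["time"], ipd["event"])
        km = k.kaplan_meier(ipd)
        ours = km.survival_at(km.event_times)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_empty_dataset_errors(self):
        with pytest.raises(k.InsufficientDataError):
            k.kaplan_meier(k.make_ipd([], []))


class TestMedian:
    def test_definition_case(self):
        km = k.kaplan_meier(k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1]))
        med, _ = k.median_survival(km)
        assert med == 2.0  # first time S <= 0.5

    def test_not_reached(self):
        km = k.kaplan_meier(k.make_ipd([1, 2, 3, 4, 5], [1, 0, 0, 0, 0]))
        med, (lo, hi) = k.median_survival(km)
        assert np.isnan(med) and np.isnan(hi)

    def test_exponential_closed_form(self):
        lam = 0.1
        cfg = k.SimTrialConfig(
            arms=(k.ArmSpec("a", lam, 5000),), censor_hazard=0.0,
            admin_censor_time=200.0, seed=5,
        )
        km = k.kaplan_meier(k.simulate_ipd(cfg))
        med, (lo, hi) = k.median_survival(km)
        true = np.log(2) / lam
        # median of the exponential, with a generous Monte-Carlo allowance
        mc_se = true / np.sqrt(5000)
        assert abs(med - true) < 3 * mc_se
        assert lo <= med <= hi


# ----------------------------------------------------------------- logrank


class TestLogrank:
    def test_identical_arms_null(self):
        ipd = pd.concat(
            [
                k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1], arm="a"),
                k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1], arm="b"),
            ]
        )
        stat, p = k.logrank(ipd, "a", "b")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_record_hand_oracle(self):
        ipd = pd.concat(
            [k.make_ipd([1, 2], [1, 1], arm="a"), k.make_ipd([3, 4], [1, 1], arm="b")]
        )
        stat, _ = k.logrank(ipd, "a", "b")
        assert stat == pytest.approx(logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1]))

    def test_random_datasets_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ta = rng.exponential(10, 15).round(1)
            tb = rng.exponential(14, 12).round(1)
            ea = rng.integers(0, 2, 15)
            eb = rng.integers(0, 2, 12)
            if ea.sum() + eb.sum() == 0:
                continue
            ipd = pd.concat(
                [k.make_ipd(ta, ea, arm="a"), k.make_ipd(tb, eb, arm="b")]
            )
            stat, _ = k.logrank(ipd, "a", "b")
            assert stat == pytest.approx(
                logrank_oracle(ta, ea, tb, eb), rel=1e-8
            )

    def test_label_order_invariance(self, sim_arm):
        ipd, _ = sim_arm
        half = len(ipd) // 2
        ipd = ipd.copy()
        ipd.loc[ipd.index[:half], "arm"] = "b"
        assert k.logrank(ipd, "a", "b")[0] == pytest.approx(k.logrank(ipd, "b", "a")[0])

    def test_missing_arm_errors(self, sim_arm):
        ipd, _ = sim_arm
        with pytest.raises(k.ValidationError):
            k.logrank(ipd, "a", "nope")

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            cfg = k.SimTrialConfig(
                arms=(k.ArmSpec("a", 0.02, 30), k.ArmSpec("b", 0.02, 30)),
                censor_hazard=0.01, admin_censor_time=30.0,
                seed=int(rng.integers(2**31)),
            )
            ipd = k.simulate_ipd(cfg)
            if ipd["event"].sum() == 0:
                continue
            rejections += k.logrank(ipd, "a", "b")[1] < 0.05
        assert 0.03 <= rejections / reps <= 0.07


# --------------------------------------------------------------------- Cox


class TestCox:
    def test_identical_arms_coef_zero(self):
        ipd = pd.concat(
            [
                k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1], arm="a"),
                k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1], arm="b"),
            ]
        )
        fit = k.cox_fit(ipd, reference_arm="a")
        assert fit.coef["b"] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr["b"] == pytest.approx(1.0, abs=1e-8)

    def test_six_record_grid_oracle(self):
        times = [1.0, 2.5, 3.0, 4.5, 6.0, 7.5]
        events = [1, 1, 0, 1, 1, 0]
        arm = ["b", "a", "b", "a", "b", "a"]
        ipd = pd.DataFrame({"time": times, "event": events, "arm": arm, "trial_id": "t"})
        fit = k.cox_fit(ipd, reference_arm="a")
        x = (np.array(arm) == "b").astype(float)
        oracle = cox_grid_oracle(times, events, x)
        assert fit.coef["b"] == pytest.approx(oracle, abs=1e-6)

    def test_label_swap_negates_coef(self):
        rng = np.random.default_rng(8)
        ipd = pd.concat(
            [
                k.make_ipd(rng.exponential(10, 40), rng.integers(0, 2, 40), arm="a"),
                k.make_ipd(rng.exponential(15, 40), rng.integers(0, 2, 40), arm="b"),
            ]
        )
        f1 = k.cox_fit(ipd, reference_arm="a")
        f2 = k.cox_fit(ipd, reference_arm="b")
        assert f1.coef["b"] == pytest.approx(-f2.coef["a"], abs=1e-8)

    def test_three_arm_pairwise_transitivity(self):
        cfg = k.SimTrialConfig(
            arms=(
                k.ArmSpec("w", 0.01, 300),
                k.ArmSpec("x", 0.0125, 300),
                k.ArmSpec("y", 0.0105, 300),
            ),
            censor_hazard=0.01, admin_censor_time=30.0, seed=21,
        )
        fit = k.cox_fit(k.simulate_ipd(cfg), reference_arm="w")
        assert fit.hr_between("x", "y") == pytest.approx(
            np.exp(fit.coef["x"] - fit.coef["y"])
        )
        assert fit.hr_between("x", "w") == pytest.approx(fit.hr["x"])

    def test_wald_and_lrt_agree_asymptotically(self):
        cfg = k.SimTrialConfig(
            arms=(k.ArmSpec("w", 0.01, 2000), k.ArmSpec("x", 0.013, 2000)),
            censor_hazard=0.01, admin_censor_time=30.0, seed=2,
        )
        fit = k.cox_fit(k.simulate_ipd(cfg), reference_arm="w")
        assert fit.wald_stat == pytest.approx(fit.lrt_stat, rel=0.10)

    def test_no_events_errors(self):
        ipd = pd.concat(
            [k.make_ipd([1, 2], [0, 0], arm="a"), k.make_ipd([1, 2], [0, 0], arm="b")]
        )
        with pytest.raises(k.ValidationError):
            k.cox_fit(ipd, reference_arm="a")


# -------------------------------------------------------------------- RMST


class TestRmst:
    def test_flat_survival(self):
        km = k.kaplan_meier(k.make_ipd([10, 12], [0, 0]))
        r = k.rmst(km, 8)
        assert r.estimate == 8.0 and r.se == 0.0

    def test_step_area_by_hand(self):
        # S = 1 on [0,1), 0.75 on [1,2), 0.5 on [2,4)
        km = k.kaplan_meier(k.make_ipd([1, 2, 4, 4], [1, 1, 0, 0]))
        r = k.rmst(km, 4)
        assert r.estimate == pytest.approx(2.75)

    def test_matches_lifelines(self, sim_arm):
        ipd, _ = sim_arm
        kmf = KaplanMeierFitter().fit(ipd["time"], ipd["event"])
        ours = k.rmst(k.kaplan_meier(ipd), 24.0)
        theirs = restricted_mean_survival_time(kmf, t=24.0)
        assert ours.estimate == pytest.approx(float(theirs), abs=1e-9)

    def test_exponential_closed_form(self):
        lam, tau = 0.1, 30.0
        cfg = k.SimTrialConfig(
            arms=(k.ArmSpec("a", lam, 5000),), censor_hazard=0.0,
            admin_censor_time=60.0, seed=9,
        )
        r = k.rmst(k.kaplan_meier(k.simulate_ipd(cfg)), tau)
        true = (1 - np.exp(-lam * tau)) / lam
        assert abs(r.estimate - true) < 3 * r.se

    def test_monotone_in_tau_and_bounded(self, sim_arm):
        ipd, _ = sim_arm
        km = k.kaplan_meier(ipd)
        taus = [5, 10, 20, 29]
        vals = [k.rmst(km, t).estimate for t in taus]
        assert all(np.diff(vals) >= 0)
        assert all(v <= t for v, t in zip(vals, taus))

    def test_refuses_extrapolation(self, sim_arm):
        ipd, _ = sim_arm
        km = k.kaplan_meier(ipd)
        with pytest.raises(k.ExtrapolationError):
            k.rmst(km, km.max_time + 5)
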