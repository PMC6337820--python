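"""Survival kernels against hand computations and dense grid oracles."""

import numpy as np
import pandas as pd
import pytest

from jointbone.imputation import TrajectoryMatrix, locf_impute
from jointbone.survival import (
    fit_cox,
    fit_extended_cox,
    kaplan_meier,
    logrank_test,
    to_counting_process,
)
from jointbone.synthetic import CohortConfig, simulate_cohort


def cox_partial_loglik(beta, time, status, x):
    """Independent scalar-covariate partial likelihood (Breslow-free: no ties
    in the fixtures it scores)."""
    ll = 0.0
    for i in np.flatnonzero(status == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        rec = pd.DataFrame({"time_obs": [1.0, 2.0, 3.0, 4.0], "status": [1, 1, 1, 1]})
        km = kaplan_meier(rec)
        assert np.allclose(km(np.array([1.0, 2.0, 3.0, 4.0])), [0.75, 0.5, 0.25, 0.0])
        assert km(0.5)[0] == 1.0

    def test_all_censored_curve_stays_at_one(self):
        rec = pd.DataFrame({"time_obs": [2.0, 5.0, 7.0], "status": [0, 0, 0]})
        km = kaplan_meier(rec)
        assert np.allclose(km(np.array([1.0, 6.0, 10.0])), 1.0)

    def test_hand_product_limit_with_censoring(self, tiny_survival):
        # events at 1 and 2, censored at 1.5: S(1)=2/3, S(2)=0
        km = kaplan_meier(tiny_survival)
        assert km(1.0)[0] == pytest.approx(2.0 / 3.0)
        assert km(1.7)[0] == pytest.approx(2.0 / 3.0)
        assert km(2.0)[0] == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_give_null(self):
        base = pd.DataFrame({"time_obs": [1.0, 2.0, 3.0], "status": [1, 1, 0]})
        rec = pd.concat(
            [base.assign(g=0), base.assign(g=1)], ignore_index=True
        )
        stat, p = logrank_test(rec, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_hypergeometric_value(self):
        """Group A events at 1,2; group B at 3,4.  Working through the risk
        sets by hand: O-E = 1/2 + 1/3 + 1/3 + 0 = 7/6 and the hypergeometric
        variances sum to 1/4 + 2/9 + 0 + 0 = 17/36, so chi2 = 49/17."""
        rec = pd.DataFrame(
            {
                "time_obs": [1.0, 2.0, 3.0, 4.0],
                "status": [1, 1, 1, 1],
                "g": [0, 0, 1, 1],
            }
        )
        stat, p = logrank_test(rec, "g")
        assert stat == pytest.approx(49.0 / 17.0, rel=1e-10)

    def test_matches_cox_score_test_binary_covariate(self):
        """With one binary covariate and no ties, the log-rank statistic
        equals the Cox score test U(0)^2 / I(0)."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            n = 30
            time = rng.exponential(10, n) + rng.uniform(0, 1e-3, n)  # no ties
            status = rng.binomial(1, 0.8, n)
            x = rng.binomial(1, 0.5, n).astype(float)
            if status.sum() == 0 or len(np.unique(x)) < 2:
                continue
            rec = pd.DataFrame({"time_obs": time, "status": status, "g": x})
            stat, _ = logrank_test(rec, "g")
            U, I = 0.0, 0.0
            for i in np.flatnonzero(status == 1):
                risk = time >= time[i]
                pbar = np.sum(x[risk]) / np.sum(risk)
                U += x[i] - pbar
                I += pbar * (1 - pbar)
            assert stat == pytest.approx(U**2 / I, rel=1e-6)

    def test_single_group_rejected(self):
        rec = pd.DataFrame({"time_obs": [1.0, 2.0], "status": [1, 1], "g": [0, 0]})
        with pytest.raises(ValueError):
            logrank_test(rec, "g")


class TestCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        base = pd.DataFrame({"time_obs": [1.0, 2.0, 3.0, 5.0], "status": [1, 1, 1, 0]})
        rec = pd.concat([base.assign(x=0.0), base.assign(x=1.0)], ignore_index=True)
        fit = fit_cox(rec, ["x"])
        assert fit.gamma.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_six_record_grid_oracle(self):
        rec = pd.DataFrame(
            {
                "time_obs": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "status": [1, 1, 1, 1, 1, 0],
                "x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            }
        )
        fit = fit_cox(rec, ["x"])
        grid = np.linspace(-3, 3, 60001)
        time, status, x = (rec[c].to_numpy() for c in ("time_obs", "status", "x"))
        lls = np.zeros_like(grid)
        for i in np.flatnonzero(status == 1):
            risk_x = x[time >= time[i]]
            lls += grid * x[i] - np.log(
                np.exp(grid[:, None] * risk_x[None, :]).sum(axis=1)
            )
        assert fit.gamma.iloc[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)
        assert fit.loglik == pytest.approx(np.max(lls), abs=1e-6)

    def test_partial_loglik_dominates_null(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame(
            {
                "time_obs": rng.exponential(5, 50),
                "status": rng.binomial(1, 0.7, 50),
                "x": rng.normal(0, 1, 50),
            }
        )
        fit = fit_cox(rec, ["x"])
        ll0 = cox_partial_loglik(
            0.0, rec.time_obs.to_numpy(), rec.status.to_numpy(), rec.x.to_numpy()
        )
        assert fit.loglik >= ll0

    def test_recovery_from_proportional_hazards_simulation(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        T = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x)))
        C = rng.uniform(0, 30, n)
        rec = pd.DataFrame(
            {"time_obs": np.minimum(T, C), "status": (T <= C).astype(int), "x": x}
        )
        fit = fit_cox(rec, ["x"])
        assert abs(fit.gamma.iloc[0] - 0.7) < 3 * fit.se.iloc[0]


class TestCountingProcess:
    baseline = pd.DataFrame(
        {"id": [1], "time_obs": [5.0], "status": [1], "age": [60.0]}
    )

    def test_measurements_define_intervals(self):
        long = pd.DataFrame({"id": [1, 1, 1], "t": [0.0, 1.0, 3.0], "y": [4.0, 3.5, 3.0]})
        cp = to_counting_process(self.baseline, long, covariates=["age"])
        assert np.allclose(cp["start"], [0.0, 1.0, 3.0])
        assert np.allclose(cp["stop"], [1.0, 3.0, 5.0])
        assert np.allclose(cp["biomarker"], [4.0, 3.5, 3.0])
        assert list(cp["status"]) == [0, 0, 1]
        assert (cp["age"] == 60.0).all()

    def test_single_baseline_measurement_censored(self):
        base = self.baseline.assign(status=0, time_obs=7.0)
        long = pd.DataFrame({"id": [1], "t": [0.0], "y": [4.0]})
        cp = to_counting_process(base, long)
        assert len(cp) == 1
        assert (cp.iloc[0]["start"], cp.iloc[0]["stop"], cp.iloc[0]["status"]) == (0.0, 7.0, 0)

    def test_truncation_discards_later_measurements(self):
        base = self.baseline.assign(time_obs=2.5, status=0)
        long = pd.DataFrame({"id": [1, 1, 1], "t": [0.0, 1.0, 3.0], "y": [4.0, 3.5, 3.0]})
        cp = to_counting_process(base, long)
        assert np.allclose(cp["stop"].to_numpy(), [1.0, 2.5])
        assert 3.0 not in cp["biomarker"].to_numpy()

    def test_patient_without_measurements_dropped(self):
        base = pd.DataFrame(
            {"id": [1, 2], "time_obs": [5.0, 4.0], "status": [1, 1], "age": [60.0, 50.0]}
        )
        long = pd.DataFrame({"id": [1], "t": [0.0], "y": [4.0]})
        cp = to_counting_process(base, long, covariates=["age"])
        assert set(cp["id"]) == {1}


class TestExtendedCox:
    def test_constant_covariate_equals_plain_cox(self):
        rng = np.random.default_rng(4)
        n = 60
        base = pd.DataFrame(
            {
                "id": np.arange(n),
                "time_obs": rng.exponential(8, n) + 0.5,
                "status": rng.binomial(1, 0.7, n),
                "x": rng.normal(0, 1, n),
            }
        )
        # time-varying layout with a constant per-patient value
        long = pd.DataFrame(
            {
                "id": np.repeat(np.arange(n), 2),
                "t": np.tile([0.0, 0.25], n),
                "y": np.repeat(base["x"].to_numpy(), 2),
            }
        )
        cp = to_counting_process(base, long, out_col="x_tv")
        ext = fit_extended_cox(cp, ["x_tv"])
        ph = fit_cox(base, ["x"])
        assert ext.gamma.iloc[0] == pytest.approx(ph.gamma.iloc[0], abs=1e-8)
        assert ext.loglik == pytest.approx(ph.loglik, abs=1e-8)

    def test_eight_row_grid_oracle(self):
        """Time-varying partial likelihood maximized by dense grid search."""
        cp = pd.DataFrame(
            {
                "id": [1, 1, 2, 2, 3, 3, 4, 4],
                "start": [0.0, 1.0, 0.0, 1.0, 0.0, 2.0, 0.0, 3.0],
                "stop": [1.0, 2.5, 1.0, 3.5, 2.0, 4.5, 3.0, 6.0],
                "status": [0, 1, 0, 1, 0, 1, 0, 0],
                "z": [1.0, 2.0, 0.5, 0.2, 1.5, 0.1, 0.3, 1.0],
            }
        )
        fit = fit_extended_cox(cp, ["z"])

        grid = np.linspace(-4, 4, 80001)
        lls = np.zeros_like(grid)
        for _, ev in cp[cp.status == 1].iterrows():
            t = ev["stop"]
            risk_z = cp.loc[(cp.start < t) & (t <= cp.stop), "z"].to_numpy()
            lls += grid * ev["z"] - np.log(
                np.exp(grid[:, None] * risk_z[None, :]).sum(axis=1)
            )
        assert fit.gamma.iloc[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_omit_and_locf_yield_identical_fits(self, default_cohort):
        covs = ["age", "sex", "extra_mets"]
        cp_omit = to_counting_process(
            default_cohort.baseline, default_cohort.longitudinal, covariates=covs
        )
        M = TrajectoryMatrix.from_long(
            default_cohort.longitudinal, np.array([0.0, 1.0, 3.0, 6.0, 9.0, 12.0])
        )
        cp_locf = to_counting_process(
            default_cohort.baseline, locf_impute(M).to_long(), covariates=covs
        )
        f1 = fit_extended_cox(cp_omit, covs + ["biomarker"])
        f2 = fit_extended_cox(cp_locf, covs + ["biomarker"])
        assert np.max(np.abs(f1.gamma.to_numpy() - f2.gamma.to_numpy())) < 1e-10

    def test_attenuation_under_measurement_error(self):
        """Plugging the noisy step function into the hazard biases the
        association toward zero: mean estimate strictly between 0 and the
        generating alpha."""
        ests = []
        for s in range(12):
            cfg = CohortConfig(
                n_patients=150, seed=700 + s, sigma=0.7,
                dropout_prob=0.0, intermittent_miss_prob=0.0,
            )
            cohort = simulate_cohort(cfg)
            cp = to_counting_process(
                cohort.baseline, cohort.longitudinal,
                covariates=["age", "sex", "extra_mets"],
            )
            fit = fit_extended_cox(cp, ["age", "sex", "extra_mets", "biomarker"])
            ests.append(float(fit.gamma["biomarker"]))
        mean = np.mean(ests)
        assert 0.0 < mean < 0.2
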