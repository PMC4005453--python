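import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmqueue.analytics import ShiftParameters
from pharmqueue.errors import InsufficientDataError
from pharmqueue.synthetic import (
    ObservationDesign,
    PatientLog,
    ShiftPlan,
    consolidated_study_design,
    estimate_rates,
    exponential_ks,
    fit_tests,
    generate_log,
    pharmacy_study_design,
    poisson_chi_square,
)


def _single_shift_design(lam=14.87, seed=0, windows=8):
    plan = ShiftPlan("m", 0.0, 30.0 * windows, lam, {"service": 4}, {"service": 30 / 14})
    return ObservationDesign((plan,), seed=seed)


class TestGenerateLog:
    def test_zero_rate_gives_empty_log(self):
        plan = ShiftPlan("m", 0.0, 240.0, 0.0, {"service": 1}, {"service": 1.0})
        log = generate_log(ObservationDesign((plan,), seed=0))
        assert len(log) == 0 and log.shift_minutes == {"m": 240.0}

    def test_deterministic_given_seed(self):
        a = generate_log(pharmacy_study_design(seed=4))
        b = generate_log(pharmacy_study_design(seed=4))
        assert a.frame.equals(b.frame)

    def test_observation_form_columns(self):
        log = generate_log(pharmacy_study_design(seed=4))
        assert list(log.frame.columns) == [
            "id", "shift", "sampled", "arrival",
            "receive_start", "receive_end", "fill_start", "fill_end",
            "cashier", "deliver_start", "deliver_end",
        ]
        assert (log.frame["cashier"] == log.frame["fill_end"]).all() or (
            log.frame["cashier"].isna() == log.frame["fill_end"].isna()
        ).all()

    def test_timestamps_non_decreasing_per_patient(self):
        log = generate_log(pharmacy_study_design(seed=4))
        cols = ["arrival", "receive_start", "receive_end", "fill_start",
                "fill_end", "deliver_start", "deliver_end"]
        complete = log.frame.dropna(subset=cols)
        diffs = complete[cols].diff(axis=1).iloc[:, 1:]
        assert (diffs.to_numpy() >= -1e-12).all()

    def test_poisson_arrival_count_calibration(self):
        """Across 100 seeds, the mean morning arrival count matches the
        Poisson mean 8 * 14.87 within 3 standard errors."""
        totals = [
            len(generate_log(_single_shift_design(seed=s))) for s in range(100)
        ]
        mean, truth = np.mean(totals), 8 * 14.87
        se = np.sqrt(truth) / np.sqrt(100)
        assert abs(mean - truth) <= 3 * se

    def test_systematic_sample_size(self):
        log = generate_log(pharmacy_study_design(seed=4, target_n=100))
        n_sampled = int(log.frame["sampled"].sum())
        assert 100 <= n_sampled <= 2 * 100

    def test_csv_round_trip(self, tmp_path):
        log = generate_log(pharmacy_study_design(seed=4))
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = PatientLog.from_csv(path)
        assert len(back) == len(log)
        assert np.allclose(
            back.frame["arrival"], log.frame["arrival"], atol=5e-4
        )


class TestEstimateRates:
    def test_recovers_rates_within_sampling_error(self):
        """30 replicated studies: mean estimates near truth (3 SE)."""
        lam = {"morning": [], "evening": []}
        mu = {"morning": [], "evening": []}
        for seed in range(30):
            log = generate_log(consolidated_study_design(seed=seed))
            for lbl, r in estimate_rates(log).items():
                lam[lbl].append(r.lam_hat)
                mu[lbl].append(r.mu_hat)
        for lbl, tl, tm in (("morning", 14.87, 14.0), ("evening", 12.5, 11.5)):
            for vals, truth in ((lam[lbl], tl), (mu[lbl], tm)):
                x = np.asarray(vals)
                se = x.std(ddof=1) / np.sqrt(len(x))
                assert abs(x.mean() - truth) <= 3 * se, (lbl, truth, x.mean())

    def test_single_patient_trivial_case(self):
        frame = pd.DataFrame(
            {"id": [0], "shift": ["m"], "sampled": [True], "arrival": [1.0],
             "service_start": [1.0], "service_end": [31.0]}
        )
        log = PatientLog(frame, {"m": 60.0})
        est = estimate_rates(log, 30.0)["m"]
        assert est.mu_hat == pytest.approx(1.0)
        assert np.isnan(est.mu_se)

    def test_doubling_time_scale_halves_lambda(self):
        log = generate_log(_single_shift_design(seed=3))
        stretched = PatientLog(
            log.frame.assign(
                **{
                    c: log.frame[c] * 2
                    for c in log.frame.columns
                    if c not in ("id", "shift", "sampled")
                }
            ),
            {"m": 2 * log.shift_minutes["m"]},
        )
        a = estimate_rates(log)["m"]
        b = estimate_rates(stretched)["m"]
        assert b.lam_hat == pytest.approx(a.lam_hat / 2)
        assert b.mu_hat == pytest.approx(a.mu_hat / 2)

    def test_empty_log_rejected(self):
        plan = ShiftPlan("m", 0.0, 240.0, 0.0, {"service": 1}, {"service": 1.0})
        log = generate_log(ObservationDesign((plan,), seed=0))
        with pytest.raises(InsufficientDataError):
            estimate_rates(log)


class TestFitTests:
    def test_type_one_error_quick_check(self):
        """Null rejection rate at alpha=0.05 over 120 studies stays in a
        generous binomial band (the precise calibration runs in the
        acceptance suite)."""
        rej = 0
        n_sim = 120
        for seed in range(n_sim):
            log = generate_log(_single_shift_design(seed=seed, windows=16))
            rep = fit_tests(log, n_boot=200, seed=seed)["m"]
            rej += rep.arrival.p_value <= 0.05
        assert 0.01 <= rej / n_sim <= 0.11

    def test_power_against_fixed_interval_arrivals(self):
        """Deterministic arrivals produce constant window counts, which
        the Poisson test rejects essentially always."""
        rej = 0
        for seed in range(20):
            counts = np.full(16, 14)
            r = poisson_chi_square(counts, n_boot=200, rng=np.random.default_rng(seed))
            rej += r.p_value <= 0.05
        assert rej / 20 >= 0.8

    def test_ks_p_values_uniform_under_null(self):
        """Probability-integral transform: bootstrap KS p-values of truly
        exponential samples are uniform on [0, 1]."""
        ps = [
            exponential_ks(
                np.random.default_rng(seed).exponential(2.14, size=220),
                n_boot=300,
                rng=np.random.default_rng(10_000 + seed),
            ).p_value
            for seed in range(60)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_asymptotic_ks_is_conservative(self):
        """With the mean estimated from the data, the classical KS
        p-value is systematically too large: this is why the bootstrap
        is the default."""
        x = np.random.default_rng(0).exponential(1.0, size=220)
        asym = exponential_ks(x, method="asymptotic")
        boot = exponential_ks(x, n_boot=500, rng=np.random.default_rng(1))
        assert asym.p_value > boot.p_value

    def test_time_origin_invariance(self):
        log = generate_log(_single_shift_design(seed=6))
        shift_cols = [
            c for c in log.frame.columns if c not in ("id", "shift", "sampled")
        ]
        moved = PatientLog(
            log.frame.assign(**{c: log.frame[c] + 17.0 for c in shift_cols}),
            dict(log.shift_minutes),
        )
        a = fit_tests(log, seed=5)["m"]
        b = fit_tests(moved, origin=17.0, seed=5)["m"]
        assert a.arrival.statistic == pytest.approx(b.arrival.statistic)
        assert a.service.statistic == pytest.approx(b.service.statistic)
        assert a.arrival.p_value == b.arrival.p_value

    def test_insufficient_windows_named_error(self):
        counts = np.array([3, 4, 5, 2])
        with pytest.raises(InsufficientDataError, match="arrival"):
            poisson_chi_square(counts)

    def test_insufficient_service_times_named_error(self):
        with pytest.raises(InsufficientDataError, match="service"):
            exponential_ks(np.array([1.0, 2.0]))

    def test_asymptotic_chi_square_needs_cells(self):
        counts = np.random.default_rng(0).poisson(14.87, 8)
        with pytest.raises(InsufficientDataError):
            poisson_chi_square(counts, method="asymptotic")
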