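import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexdev.gam import (
    DerivativeBand,
    age_significance,
    build_age_basis,
    derivative_band,
    fdr_adjust,
    fit_gam,
    fit_trajectories,
    partial_r2_signed,
    plateau_age,
)


def _table(n=200, seed=0, fn=lambda a: 2 + 0.5 * a, sigma=0.0, age_range=(5, 36)):
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, n)
    return pd.DataFrame(
        {
            "age": age,
            "value": fn(age) + rng.normal(0, sigma, n),
            "sex": rng.choice(["F", "M"], n),
            "subject_id": [f"s{i}" for i in range(n)],
        }
    )


class TestAgeBasis:
    def test_constant_outside_span(self):
        ages = np.random.default_rng(0).uniform(0, 10, 50)
        basis = build_age_basis(ages, k=3)
        # projecting the constant onto the centered columns leaves nothing
        coefs, res, *_ = np.linalg.lstsq(basis.matrix, np.ones(50), rcond=None)
        assert np.allclose(basis.matrix @ coefs, 0.0, atol=1e-10)

    def test_penalty_null_space_is_linear(self):
        ages = np.linspace(0, 10, 30)
        basis = build_age_basis(ages, k=3)
        # the first (linear) direction carries zero penalty
        v = np.zeros(2)
        v[0] = 1.0
        assert v @ basis.penalty @ v == 0.0
        v2 = np.array([0.0, 1.0])
        assert v2 @ basis.penalty @ v2 > 0.0

    def test_reproduces_quadratic_unpenalized(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 10, 80)
        y = 1.0 - 0.7 * ages + 0.05 * ages**2
        basis = build_age_basis(ages, k=3)
        X = np.column_stack([np.ones(80), basis.matrix])
        coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.abs(X @ coefs - y).max() <= 1e-6

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError):
            build_age_basis(np.array([1.0, 1.0, 2.0]), k=3)

    def test_evaluate_consistent_with_matrix(self):
        ages = np.random.default_rng(2).uniform(0, 10, 40)
        basis = build_age_basis(ages, k=3)
        assert np.allclose(basis.evaluate(ages), basis.matrix, atol=1e-10)


class TestFitGam:
    def test_noiseless_linear_truth(self):
        df = _table()
        fit = fit_gam(df)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert np.abs(fit.fitted - df["value"].to_numpy()).max() <= 1e-6

    def test_lambda_zero_equals_normal_equations(self):
        df = _table(n=100, seed=3, fn=lambda a: 1 + 0.1 * a + 0.01 * a**2, sigma=0.2)
        fit = fit_gam(df, lambda_smooth=0.0)
        basis = build_age_basis(df["age"].to_numpy())
        X = np.column_stack(
            [np.ones(100), (df["sex"] == "M").astype(float), basis.matrix]
        )
        beta_ols = np.linalg.solve(X.T @ X, X.T @ df["value"].to_numpy())
        assert np.abs(fit.beta - beta_ols).max() <= 1e-8

    def test_large_lambda_collapses_to_linear(self):
        df = _table(n=150, seed=4, fn=lambda a: np.sqrt(a), sigma=0.05)
        fit = fit_gam(df, lambda_smooth=1e12)
        # curved coefficient shrunk to ~0: fitted values linear in age
        resid = np.polyfit(df["age"], fit.fitted - fit.beta[1] * (df["sex"] == "M"), 1, full=True)[1]
        assert float(resid[0]) < 1e-10

    def test_flat_truth_slope_near_zero(self):
        slopes = []
        for rep in range(30):
            df = _table(n=200, seed=100 + rep, fn=lambda a: 1.0 + 0 * a, sigma=0.05)
            fit = fit_gam(df)
            band = derivative_band(fit, n_sim=500, seed=rep)
            slopes.append(band.mean_slope())
        assert abs(np.mean(slopes)) < 5e-4

    def test_longitudinal_sigma_b_recovery(self):
        sigma_b, sigma = 0.05, 0.03
        rng = np.random.default_rng(12)
        rows = []
        for i in range(50):
            b = rng.normal(0, sigma_b)
            sex = rng.choice(["F", "M"])
            for a in np.sort(rng.uniform(0.1, 3.0, 5)):
                mu = 1.2 + 0.3 * (1 - np.exp(-1.5 * a))
                rows.append((f"s{i}", a, sex, mu + b + rng.normal(0, sigma)))
        df = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "value"])
        fit = fit_gam(df, random_intercept="subject")
        assert fit.sigma_b2 == pytest.approx(sigma_b**2, rel=0.25)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_gam(_table(n=5))

    def test_constant_sex_rejected(self):
        df = _table(n=50, seed=6)
        df["sex"] = "F"
        with pytest.raises(ValueError, match="sex"):
            fit_gam(df)


class TestAgeSignificance:
    def test_identical_fits_p_one(self):
        df = _table(n=100, seed=7, sigma=0.1)
        full = fit_gam(df)
        assert age_significance(full, full_as_reduced(full)) == 1.0

    def test_strong_signal_tiny_p(self):
        df = _table(n=500, seed=8, fn=lambda a: 1 + 0.5 * a, sigma=0.01)
        full = fit_gam(df)
        reduced = fit_gam(df, include_age=False)
        assert age_significance(full, reduced) < 1e-10

    def test_type_i_error_calibrated_quick(self):
        # small version of the calibration criterion; full run in acceptance
        rej = 0
        reps = 120
        for rep in range(reps):
            df = _table(n=200, seed=2000 + rep, fn=lambda a: 1 + 0 * a, sigma=0.05)
            full = fit_gam(df)
            reduced = fit_gam(df, include_age=False)
            if age_significance(full, reduced) < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.10

    def test_non_nested_rejected(self):
        a = fit_gam(_table(n=50, seed=9, sigma=0.1))
        b = fit_gam(_table(n=60, seed=10, sigma=0.1))
        with pytest.raises(ValueError):
            age_significance(a, b)


def full_as_reduced(fit):
    """Shallow stand-in: a 'reduced' fit identical to the full one."""
    import copy

    red = copy.copy(fit)
    red.term_slices = {k: v for k, v in fit.term_slices.items() if k != "age"}
    return red


class TestPartialR2:
    def test_noiseless_increasing_near_one(self):
        df = _table(n=300, seed=11, fn=lambda a: 1 + 0.2 * a, sigma=1e-8)
        full, reduced = fit_gam(df), fit_gam(df, include_age=False)
        band = derivative_band(full, n_sim=200, seed=0)
        assert partial_r2_signed(full, reduced, band) == pytest.approx(1.0, abs=1e-6)

    def test_decreasing_sign_negative(self):
        df = _table(n=300, seed=12, fn=lambda a: 10 - 0.2 * a, sigma=1e-8)
        full, reduced = fit_gam(df), fit_gam(df, include_age=False)
        band = derivative_band(full, n_sim=200, seed=0)
        assert partial_r2_signed(full, reduced, band) == pytest.approx(-1.0, abs=1e-6)

    def test_flat_truth_small_magnitude(self):
        vals = []
        for rep in range(50):
            df = _table(n=200, seed=3000 + rep, fn=lambda a: 1 + 0 * a, sigma=0.05)
            full, reduced = fit_gam(df), fit_gam(df, include_age=False)
            band = derivative_band(full, n_sim=200, seed=rep)
            vals.append(abs(partial_r2_signed(full, reduced, band)))
        # expected magnitude ~ edf/n
        assert np.mean(vals) < 0.03

    def test_affine_response_invariance(self):
        df = _table(n=150, seed=13, fn=lambda a: 1 + 0.05 * a, sigma=0.1)
        full, reduced = fit_gam(df), fit_gam(df, include_age=False)
        band = derivative_band(full, n_sim=200, seed=0)
        v1 = partial_r2_signed(full, reduced, band)
        df2 = df.assign(value=3.0 * df["value"] + 7.0)
        full2, reduced2 = fit_gam(df2), fit_gam(df2, include_age=False)
        band2 = derivative_band(full2, n_sim=200, seed=0)
        assert partial_r2_signed(full2, reduced2, band2) == pytest.approx(v1, abs=1e-6)


class TestDerivativeBand:
    def test_linear_truth_recovers_slope(self):
        df = _table(n=800, seed=14, fn=lambda a: 2 + 0.5 * a, sigma=0.05)
        fit = fit_gam(df)
        band = derivative_band(fit, n_sim=2000, seed=1)
        se = band.se.mean()
        assert np.all(np.abs(band.estimate - 0.5) < 3 * np.maximum(band.se, se))

    def test_simultaneous_wider_than_pointwise(self):
        from scipy import stats

        df = _table(n=200, seed=15, sigma=0.1)
        fit = fit_gam(df)
        band = derivative_band(fit, n_sim=2000, seed=2)
        assert band.critical >= stats.norm.ppf(0.975)
        half = band.upper - band.estimate
        pointwise = stats.norm.ppf(0.975) * band.se
        assert np.all(half >= pointwise - 1e-12)

    def test_band_ordering_invariant(self):
        df = _table(n=100, seed=16, sigma=0.1)
        band = derivative_band(fit_gam(df), n_sim=500, seed=3)
        assert np.all(band.lower <= band.estimate) and np.all(band.estimate <= band.upper)

    def test_deterministic_under_seed(self):
        df = _table(n=100, seed=17, sigma=0.1)
        fit = fit_gam(df)
        b1 = derivative_band(fit, n_sim=500, seed=4)
        b2 = derivative_band(fit, n_sim=500, seed=4)
        assert np.array_equal(b1.lower, b2.lower)


def _constructed_band(grid, est, lo, hi):
    return DerivativeBand(
        grid=grid, estimate=est, lower=lo, upper=hi,
        se=(hi - lo) / 4, critical=2.0, level=0.95, n_sim=0, seed=0,
    )


class TestPlateauAge:
    def test_interior_window_gives_plateau(self):
        grid = np.linspace(5, 36, 100)
        est = np.where(grid <= 15, 0.1, 0.0)
        lo = np.where(grid <= 15, 0.05, -0.01)
        hi = est + 0.05
        res = plateau_age(_constructed_band(grid, est, lo, hi))
        assert res.plateau_reached
        assert res.plateau_age == pytest.approx(grid[grid <= 15].max())

    def test_significance_to_boundary_censored(self):
        grid = np.linspace(5, 36, 100)
        est = np.full(100, 0.1)
        res = plateau_age(_constructed_band(grid, est, est - 0.01, est + 0.01))
        assert not res.plateau_reached
        assert res.plateau_age is None

    def test_never_significant_no_windows(self):
        grid = np.linspace(5, 36, 100)
        est = np.zeros(100)
        res = plateau_age(_constructed_band(grid, est, est - 0.1, est + 0.1))
        assert not res.plateau_reached
        assert res.windows == []

    def test_trailing_negative_artifact_ignored(self):
        # rising window ends mid-range; spurious negative window at the end
        grid = np.linspace(5, 36, 100)
        est = np.linspace(0.1, -0.05, 100)
        lo = est - 0.02
        hi = est + 0.02
        res = plateau_age(_constructed_band(grid, est, lo, hi))
        assert res.plateau_reached
        assert res.plateau_age < 36


class TestFdrAdjust:
    def brute_force(self, p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
            ]
            q[idx] = min(1.0, min(candidates))
        return q

    def test_worked_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(q, self.brute_force([0.01, 0.02, 0.03, 0.04]))

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        assert np.allclose(fdr_adjust(p), self.brute_force(p), atol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestFitTrajectories:
    def test_results_schema_and_fdr(self):
        rng = np.random.default_rng(20)
        rows = []
        for pid in range(3):
            for db in (1, 2):
                age = rng.uniform(5, 36, 40)
                mu = 1 + 0.02 * pid * age
                for a, m in zip(age, mu):
                    rows.append((f"s{rng.integers(1e6)}", a, rng.choice(["F", "M"]), pid, db, m + rng.normal(0, 0.05)))
        table = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "parcel_id", "depth_bin", "value"])
        results, bands = fit_trajectories(table, n_sim=300, seed=0)
        assert len(results) == 6
        assert {"partial_r2", "p_age", "q_age", "mean_slope", "plateau_age", "plateau_reached"} <= set(results.columns)
        assert results.attrs["fdr_family"] == "depth_bin"
        assert len(bands) == 6
        # q-values computed within each depth bin
        for db, sub in results.groupby("depth_bin"):
            assert np.allclose(np.sort(sub["q_age"]), np.sort(fdr_adjust(sub["p_age"].to_numpy())))
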