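"""Regression core: flagging, design matrix, subset fitting, Phred transform."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import bqrecal as bq
from bqrecal.model import (
    BASE_EXOG_NAMES,
    FlaggedPositions,
    fit_subsets,
    median_coefficients,
    predict_error_probability,
    probability_to_phred,
)


def training_from_counts(error_counts, clean_per_pos=100):
    """Training table with the given error count at read positions 1..len."""
    rows = []
    for i, n_err in enumerate(error_counts, start=1):
        rows += [(i, 1)] * n_err + [(i, 0)] * clean_per_pos
    df = pd.DataFrame(rows, columns=["read_pos", "is_error"])
    df["chrom"], df["pos"], df["base"] = "c", 1, "A"
    df["ref_base"] = np.where(df["is_error"] == 1, "C", "A")
    df["qual"] = 30
    df["read_mean_qual"] = 30.0
    return df


class TestFlagReadPositions:
    def test_uniform_errors_flag_nothing(self):
        fl = bq.flag_read_positions(training_from_counts([10, 10, 10, 10]))
        assert fl.positions == () and fl.threshold == pytest.approx(15.0)

    def test_single_outlier_position_flagged(self):
        # counts [10,10,10,100]: mean 32.5, threshold 48.75 -> only position 4
        fl = bq.flag_read_positions(training_from_counts([10, 10, 10, 100]))
        assert fl.positions == (4,)
        assert fl.threshold == pytest.approx(48.75)

    def test_matches_brute_force_scan_on_simulated_errors(self, training_small):
        tr = training_small.training
        fl = bq.flag_read_positions(tr)
        read_length = int(tr["read_pos"].max())
        counts = {
            p: int(((tr["read_pos"] == p) & (tr["is_error"] == 1)).sum())
            for p in range(1, read_length + 1)
        }
        threshold = 1.5 * sum(counts.values()) / read_length
        expected = tuple(p for p in sorted(counts) if counts[p] > threshold)
        assert fl.positions == expected
        assert fl.k >= 1  # simulated errors are end-of-read enriched

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            bq.flag_read_positions(training_from_counts([])[:0])


class TestDesignMatrix:
    flagged = FlaggedPositions(positions=(3, 5), threshold=1.0)

    def row(self, base, qual, read_pos):
        df = pd.DataFrame(
            {
                "base": [base],
                "qual": [qual],
                "read_mean_qual": [20.0],
                "read_pos": [read_pos],
                "is_error": [0],
            }
        )
        X, y, names = bq.build_design_matrix(df, self.flagged)
        return dict(zip(names, X[0])), y

    def test_quality_zero_base_g_unflagged(self):
        r, _ = self.row("G", 0, 4)
        assert r["qual"] == 0 and r["qual_is_zero"] == 1
        assert (r["base_A"], r["base_C"], r["base_G"]) == (0, 0, 1)
        assert r["read_pos_3"] == 0 and r["read_pos_5"] == 0

    def test_base_t_is_reference_category(self):
        r, _ = self.row("T", 30, 1)
        assert (r["base_A"], r["base_C"], r["base_G"]) == (0, 0, 0)

    def test_flagged_position_indicator_fires(self):
        r, _ = self.row("A", 30, 5)
        assert r["base_A"] == 1
        assert r["read_pos_3"] == 0 and r["read_pos_5"] == 1

    def test_column_order_and_labels(self, training_small):
        tr = training_small.training
        fl = bq.flag_read_positions(tr)
        X, y, names = bq.build_design_matrix(tr, fl)
        assert names[:8] == BASE_EXOG_NAMES
        assert X.shape == (len(tr), 8 + fl.k)
        assert (y == tr["is_error"].to_numpy()).all()
        assert (X[:, 0] == 1).all()


def simulate_logistic(n, beta, seed):
    """Draw (X, y) from the logistic model with known coefficients."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = np.column_stack(
        [np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)]
    )
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    return X, y


class TestFitSubsets:
    beta = np.array([-2.0, 0.8, -0.5, 0.3])

    def test_single_subset_equals_direct_full_fit(self):
        X, y = simulate_logistic(5_000, self.beta, seed=5)
        coefs = fit_subsets(X, y, subset_size=10_000)
        assert coefs.shape == (1, 4)
        direct = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        assert np.allclose(coefs[0], direct, atol=1e-6)

    def test_subset_count_is_ceiling_division(self):
        X, y = simulate_logistic(25_000, self.beta, seed=6)
        coefs = fit_subsets(X, y, subset_size=10_000)
        assert coefs.shape[0] == 3

    def test_each_subset_recovers_generating_coefficients(self):
        X, y = simulate_logistic(200_000, self.beta, seed=7)
        coefs = fit_subsets(X, y, subset_size=50_000)
        assert coefs.shape[0] == 4
        for s in range(4):
            sl = slice(s * 50_000, (s + 1) * 50_000)
            se = sm.GLM(y[sl], X[sl], family=sm.families.Binomial()).fit().bse
            assert (np.abs(coefs[s] - self.beta) < 3 * se).all()

    def test_single_class_subset_skipped_with_warning(self):
        X, y = simulate_logistic(2_000, self.beta, seed=8)
        y[:1000] = 0.0  # first subset has one class only
        with pytest.warns(UserWarning, match="single response class"):
            coefs = fit_subsets(X, y, subset_size=1_000)
        assert coefs.shape[0] == 1

    def test_all_subsets_failing_is_an_error(self):
        X = np.ones((100, 2))
        y = np.zeros(100)
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_subsets(X, y, subset_size=50)

    def test_constant_column_dropped_per_subset(self):
        X, y = simulate_logistic(4_000, self.beta, seed=9)
        X = np.column_stack([X, np.zeros(4_000)])  # globally constant extra column
        X[:2_000, -1] = np.where(np.arange(2_000) % 2 == 0, 1.0, 0.0)
        coefs = fit_subsets(X, y, subset_size=2_000)
        assert np.isfinite(coefs[0, -1])
        assert np.isnan(coefs[1, -1])  # absent from the second subset's vector


class TestMedianCoefficients:
    def test_median_of_one_is_identity(self):
        v = np.array([[1.0, -2.0, 3.0]])
        assert np.array_equal(median_coefficients(v), v[0])

    def test_odd_and_even_counts(self):
        assert median_coefficients(np.array([[1.0], [2.0], [9.0]]))[0] == 2.0
        assert median_coefficients(np.array([[1.0], [2.0], [3.0], [10.0]]))[0] == 2.5

    def test_nan_entries_are_absent_not_zero(self):
        m = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        assert np.array_equal(median_coefficients(m), [3.0, 5.0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            median_coefficients(np.empty((0, 3)))


class TestPredictAndPhred:
    def test_zero_linear_predictor_gives_half(self):
        assert predict_error_probability(np.zeros(3), np.zeros((1, 3)))[0] == 0.5

    def test_intercept_only_model_is_constant(self):
        beta = np.array([logit(0.001), 0.0, 0.0])
        X = np.random.default_rng(0).normal(size=(20, 3))
        X[:, 0] = 1.0
        assert np.allclose(predict_error_probability(beta, X), 0.001)

    @given(st.lists(st.floats(-3, 3), min_size=4, max_size=4),
           st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_matches_hand_rolled_inverse_logit(self, beta, x):
        beta, x = np.array(beta), np.array(x)
        p = predict_error_probability(beta, x[None, :])[0]
        eta = sum(b * v for b, v in zip(beta, x))
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-eta)), abs=1e-12)

    @pytest.mark.parametrize("p,q", [(0.001, 30), (0.5, 3), (1.0, 0), (1e-12, 60)])
    def test_phred_transform_examples(self, p, q):
        assert probability_to_phred(p) == q

    def test_phred_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            probability_to_phred(0.0)
        with pytest.raises(ValueError):
            probability_to_phred(-0.1)

    @given(st.floats(1e-30, 1.0))
    @settings(deadline=None, max_examples=100)
    def test_phred_is_integer_in_range_and_monotone(self, p):
        q = probability_to_phred(p)
        assert isinstance(q, int) and 0 <= q <= 60
        assert probability_to_phred(min(1.0, p * 2)) <= q


class TestModelResults:
    def test_median_of_subsets_close_to_full_fit(self, training_small):
        """With identically distributed subsets the median-of-subsets estimate
        agrees with a single full-data fit to within 2 standard errors."""
        tr = training_small.training
        model = bq.BaseQualityModel(tr, subset_size=len(tr) // 3 + 1)
        res = model.fit()
        assert len(res.subset_params) == 3
        full = sm.GLM(
            model.endog, model.exog, family=sm.families.Binomial()
        ).fit()
        assert (np.abs(res.params.to_numpy() - full.params) < 2 * full.bse).all()

    def test_summary_mentions_flagged_positions_and_coefficients(self, fitted_small):
        text = fitted_small.summary()
        assert "flagged read positions" in text
        assert "qual" in text and "intercept" in text

    def test_json_roundtrip_preserves_predictions(self, fitted_small, tmp_path):
        path = tmp_path / "model.json"
        fitted_small.save(path)
        loaded = bq.BaseQualityResults.load(path)
        quals = np.array([30, 2, 40, 0, 17])
        seq = "ACGTN"
        assert np.array_equal(
            loaded.recalibrate_read(quals, seq),
            fitted_small.recalibrate_read(quals, seq),
        )
        pd.testing.assert_series_equal(loaded.params, fitted_small.params)

    def test_recalibrate_read_consistent_with_table(self, fitted_small):
        quals = np.array([40, 30, 20, 10, 5])
        seq = "ACGTA"
        from_read = fitted_small.recalibrate_read(quals, seq)
        table = pd.DataFrame(
            {
                "qual": quals,
                "read_mean_qual": quals.mean(),
                "read_pos": np.arange(1, 6),
                "base": list(seq),
            }
        )
        assert np.array_equal(from_read, fitted_small.recalibrate_table(table))
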