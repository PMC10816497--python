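"""Design matrices, OLS fitting, prediction and correlation evaluation."""

import numpy as np
import pandas as pd
import pytest

from peakmotifs import (
    MotifPresenceTransformer,
    PeakScoreRegression,
    build_design,
    evaluate_correlation,
    fit_peak_score_model,
    generate_scores,
)


class TestDesignMatrix:
    def test_presence_row_and_prediction_identity(self):
        # sequence containing only the 1st and 3rd motif -> row (1, 0, 1),
        # predicted y = B0 + B1 + B3
        seqs = ["AAAAGCGAGA"]  # contains AAAA and GAGA but no CCCC on either strand
        X = build_design(seqs, ["AAAA", "CCCC", "GAGA"])
        assert X.iloc[0].tolist() == [1.0, 0.0, 1.0]
        fit = PeakScoreRegression()
        fit.intercept_, fit.coef_ = 1.0, np.array([2.0, 4.0, 8.0])
        fit.feature_names_ = list(X.columns)
        assert fit.predict(X)[0] == pytest.approx(1.0 + 2.0 + 8.0)

    def test_motif_free_sequence_gives_zero_row(self):
        X = build_design(["TTTT"], ["AAAA"], both_strands=False)
        assert X.iloc[0].tolist() == [0.0]

    def test_count_mode_counts_planted_occurrences(self):
        # AAAA planted twice (disjoint), AAAAA contributes overlapping windows
        X = build_design(["AAAACCAAAA"], ["AAAA"], mode="count", both_strands=False)
        assert X.iloc[0, 0] == 2.0

    def test_presence_and_count_coincide_for_single_occurrences(self):
        # single occurrences, non-palindromic motifs (a palindrome's one
        # occurrence legitimately counts once per strand)
        seqs = ["AACGGCTTTTT", "TTGCACCCCCA", "CCCGTATATTA"]
        motifs = ["AACGG", "TTGCA"]
        Xp = build_design(seqs, motifs, mode="presence")
        Xc = build_design(seqs, motifs, mode="count")
        assert (Xc.to_numpy() <= 1).all()
        assert Xp.equals(Xc)

    def test_transformer_sklearn_contract(self):
        tr = MotifPresenceTransformer(["AAA"], mode="presence")
        assert tr.get_params()["mode"] == "presence"
        out = tr.fit().transform(["AAAT"])
        assert out.shape == (1, 1)
        assert list(tr.get_feature_names_out()) == ["AAA"]


class TestOLS:
    def test_exact_linear_data_recovered(self):
        X = pd.DataFrame({"m": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]})
        y = 2.0 + 3.0 * X["m"].to_numpy()
        fit = PeakScoreRegression().fit(X, y)
        assert fit.intercept_ == pytest.approx(2.0, abs=1e-10)
        assert fit.coef_[0] == pytest.approx(3.0, abs=1e-10)
        assert fit.resid_var_ == pytest.approx(0.0, abs=1e-18)

    def test_duplicate_column_dropped_fit_unchanged(self, rng):
        x = rng.integers(0, 2, size=40).astype(float)
        z = rng.integers(0, 2, size=40).astype(float)
        y = 1.0 + 2.0 * x - z + rng.normal(0, 0.1, 40)
        X1 = pd.DataFrame({"a": x, "b": z})
        X2 = pd.DataFrame({"a": x, "b": z, "a_copy": x})
        f1 = PeakScoreRegression().fit(X1, y)
        with pytest.warns(UserWarning, match="duplicate"):
            f2 = PeakScoreRegression().fit(X2, y)
        assert f2.dropped_ == ["a_copy"]
        assert np.allclose(f1.coef_, f2.coef_)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.integers(0, 2, 30).astype(float), "c": np.ones(30)})
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="constant"):
            fit = PeakScoreRegression().fit(X, y)
        assert fit.dropped_ == ["c"]

    def test_underdetermined_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="N > p"):
            PeakScoreRegression().fit(X, np.arange(3.0))

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(ValueError, match="nonpositive peak score"):
            fit_peak_score_model(["AAAA", "CCCC", "GGGG", "TTTT"], [1.0, -2.0, 3.0, 4.0], ["AA"])

    def test_residuals_orthogonal_to_design(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, size=(60, 3)).astype(float), columns=list("abc"))
        y = 1 + X.to_numpy() @ [0.5, -0.2, 0.1] + rng.normal(0, 0.3, 60)
        fit = PeakScoreRegression().fit(X, y)
        resid = y - fit.predict(X)
        for c in fit.feature_names_:
            assert abs(resid @ X[c].to_numpy()) < 1e-8

    def test_training_mean_prediction_matches_mean_response(self, rng):
        X = pd.DataFrame({"a": rng.integers(0, 2, 50).astype(float)})
        y = 2 + X["a"].to_numpy() + rng.normal(0, 0.5, 50)
        fit = PeakScoreRegression().fit(X, y)
        assert fit.predict(X).mean() == pytest.approx(y.mean(), abs=1e-10)

    def test_training_r2_equals_model_rsquared(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, size=(80, 4)).astype(float))
        y = 1 + X.to_numpy() @ [0.4, 0.0, -0.3, 0.2] + rng.normal(0, 0.4, 80)
        fit = PeakScoreRegression().fit(X, y)
        r = evaluate_correlation(y, fit.predict(X)).r
        assert r**2 == pytest.approx(fit.rsquared_, abs=1e-8)

    def test_pure_noise_column_never_decreases_training_r(self, rng):
        X = pd.DataFrame({"a": rng.integers(0, 2, 100).astype(float)})
        y = 1 + 0.8 * X["a"].to_numpy() + rng.normal(0, 0.5, 100)
        r1 = evaluate_correlation(y, PeakScoreRegression().fit(X, y).predict(X)).r
        X2 = X.assign(noise=rng.integers(0, 2, 100).astype(float))
        f2 = PeakScoreRegression().fit(X2, y)
        r2 = evaluate_correlation(y, f2.predict(X2)).r
        assert r2 >= r1 - 1e-12

    def test_predict_missing_column_rejected(self, rng):
        X = pd.DataFrame({"a": rng.integers(0, 2, 30).astype(float)})
        fit = PeakScoreRegression().fit(X, rng.normal(size=30))
        with pytest.raises(ValueError, match="missing fitted columns"):
            fit.predict(pd.DataFrame({"b": [1.0]}))


class TestInference:
    def test_significant_coefficients_alpha_one_returns_all(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, size=(40, 3)).astype(float), columns=list("abc"))
        fit = PeakScoreRegression().fit(X, rng.normal(size=40))
        assert len(fit.significant_coefficients(alpha=1.0)) == 3

    def test_planted_strong_effect_detected(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, size=(200, 5)).astype(float))
        X.columns = [f"m{i}" for i in range(5)]
        y = 1 + 1.5 * X["m2"].to_numpy() + rng.normal(0, 0.5, 200)
        fit = PeakScoreRegression().fit(X, y)
        assert "m2" in fit.significant_coefficients(0.05)["motif"].tolist()

    def test_coefficient_recovery_from_generated_scores(self, rng):
        # noiseless scores regenerate the betas exactly
        presence = pd.DataFrame(rng.integers(0, 2, size=(50, 3)).astype(float),
                                columns=["AAA", "CCC", "GGG"])
        betas = [2.0, 0.5, -0.3, 0.8]
        scores = generate_scores(presence, betas, 0.0, rng)
        fit = PeakScoreRegression().fit(presence, np.log(scores))
        assert fit.intercept_ == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(fit.coef_, betas[1:], atol=1e-8)


class TestCorrelation:
    def test_perfect_and_anti_correlation(self, rng):
        y = rng.normal(size=20)
        assert evaluate_correlation(y, y).r == pytest.approx(1.0)
        assert evaluate_correlation(y, -y).r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_bonferroni_over_evaluation_sets(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(0, 2.5, 30)
        res1 = evaluate_correlation(y, yhat, n_tests=1)
        res50 = evaluate_correlation(y, yhat, n_tests=50)
        assert res1.r == res50.r and res1.p_value == res50.p_value
        if 0.001 < res1.p_value < 0.05:
            assert res1.significant and not res50.significant

    def test_holdout_prediction_significant_at_spec_scale(self, rng):
        # held-out control set generated from the same betas
        m = 5
        betas = np.array([2.0, 0.4, 0.3, -0.3, 0.25, -0.2])
        Xtr = pd.DataFrame(rng.integers(0, 2, size=(1000, m)).astype(float))
        Xct = pd.DataFrame(rng.integers(0, 2, size=(1000, m)).astype(float))
        Xtr.columns = Xct.columns = [f"m{i}" for i in range(m)]
        ytr = betas[0] + Xtr.to_numpy() @ betas[1:] + rng.normal(0, 0.5, 1000)
        yct = betas[0] + Xct.to_numpy() @ betas[1:] + rng.normal(0, 0.5, 1000)
        fit = PeakScoreRegression().fit(Xtr, ytr)
        res = evaluate_correlation(yct, fit.predict(Xct), n_tests=2)
        assert res.r > 0 and res.significant
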