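"""Printed prediction equations and the coefficient-weighting transform."""

import warnings

import numpy as np
import pytest

import scolioscreen as sc
from scolioscreen.model import SCHEMES
from scolioscreen.variables import MODEL_VARIABLES
from scolioscreen.weighting import odds_ratio_to_auc, scheme_weights


class TestPrintedEquations:
    def test_equation_1_coefficients(self):
        m = sc.printed_equation(1)
        assert m.intercept == -7.124
        coefs = m.coefficients()
        assert coefs["gender"] == 0.705
        assert coefs["atr_lumbar"] == 1.471
        assert m.scheme == "plain" and m.provenance == "printed_equation"
        assert m.encoding == "single_score"

    def test_shared_intercepts_and_schemes(self):
        assert sc.printed_equation(2).intercept == sc.printed_equation(4).intercept == -3.648
        assert sc.printed_equation(3).coefficients()["atr_thoracolumbar"] == 1.420
        assert [sc.printed_equation(k).scheme for k in (1, 2, 3, 4)] == list(SCHEMES)

    def test_invalid_equation_number(self):
        with pytest.raises(ValueError):
            sc.printed_equation(5)

    def test_zero_covariates_probability(self):
        """At the all-zero covariate vector the plain equation's response is
        the logistic of its intercept, about 8.0e-4."""
        p = sc.predict_probability(sc.printed_equation(1), np.zeros(12))
        assert p == pytest.approx(1 / (1 + np.exp(7.124)), abs=1e-12)
        assert p == pytest.approx(8.0e-4, abs=1e-5)

    def test_probability_monotone_in_lumbar_rotation(self):
        m = sc.printed_equation(1)
        x = np.tile(np.array([1.0, 13.0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0]), (3, 1))
        x[:, 11] = [0, 1, 2]
        p = sc.predict_probability(m, x)
        assert p[0] < p[1] < p[2]
        assert ((0 < p) & (p < 1)).all()

    def test_json_round_trip(self, tmp_path):
        m = sc.printed_equation(3)
        path = tmp_path / "eq3.json"
        m.to_json(path)
        back = sc.PredictionModel.from_json(path)
        assert back.intercept == m.intercept
        assert np.array_equal(back.coef, m.coef)
        assert back.scheme == m.scheme


class TestClassify:
    def test_boundary_and_extremes(self):
        assert sc.classify(0.5) == 1  # ties classify positive
        assert sc.classify(0.0) == 0 and sc.classify(1.0) == 1

    def test_invalid_threshold(self):
        for t in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sc.classify(0.5, threshold=t)

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        counts = [sc.classify(p, t).sum() for t in np.linspace(0.01, 0.99, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.fixture(scope="module")
def fitted_pair():
    cohort = sc.generate_cohort(sc.default_spec(seed=29))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plain = sc.fit_multivariate(cohort, encoding="single_score")
    return cohort, plain


class TestApplyWeighting:
    def test_uniform_weights_identity(self, fitted_pair):
        cohort, plain = fitted_pair
        w = {v: 1.0 for v in MODEL_VARIABLES}
        out = sc.apply_weighting(plain, w, "auc_weighted", cohort)
        assert np.allclose(out.coef, plain.coef)
        # ML intercept already balances mean prediction, so recalibration
        # reproduces it
        assert out.intercept == pytest.approx(plain.intercept, abs=1e-6)

    def test_raw_weight_scale_invariance(self, fitted_pair):
        cohort, plain = fitted_pair
        w = {v: float(i + 1) for i, v in enumerate(MODEL_VARIABLES)}
        doubled = {v: 2 * x for v, x in w.items()}
        a = sc.apply_weighting(plain, w, "aor_weighted", cohort)
        b = sc.apply_weighting(plain, doubled, "aor_weighted", cohort)
        assert np.allclose(a.coef, b.coef)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-9)

    def test_missing_and_nonpositive_weights_rejected(self, fitted_pair):
        cohort, plain = fitted_pair
        with pytest.raises(KeyError):
            sc.apply_weighting(plain, {"gender": 1.0}, "aor_weighted", cohort)
        bad = {v: 1.0 for v in MODEL_VARIABLES}
        bad["age"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            sc.apply_weighting(plain, bad, "aor_weighted", cohort)

    def test_mean_prediction_preserved(self, fitted_pair):
        cohort, plain = fitted_pair
        w = {v: float(i + 1) for i, v in enumerate(MODEL_VARIABLES)}
        out = sc.apply_weighting(plain, w, "aor_auc_weighted", cohort)
        p = sc.predict_probability(out, cohort)
        assert np.mean(p) == pytest.approx(cohort["ais"].mean(), abs=1e-9)

    def test_nonuniform_weights_change_ranking(self):
        """A two-variable construction where weighting reorders subjects."""
        terms = sc.model.encoding_terms("single_score")
        coef = np.zeros(12)
        coef[0], coef[2] = 1.0, 1.0  # gender and shoulder equally weighted
        m = sc.PredictionModel(0.0, terms, coef, "single_score")
        a = np.zeros(12)
        a[0] = 1.0  # girl, normal shoulder
        b = np.zeros(12)
        b[2] = 2.0  # boy, right shoulder
        assert sc.predict_probability(m, a[None])[0] < sc.predict_probability(m, b[None])[0]
        heavy_gender = m.coef * np.array([3.0, *(1.0,) * 11])
        m2 = sc.PredictionModel(0.0, terms, heavy_gender, "single_score")
        assert sc.predict_probability(m2, a[None])[0] > sc.predict_probability(m2, b[None])[0]


class TestWeightVectors:
    def test_odds_ratio_to_auc_scale(self):
        assert odds_ratio_to_auc(1.0) == pytest.approx(0.5)
        assert odds_ratio_to_auc(5.0) > odds_ratio_to_auc(2.0) > 0.5
        assert 0 < odds_ratio_to_auc(0.2) < 0.5
        with pytest.raises(ValueError):
            odds_ratio_to_auc(0.0)

    def test_scheme_weights_cover_all_variables(self, fitted_pair):
        cohort, _ = fitted_pair
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dummy = sc.fit_multivariate(cohort, encoding="dummy_expanded")
        w_aor = sc.aor_weights(dummy, cohort)
        w_auc = sc.auc_weights(cohort)
        for scheme in ("aor_weighted", "auc_weighted", "aor_auc_weighted"):
            w = scheme_weights(scheme, w_aor, w_auc)
            assert set(w) == set(MODEL_VARIABLES)
            assert all(x > 0 for x in w.values())
        norm = sc.normalize_weights(scheme_weights("aor_auc_weighted", w_aor, w_auc))
        assert np.mean(list(norm.values())) == pytest.approx(1.0)
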