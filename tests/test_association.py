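"""Odds ratios and logistic fits: published values, oracles, recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import scolioscreen as sc
from scolioscreen.association import SEPARATION_BOUND, Z95


@pytest.mark.parametrize(
    "variable,level,expected",
    [
        ("gender", "girl", 3.26),
        ("shoulder_height_diff", "left", 6.56),
        ("shoulder_height_diff", "right", 9.81),
        # the published table prints 11.71 for scapular-left; the counts
        # give 11.7048, which rounds to 11.70
        ("scapular_tilt", "left", 11.70),
        ("scapular_tilt", "right", 16.55),
        ("lumbar_concave", "left", 10.56),
        ("pelvic_tilt", "right", 12.60),
        ("atr_thoracic", "right_gt5", 14.41),
        ("atr_thoracolumbar", "left_gt5", 5.11),
        ("atr_lumbar", "left_gt5", 7.25),
        ("atr_lumbar", "right_gt5", 8.52),
    ],
)
def test_published_univariate_ors(variable, level, expected):
    e = sc.univariate_or(sc.table1_contingency(variable), level)
    assert round(e.estimate, 2) == expected
    assert not e.corrected


def test_girls_or_wald_ci():
    e = sc.univariate_or(sc.table1_contingency("gender"), "girl")
    assert (round(e.ci_low, 2), round(e.ci_high, 2)) == (2.69, 3.96)
    assert e.p_value < 0.001


def test_balanced_table_or_one_symmetric_ci():
    table = sc.ContingencyTable("x", ("a", "b"), np.array([[25, 25], [25, 25]]))
    e = sc.univariate_or(table, "b")
    assert e.estimate == pytest.approx(1.0)
    assert np.log(e.ci_low) == pytest.approx(-np.log(e.ci_high))


def test_zero_cell_haldane_correction():
    table = sc.ContingencyTable("x", ("a", "b"), np.array([[40, 35], [0, 12]]))
    e = sc.univariate_or(table, "b")
    assert e.corrected
    assert np.isfinite(e.estimate) and e.estimate > 1


def test_reference_level_rejected(gender_table):
    with pytest.raises(ValueError, match="reference"):
        sc.univariate_or(gender_table, "boy")


@pytest.mark.parametrize("variable", ["gender", "scapular_tilt", "atr_lumbar"])
def test_or_equals_exp_slope_of_logistic_fit(variable):
    """Closed-form OR agrees with exp(slope) of a one-predictor logistic
    fit on the expanded records (two independent code paths)."""
    table = sc.table1_contingency(variable)
    for i, level in enumerate(table.levels[1:], start=1):
        closed = sc.univariate_or(table, level).estimate
        n_ref, n_lvl = table.counts[0], table.counts[i]
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [n_ref[0], n_ref[1], n_lvl[0], n_lvl[1]])
        y = np.repeat([0.0, 1.0, 0.0, 1.0], [n_ref[0], n_ref[1], n_lvl[0], n_lvl[1]])
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert closed == pytest.approx(float(np.exp(fit.params[1])), rel=1e-6)


class TestContinuousOr:
    @staticmethod
    def _frame(x, y):
        return pd.DataFrame({"age": x, "ais": y})

    def test_null_predictor_estimate_near_one(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(100):
            x = rng.normal(13, 2, size=600)
            y = rng.integers(0, 2, size=600)
            e = sc.univariate_or_continuous(self._frame(x, y), "age")
            covered += e.ci_low <= 1.0 <= e.ci_high
        assert covered >= 88  # nominal 95 of 100

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            sc.univariate_or_continuous(self._frame([1.0, 2.0, 3.0], [1, 1, 1]), "age")

    def test_recovers_published_per_year_effect(self):
        """Data generated with true per-year log-odds ln(1.14) at n=1779
        yields an estimate whose own CI covers the truth in >=90% of runs."""
        rng = np.random.default_rng(7)
        beta = np.log(1.14)
        hits = 0
        for _ in range(50):
            x = rng.normal(13, 2, size=1779)
            p = 1 / (1 + np.exp(-(-13 * beta + beta * x)))
            y = rng.random(1779) < p
            e = sc.univariate_or_continuous(self._frame(x, y.astype(int)), "age")
            hits += e.ci_low <= 1.14 <= e.ci_high
        assert hits >= 45


class TestMultivariate:
    def test_single_binary_predictor_matches_closed_form(self):
        """With one informative predictor the multivariate AOR reduces to
        the closed-form univariate OR."""
        rng = np.random.default_rng(1)
        cohort = sc.generate_cohort(sc.default_spec(seed=1))
        # collapse every other predictor to a constant
        flat = cohort.copy()
        for name in sc.variables.MODEL_VARIABLES:
            if name in ("gender", "age"):
                continue
            flat[name] = sc.variables.VARIABLES[name].reference
        flat["age"] = 13.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sc.fit_multivariate(flat, encoding="dummy_expanded")
        aor = dict(
            (e.variable, e.estimate) for e in sc.multivariate_effects(model)
        )["gender"]
        closed = sc.univariate_or(sc.tabulate(flat, "gender"), "girl").estimate
        assert aor == pytest.approx(closed, rel=1e-6)

    def test_two_predictor_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 5000
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        eta = -0.2 + 0.7 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = sm.GLM(
            y, sm.add_constant(np.column_stack([x1, x2])),
            family=sm.families.Binomial(),
        ).fit()
        assert abs(fit.params[1] - 0.7) <= 3 * fit.bse[1]
        assert abs(fit.params[2] + 0.5) <= 3 * fit.bse[2]

    def test_loglik_beats_coarse_grid(self):
        """On a 20-record toy problem the IRLS optimum dominates every
        point of a brute-force grid over (intercept, slope)."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-x))).astype(float)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        best = loglik(fit.params[0], fit.params[1])
        grid = np.linspace(-3, 3, 31)
        assert all(best >= loglik(b0, b1) - 1e-9 for b0 in grid for b1 in grid)

    def test_mean_fitted_probability_equals_case_fraction(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sc.fit_multivariate(default_cohort, encoding="single_score")
        p = sc.predict_probability(model, default_cohort)
        assert np.mean(p) == pytest.approx(default_cohort["ais"].mean(), abs=1e-6)

    def test_rank_deficiency_raises(self, default_cohort):
        dup = default_cohort.copy()
        dup["scapular_tilt"] = dup["shoulder_height_diff"]  # perfectly collinear
        with pytest.raises(np.linalg.LinAlgError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.fit_multivariate(dup, encoding="dummy_expanded")

    def test_small_sample_warns(self, default_cohort):
        with pytest.warns(UserWarning, match="20 per parameter"):
            sc.fit_multivariate(default_cohort.iloc[::12], encoding="dummy_expanded")

    def test_separation_reported_not_raised(self, default_cohort):
        sep = default_cohort.copy()
        # make flat back perfectly predict case status
        sep["flat_back"] = np.where(sep["ais"] == 1, "abnormal", "normal")
        with pytest.warns(sc.SeparationWarning):
            model = sc.fit_multivariate(sep, encoding="single_score")
        assert "flat_back" in model.separation
        assert abs(dict(zip(model.terms, model.coef))["flat_back"]) > SEPARATION_BOUND
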