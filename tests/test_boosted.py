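"""Boosted-tree estimator: tuning, training, SHAP values, S-ORs."""

import itertools
from math import comb, factorial

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from interactsim import (
    BoostParams,
    SCENARIOS,
    ShapMatrix,
    compute_shap,
    fit_binary_design,
    generate_cohort,
    shap_based_ors,
    train_boosted,
    tune_hyperparameters,
)
from interactsim.boosted import cv_log_loss, _dmatrix
from interactsim.cohort import calibrated_model

from conftest import make_cohort, tiny_model

COLUMNS = tuple(calibrated_model("small").names)


def random_cohort(rng, n=400, p_y=0.5, columns=COLUMNS):
    x = rng.integers(0, 2, size=(n, len(columns)))
    y = rng.integers(0, 2, size=n) if p_y == 0.5 else (rng.random(n) < p_y)
    return make_cohort(columns, x, y.astype(int))


class TestBoostParams:
    @pytest.mark.parametrize(
        "kwargs", [{"n_estimators": 0}, {"max_depth": 0},
                   {"min_child_weight": 0.0}, {"learning_rate": 1.5}]
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BoostParams(**kwargs)


class TestTuning:
    def test_single_point_grid_is_returned(self, rng):
        cohort = random_cohort(rng)
        only = BoostParams(50, 2, 1)
        assert tune_hyperparameters(cohort, (only,), seed=1) == only

    def test_exact_ties_prefer_the_simplest_model(self, rng):
        """With constant features no tree can split, so every depth and
        child-weight setting yields the identical model; the tie-break
        must pick the smallest depth, then child weight."""
        n = 200
        cohort = make_cohort(
            ("diet", "woman"), np.zeros((n, 2), dtype=int),
            rng.integers(0, 2, size=n),
        )
        grid = tuple(
            BoostParams(20, md, mcw)
            for md, mcw in itertools.product((4, 3, 2), (10.0, 1.0))
        )
        best = tune_hyperparameters(cohort, grid, seed=3)
        assert (best.max_depth, best.min_child_weight) == (2, 1.0)

    def test_supergrid_optimum_is_no_worse_than_subgrid(self, rng):
        cohort = random_cohort(rng, n=600, p_y=0.4)
        sub = (BoostParams(20, 2, 5), BoostParams(40, 3, 1))
        sup = sub + (BoostParams(20, 4, 1), BoostParams(60, 2, 10))
        loss = lambda g: cv_log_loss(
            cohort, tune_hyperparameters(cohort, g, seed=5), seed=5
        )
        assert loss(sup) <= loss(sub) + 1e-12

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(random_cohort(rng), ())


class TestTraining:
    def test_deterministic_under_seed(self, rng):
        cohort = random_cohort(rng)
        m1 = train_boosted(cohort, BoostParams(30, 3, 1), seed=9)
        m2 = train_boosted(cohort, BoostParams(30, 3, 1), seed=9)
        d = _dmatrix(cohort.x, cohort.columns)
        np.testing.assert_array_equal(
            m1.predict(d, output_margin=True), m2.predict(d, output_margin=True)
        )

    def test_single_class_cohort_rejected(self):
        cohort = make_cohort(("diet", "woman"), np.eye(4, 2, dtype=int),
                             np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="single class"):
            train_boosted(cohort, BoostParams())

    def test_null_cohort_predicts_the_base_rate(self, rng):
        cohort = random_cohort(rng, n=5000, p_y=0.3)
        booster = train_boosted(cohort, BoostParams(50, 2, 5), seed=1)
        pred = booster.predict(_dmatrix(cohort.x, cohort.columns))
        assert abs(pred.mean() - cohort.y.mean()) < 0.01

    def test_beats_diet_only_discrimination_on_an_interaction_cohort(self):
        model = calibrated_model("moderate")
        cohort = generate_cohort(model, SCENARIOS["moderate"], n=20_000, seed=8)
        booster = train_boosted(cohort, BoostParams(), seed=8)
        margin = booster.predict(_dmatrix(cohort.x, cohort.columns),
                                 output_margin=True)
        auc = roc_auc_score(cohort.y, margin)
        diet_fit = fit_binary_design(cohort.y, cohort.x[:, :1], ["diet"])
        diet_auc = roc_auc_score(
            cohort.y, cohort.x[:, 0] * diet_fit.params["diet"]
        )
        assert 0.5 < auc < 1.0
        assert auc > diet_auc


class TestShapValues:
    def test_stump_matches_exhaustive_shapley_enumeration(self, rng):
        """A single depth-1 tree splitting on diet: the exact Shapley value
        over all feature coalitions (with the tree's cover-weighted
        expectation as the value function) equals the computed attribution,
        and all other features get exactly zero."""
        n = 2000
        x = rng.integers(0, 2, size=(n, len(COLUMNS)))
        y = np.where(rng.random(n) < 0.05, 1 - x[:, 0], x[:, 0])
        cohort = make_cohort(COLUMNS, x, y)
        booster = train_boosted(cohort, BoostParams(1, 1, 1, 0.7), seed=0)
        tree = booster.trees_to_dataframe()
        split_rows = tree[tree.Feature != "Leaf"]
        assert list(split_rows.Feature) == ["diet"], "stump must split on diet"
        leaves = tree[tree.Feature == "Leaf"].set_index("ID")
        yes_id, no_id, split = (split_rows.Yes.iloc[0], split_rows.No.iloc[0],
                                split_rows.Split.iloc[0])
        v_yes, c_yes = leaves.loc[yes_id, ["Gain", "Cover"]]
        v_no, c_no = leaves.loc[no_id, ["Gain", "Cover"]]
        expected_leaf = (c_yes * v_yes + c_no * v_no) / (c_yes + c_no)

        shap = compute_shap(booster, cohort)
        margins = booster.predict(_dmatrix(cohort.x, cohort.columns),
                                  output_margin=True)
        for i in (0, 1, 7):
            leaf_i = v_yes if x[i, 0] < split else v_no
            base_margin = margins[i] - leaf_i  # the model's constant offset
            # Shapley value of `diet` by enumeration over coalitions S of the
            # other 10 features: v(S + diet) - v(S) is leaf(x) - E[leaf] for
            # every S, weighted by |S|!(p-|S|-1)!/p!
            p = len(COLUMNS)
            phi_diet = sum(
                comb(p - 1, s) * factorial(s) * factorial(p - 1 - s)
                / factorial(p) * (leaf_i - expected_leaf)
                for s in range(p)
            )
            assert shap.values[i, 0] == pytest.approx(phi_diet, abs=1e-5)
            np.testing.assert_allclose(shap.values[i, 1:], 0.0, atol=1e-6)
            assert shap.base_value == pytest.approx(
                base_margin + expected_leaf, abs=1e-5
            )

    def test_constant_model_gives_all_zero_attributions(self, rng):
        n = 300
        cohort = make_cohort(("diet", "woman"), np.zeros((n, 2), dtype=int),
                             rng.integers(0, 2, size=n))
        booster = train_boosted(cohort, BoostParams(10, 2, 1), seed=0)
        shap = compute_shap(booster, cohort)
        np.testing.assert_allclose(shap.values, 0.0, atol=1e-6)
        margin = booster.predict(_dmatrix(cohort.x, cohort.columns),
                                 output_margin=True)
        assert shap.base_value == pytest.approx(float(margin[0]), abs=1e-5)

    def test_local_accuracy_on_a_fitted_interaction_model(self):
        model = calibrated_model("large")
        cohort = generate_cohort(model, SCENARIOS["large"], n=10_000, seed=5)
        shap = compute_shap(train_boosted(cohort, BoostParams(), seed=5), cohort)
        assert shap.max_residual < 1e-4

    def test_schema_mismatch_rejected(self, rng):
        cohort = random_cohort(rng)
        booster = train_boosted(cohort, BoostParams(5, 2, 1), seed=0)
        renamed = make_cohort([c.upper() for c in COLUMNS], cohort.x, cohort.y)
        with pytest.raises(ValueError, match="schema"):
            compute_shap(booster, renamed)


def cell_cohort(n_per_cell=5):
    """One cohort with n_per_cell individuals in each diet-by-sex cell."""
    cells = list(itertools.product((0, 1), (0, 1)))
    x = np.array([[d, w] for d, w in cells for _ in range(n_per_cell)])
    return make_cohort(("diet", "woman"), x, np.zeros(len(x), dtype=int))


class TestShapORs:
    def test_zero_attributions_give_unit_odds_ratios(self):
        cohort = cell_cohort()
        shap = ShapMatrix(np.zeros((cohort.n, 2)), 0.0, ("diet", "woman"))
        ors = shap_based_ors(shap, cohort)
        assert (ors.or_m_hat, ors.or_w_hat) == (1.0, 1.0)

    def test_cell_mean_difference_is_exponentiated(self):
        cohort = cell_cohort()
        phi = np.where(cohort.diet == 1, -0.2, 0.1)
        shap = ShapMatrix(np.column_stack([phi, np.zeros_like(phi)]), 0.0,
                          ("diet", "woman"))
        ors = shap_based_ors(shap, cohort)
        assert ors.or_m_hat == pytest.approx(np.exp(-0.3))
        assert ors.or_w_hat == pytest.approx(np.exp(-0.3))

    def test_empty_cell_error_names_the_cell(self):
        x = np.array([[0, 0], [1, 0], [0, 1]])  # no diet=1, woman=1
        cohort = make_cohort(("diet", "woman"), x, np.zeros(3, dtype=int))
        shap = ShapMatrix(np.zeros((3, 2)), 0.0, ("diet", "woman"))
        with pytest.raises(ValueError, match="diet=1,woman=1"):
            shap_based_ors(shap, cohort)

    def test_relabeling_the_sexes_swaps_the_stratum_ors(self, rng):
        n = 200
        x = np.column_stack([rng.integers(0, 2, n), rng.integers(0, 2, n)])
        x[:3] = [[0, 0], [1, 1], [0, 1]]  # ensure every cell is populated
        x[3] = [1, 0]
        cohort = make_cohort(("diet", "woman"), x, np.zeros(n, dtype=int))
        flipped = make_cohort(("diet", "woman"),
                              np.column_stack([x[:, 0], 1 - x[:, 1]]),
                              cohort.y)
        phi = rng.normal(size=(n, 2))
        shap = ShapMatrix(phi, 0.0, ("diet", "woman"))
        a, b = shap_based_ors(shap, cohort), shap_based_ors(shap, flipped)
        assert a.or_m_hat == pytest.approx(b.or_w_hat)
        assert a.or_w_hat == pytest.approx(b.or_m_hat)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_the_defining_cell_mean_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = np.column_stack([rng.integers(0, 2, n), rng.integers(0, 2, n)])
        x[:4] = list(itertools.product((0, 1), (0, 1)))
        phi = rng.normal(scale=0.5, size=(n, 2))
        cohort = make_cohort(("diet", "woman"), x, np.zeros(n, dtype=int))
        ors = shap_based_ors(ShapMatrix(phi, 0.0, ("diet", "woman")), cohort)
        d, w, f = x[:, 0], x[:, 1], phi[:, 0]
        for sex, got in ((0, ors.or_m_hat), (1, ors.or_w_hat)):
            expect = np.exp(f[(d == 1) & (w == sex)].mean()
                            - f[(d == 0) & (w == sex)].mean())
            assert got == pytest.approx(expect, rel=1e-12)

    def test_null_generating_mechanism_centers_log_or_at_zero(self):
        """With a zero diet effect in the data-generating model, the
        distribution of ln(S-OR) across replications is centered at 0."""
        model = tiny_model(diet_prev=0.25, intercept=-0.16)
        scenario = SCENARIOS["null"]
        logs = []
        for rep in range(100):
            cohort = generate_cohort(model, scenario, n=10_000, seed=3000 + rep)
            booster = train_boosted(cohort, BoostParams(50, 2, 5), seed=rep)
            ors = shap_based_ors(compute_shap(booster, cohort), cohort)
            logs.extend([np.log(ors.or_m_hat), np.log(ors.or_w_hat)])
        logs = np.asarray(logs)
        mc_err = logs.std(ddof=1) / np.sqrt(logs.size)
        assert abs(logs.mean()) < 4 * mc_err + 1e-3
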