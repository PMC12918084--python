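import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from healthmrp.errors import AlignmentError, DataError
from healthmrp.frame import JointTable, PostStratFrame, estimate_joint_from_microdata
from healthmrp.model import (
    McmcSettings,
    PosteriorDraws,
    PriorSpec,
    fit_mrp,
    poststratify,
    predict_cells,
)
from healthmrp.schema import CellIndex, IMD_VARIABLE, enumerate_cells
from healthmrp.synthetic import OUTCOMES, TrueParams, generate_source_survey

TINY = McmcSettings(chains=2, warmup=300, draws=200, seed=17)


def _loop_predict(draws, cells):
    """Independent per-cell loop oracle for predict_cells."""
    schema = cells.schema
    out = np.empty((draws.n_draws, cells.n_cells))
    for d in range(draws.n_draws):
        row = draws.params.iloc[d]
        for c, assignment in enumerate(cells.assignments()):
            eta = row["intercept"]
            for var, level in zip(schema.variables, assignment):
                if var.name == IMD_VARIABLE:
                    eta += row[f"imd[{var.code(level) + 1}]"]
                elif level != var.reference:
                    eta += row[f"{var.name}[{level}]"]
            out[d, c] = 1.0 / (1.0 + np.exp(-eta))
    return out


class TestPredictCells:
    def test_all_zero_coefficients_give_half(self, model_schema, make_posterior_draws):
        draws = make_posterior_draws(model_schema, 5, zero=True)
        preds = predict_cells(draws, enumerate_cells(model_schema))
        assert np.allclose(preds.matrix, 0.5)

    def test_single_binary_closed_form(self, model_schema, make_posterior_draws):
        draws = make_posterior_draws(model_schema, 1, zero=True)
        draws.params.loc[0, "t[1]"] = 1.0
        preds = predict_cells(draws, enumerate_cells(model_schema))
        arr = preds.matrix.reshape(2, 5)
        assert np.allclose(arr[0], 0.5)
        assert np.allclose(arr[1], expit(1.0))

    def test_matches_loop_oracle(self, model_schema, make_posterior_draws):
        rng = np.random.default_rng(21)
        draws = make_posterior_draws(model_schema, 30, rng=rng)
        cells = enumerate_cells(model_schema)
        preds = predict_cells(draws, cells)
        assert np.abs(preds.matrix - _loop_predict(draws, cells)).max() < 1e-12

    def test_permutation_equivariance(self, model_schema, make_posterior_draws):
        rng = np.random.default_rng(4)
        draws = make_posterior_draws(model_schema, 10, rng=rng)
        cells = enumerate_cells(model_schema)
        perm = rng.permutation(cells.n_cells)
        permuted = CellIndex(model_schema, cells.codes[perm])
        assert np.array_equal(
            predict_cells(draws, permuted).matrix,
            predict_cells(draws, cells).matrix[:, perm],
        )


class TestPoststratify:
    def test_uniform_predictions_return_p(self, model_schema, make_random_frame):
        frame = make_random_frame(model_schema, np.random.default_rng(1))
        from healthmrp.model import CellPredictions

        preds = CellPredictions(frame.cell_index, np.full((4, frame.cell_index.n_cells), 0.37))
        assert np.allclose(poststratify(preds, frame), 0.37)

    def test_two_cell_example(self):
        from healthmrp.schema import Covariate, CovariateSchema
        from healthmrp.model import CellPredictions

        schema = CovariateSchema((Covariate("t", ("0", "1"), "0"),))
        index = enumerate_cells(schema)
        frame = PostStratFrame(index, np.array([0.25, 0.75]))
        preds = CellPredictions(index, np.array([[0.2, 0.6]]))
        assert np.allclose(poststratify(preds, frame), 0.5)

    def test_matches_loop_oracle_and_bounds(self, model_schema, make_posterior_draws,
                                            make_random_frame):
        rng = np.random.default_rng(33)
        draws = make_posterior_draws(model_schema, 20, rng=rng)
        frame = make_random_frame(model_schema, rng)
        preds = predict_cells(draws, frame.cell_index)
        got = poststratify(preds, frame)
        expected = np.array(
            [sum(w * p for w, p in zip(frame.weights, preds.matrix[d]))
             for d in range(draws.n_draws)]
        )
        assert np.abs(got - expected).max() < 1e-12
        assert (got >= preds.matrix.min(axis=1)).all()
        assert (got <= preds.matrix.max(axis=1)).all()

    def test_alignment_mismatch_rejected(self, model_schema, toy_schema,
                                         make_posterior_draws, make_random_frame):
        draws = make_posterior_draws(model_schema, 3, zero=True)
        preds = predict_cells(draws, enumerate_cells(model_schema))
        other = make_random_frame(toy_schema, np.random.default_rng(0))
        with pytest.raises(AlignmentError):
            poststratify(preds, other)


class TestFitMrp:
    def test_single_class_outcome_rejected(self, schema11):
        params = {"literacy": TrueParams(50.0, {})}  # everyone fails the threshold
        survey = generate_source_survey(schema11, params, n=200, seed=1,
                                        subsample_fractions={"literacy": 1.0})
        with pytest.raises(DataError, match="single-class"):
            fit_mrp(survey, "literacy", schema11, settings=TINY)

    def test_missing_covariate_rejected(self, schema11):
        params = {"literacy": TrueParams(0.0, {})}
        survey = generate_source_survey(schema11, params, n=100, seed=1)
        survey.data.drop(columns=["age"], inplace=True)
        with pytest.raises(DataError, match="age"):
            fit_mrp(survey, "literacy", schema11, settings=TINY)

    def test_unknown_outcome_rejected(self, schema11):
        params = {"literacy": TrueParams(0.0, {})}
        survey = generate_source_survey(schema11, params, n=100, seed=1)
        with pytest.raises(DataError):
            fit_mrp(survey, "reading_tea_leaves", schema11, settings=TINY)

    def test_same_seed_reproduces_draws_exactly(self, schema11):
        params = {o: TrueParams(0.0, {}) for o in OUTCOMES}
        survey = generate_source_survey(schema11, params, n=800, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_mrp(survey, "literacy", schema11, settings=TINY)
            b = fit_mrp(survey, "literacy", schema11, settings=TINY)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_null_data_recovers_zero_effects(self, schema11):
        """Outcome independent of all covariates at prevalence 0.5: posterior
        means of fixed effects and of the identified cell-level intercepts
        (intercept + IMD effect) all lie near zero."""
        params = {"literacy": TrueParams(0.0, {})}
        survey = generate_source_survey(schema11, params, n=4000, seed=29,
                                        subsample_fractions={"literacy": 1.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_mrp(survey, "literacy", schema11,
                            settings=McmcSettings(chains=2, warmup=500, draws=500, seed=5))
        means = draws.params.mean()
        for col in draws.fixed_effect_columns():
            assert abs(means[col]) < 0.15, col
        for q in range(1, 6):
            assert abs(means["intercept"] + means[f"imd[{q}]"]) < 0.15

    def test_partial_pooling_shrinks_quintile_effects(self, schema11):
        """With no true between-quintile variation the posterior quintile
        effects stay tightly grouped around their common mean."""
        params = {"literacy": TrueParams(
            0.3, {("qualification", ">=level2"): -1.0}, imd_sigma=0.0,
            imd_effects=(0.0,) * 5)}
        survey = generate_source_survey(schema11, params, n=4000, seed=41,
                                        subsample_fractions={"literacy": 1.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_mrp(survey, "literacy", schema11,
                            settings=McmcSettings(chains=2, warmup=500, draws=500, seed=6))
        u = draws.params[draws.imd_columns()].mean().to_numpy()
        assert u.max() - u.min() < 0.25

    def test_posterior_predictive_tracks_sample_prevalence(self, schema11):
        """Post-stratifying over the source sample's own empirical frame
        reproduces the sample prevalence."""
        from healthmrp.synthetic import default_true_params

        params = {"literacy": default_true_params()["literacy"]}
        survey = generate_source_survey(schema11, params, n=4000, seed=55,
                                        subsample_fractions={"literacy": 1.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_mrp(survey, "literacy", schema11,
                            settings=McmcSettings(chains=2, warmup=500, draws=500, seed=7))
        joint = estimate_joint_from_microdata(survey.data, schema11, schema11.names)
        frame = PostStratFrame(enumerate_cells(schema11), joint.probs.reshape(-1))
        preds = predict_cells(draws, frame.cell_index)
        mrp_prev = float(poststratify(preds, frame).mean())
        sample_prev = float(survey.data["literacy"].mean())
        assert abs(mrp_prev - sample_prev) < 0.03


class TestSettingsAndPriors:
    def test_bad_settings_rejected(self):
        with pytest.raises(Exception):
            McmcSettings(chains=0)

    def test_bad_prior_rejected(self):
        with pytest.raises(Exception):
            PriorSpec(fixed_effect_sd=-1.0)

    def test_draw_count_contract(self, schema11):
        params = {"literacy": TrueParams(0.0, {})}
        survey = generate_source_survey(schema11, params, n=400, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_mrp(survey, "literacy", schema11,
                            settings=McmcSettings(chains=3, warmup=100, draws=50, seed=9))
        assert draws.n_draws == 3 * 50
        assert (draws.params["imd_sigma"] > 0).all()

    def test_csv_roundtrip(self, tmp_path, schema11):
        params = {"literacy": TrueParams(0.0, {})}
        survey = generate_source_survey(schema11, params, n=400, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_mrp(survey, "literacy", schema11,
                            settings=McmcSettings(chains=2, warmup=100, draws=50, seed=9))
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        back = PosteriorDraws.from_csv(path, schema11, "literacy")
        assert back.chains == 2
        assert np.allclose(back.params.to_numpy(), draws.params.to_numpy())
        assert back.diagnostics["params"]["intercept"]["rhat"] == pytest.approx(
            draws.diagnostics["params"]["intercept"]["rhat"])
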