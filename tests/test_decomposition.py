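import numpy as np
import pytest
from scipy.special import expit

from nutridecomp import (
    Schema,
    Variable,
    build_design,
    decompose,
    delta_se,
    detailed_decompose,
    fit,
    generate_survey,
    normalize_categorical,
    pct_contribution,
)
from nutridecomp.core_data import ContractError, DesignMatrix, SurveyDataset
from nutridecomp.decomposition import (
    DegenerateAllocationError,
    UndefinedPercentageError,
    _grad_components,
)
from nutridecomp.weighted_logit import LogitFit

from conftest import make_three_var_config, simple_design


def make_fit(beta, groups, columns, cov=None):
    beta = np.asarray(beta, dtype=float)
    if cov is None:
        cov = np.zeros((len(beta), len(beta)))
    return LogitFit(beta=beta, cov=cov, n_obs=2, converged=True,
                    iterations=1, loglik=0.0, columns=columns, groups=groups)


@pytest.fixture
def worked_example():
    """Two 2-row surveys, one binary covariate, hand-solvable."""
    d_B = simple_design([0, 1], [0, 0])
    d_A = simple_design([1, 1], [0, 0])
    f_B = make_fit([0.0, 0.0], {"x": [1]}, ["intercept", "x=1"])
    f_A = make_fit([0.0, 1.0], {"x": [1]}, ["intercept", "x=1"])
    return d_A, d_B, f_A, f_B


class TestTotals:
    def test_identity_case_is_all_zero(self, worked_example):
        d_A, _, f_A, _ = worked_example
        r = decompose(d_A, d_A, f_A, f_A)
        assert r.E == 0.0 and r.C == 0.0 and r.total == 0.0

    def test_equal_fits_force_zero_C(self, worked_example):
        d_A, d_B, f_A, _ = worked_example
        r = decompose(d_A, d_B, f_A, f_A)
        assert r.C == pytest.approx(0.0, abs=1e-15)
        assert r.E != 0.0

    def test_hand_worked_two_row_example(self, worked_example):
        d_A, d_B, f_A, f_B = worked_example
        r = decompose(d_A, d_B, f_A, f_B)
        expected_E = expit(1.0) - 0.5 * (0.5 + expit(1.0))
        expected_C = 0.5 * (0.5 + expit(1.0)) - 0.5
        assert r.E == pytest.approx(expected_E, abs=1e-12)
        assert r.C == pytest.approx(expected_C, abs=1e-12)
        assert r.total == pytest.approx(expected_E + expected_C, abs=1e-12)

    def test_column_mismatch_rejected(self, worked_example, fitted_pair):
        d_A, d_B, f_A, f_B = worked_example
        other_A = fitted_pair[0]
        with pytest.raises(ContractError):
            decompose(other_A, d_B, f_A, f_B)

    def test_swapping_surveys_negates_total(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        fwd = decompose(d_A, d_B, f_A, f_B)
        rev = decompose(d_B, d_A, f_B, f_A)
        assert rev.total == pytest.approx(-fwd.total, abs=1e-12)

    def test_path_identity_with_converged_fits(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        r = decompose(d_A, d_B, f_A, f_B)
        prev_A = float((d_A.weights * d_A.outcome).sum() / d_A.weights.sum())
        prev_B = float((d_B.weights * d_B.outcome).sum() / d_B.weights.sum())
        assert r.total == pytest.approx(prev_A - prev_B, abs=1e-8)


class TestNormalization:
    def test_binary_variable_deviation_coding(self):
        f = make_fit([0.2, 0.8], {"x": [1]}, ["intercept", "x=1"])
        nf = normalize_categorical(f)
        assert nf.columns[0] == "intercept"
        np.testing.assert_allclose(nf.beta, [0.2 + 0.4, -0.4, 0.4], atol=1e-15)

    def test_centered_effects_are_fixed_point(self):
        # three-level variable with effects (0, 1, -1): mean already 0
        f = make_fit([0.3, 1.0, -1.0], {"z": [1, 2]},
                     ["intercept", "z=b", "z=c"])
        nf = normalize_categorical(f)
        np.testing.assert_allclose(nf.beta, [0.3, 0.0, 1.0, -1.0], atol=1e-15)

    def test_linear_predictor_preserved(self, fitted_pair):
        d_A, _, f_A, _ = fitted_pair
        nf = normalize_categorical(f_A, d_A.schema)
        expanded = _expand_design(d_A)
        eta_raw = d_A.values @ f_A.beta
        eta_norm = expanded @ nf.beta
        np.testing.assert_allclose(eta_norm, eta_raw, atol=1e-12)

    def test_covariance_transforms_consistently(self, fitted_pair):
        d_A, _, f_A, _ = fitted_pair
        nf = normalize_categorical(f_A, d_A.schema)
        # any contrast expressible in both codings has the same variance:
        # difference between two non-reference categories of one variable
        var = list(f_A.groups)[0]
        j1, j2 = f_A.groups[var][:2]
        c_raw = np.zeros(f_A.n_params)
        c_raw[j1], c_raw[j2] = 1.0, -1.0
        k1, k2 = nf.groups[var][1], nf.groups[var][2]
        c_norm = np.zeros(nf.n_params)
        c_norm[k1], c_norm[k2] = 1.0, -1.0
        v_raw = float(c_raw @ f_A.cov @ c_raw)
        v_norm = float(c_norm @ nf.cov @ c_norm)
        assert v_norm == pytest.approx(v_raw, rel=1e-10)


def _expand_design(d: DesignMatrix) -> np.ndarray:
    """Design with one dummy per category (reference columns inserted)."""
    cols = [np.ones(d.n_obs)]
    for var, idx in d.groups.items():
        block = d.values[:, idx]
        cols.append(1.0 - block.sum(axis=1))
        for j in idx:
            cols.append(d.values[:, j])
    return np.column_stack(cols)


class TestDetailed:
    def test_single_binary_covariate_exhausts_totals(self, worked_example):
        d_A, d_B, f_A, f_B = worked_example
        r = detailed_decompose(d_A, d_B, f_A, f_B, normalize=False)
        row = r.detail[r.detail["variable"] == "x"].iloc[0]
        const = r.detail[r.detail["variable"] == "Constant"].iloc[0]
        assert row["E"] == pytest.approx(r.E, abs=1e-12)
        assert const["C"] + row["C"] == pytest.approx(r.C, abs=1e-12)
        # intercept means are equal across surveys, so E has no constant part
        assert const["E"] == 0.0

    def test_equal_fits_zero_all_C_terms(self, fitted_pair):
        d_A, d_B, f_A, _ = fitted_pair
        r = detailed_decompose(d_A, d_B, f_A, f_A)
        np.testing.assert_allclose(r.detail["C"].to_numpy(), 0.0, atol=1e-12)

    @pytest.mark.parametrize("normalize", [True, False])
    def test_detail_sums_to_components(self, fitted_pair, normalize):
        d_A, d_B, f_A, f_B = fitted_pair
        r = detailed_decompose(d_A, d_B, f_A, f_B, normalize=normalize)
        assert r.detail["E"].sum() == pytest.approx(r.E, abs=1e-10)
        assert r.detail["C"].sum() == pytest.approx(r.C, abs=1e-10)
        assert r.E + r.C == pytest.approx(r.total, abs=1e-10)
        assert r.pct_E + r.pct_C == pytest.approx(100.0, abs=1e-8)

    def test_pct_of_detail_relative_to_grand_total(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        r = detailed_decompose(d_A, d_B, f_A, f_B)
        got = r.detail["E_pct"].to_numpy()
        want = 100.0 * r.detail["E"].to_numpy() / r.total
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_degenerate_allocation_detected(self):
        # two covariates whose mean-shift contributions cancel exactly in
        # the linearization while E stays away from zero
        schema = Schema((Variable("u", ("0", "1")), Variable("v", ("0", "1"))))
        vals_B = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 0], [1, 0, 0]], float)
        vals_A = np.array([[1, 1, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0]], float)
        cols = ["intercept", "u=1", "v=1"]
        groups = {"u": [1], "v": [2]}
        mk = lambda V: DesignMatrix(V, np.ones(4), np.zeros(4), groups, cols,
                                    schema)
        d_B, d_A = mk(vals_B), mk(vals_A)
        f_B = make_fit([0.0, 0.0, 0.0], groups, cols)
        # mean shifts are +0.25 (u) and -0.5 (v); effects 2 and 1 cancel in
        # the linearization while E itself stays nonzero (F is nonlinear)
        f_A = make_fit([0.0, 2.0, 1.0], groups, cols)
        with pytest.raises(DegenerateAllocationError):
            detailed_decompose(d_A, d_B, f_A, f_B, normalize=False)

    def test_zero_total_marks_pct_undefined(self, worked_example):
        d_A, _, f_A, _ = worked_example
        r = detailed_decompose(d_A, d_A, f_A, f_A)
        assert np.isnan(r.pct_E) and np.isnan(r.pct_C)
        assert np.allclose(r.detail["E"], 0.0) and np.allclose(r.detail["C"], 0.0)


class TestReferenceInvariance:
    @staticmethod
    def _decompose_under(schema, cfg):
        ds_B = generate_survey(cfg, 0)
        ds_A = generate_survey(cfg, 1)
        ds_B = SurveyDataset(ds_B.frame, schema, ds_B.survey)
        ds_A = SurveyDataset(ds_A.frame, schema, ds_A.survey)
        d_B, d_A = build_design(ds_B), build_design(ds_A)
        return detailed_decompose(d_A, d_B, fit(d_A), fit(d_B), normalize=True)

    def test_totals_and_normalized_detail_invariant(self, three_var_schema):
        cfg = make_three_var_config(three_var_schema, n=1500)
        base = self._decompose_under(three_var_schema, cfg)
        base_detail = base.detail.set_index(["variable", "category"])
        # move the reference of two variables and recompute from scratch
        alt_schema = (three_var_schema
                      .with_reference("edu", "Secondary")
                      .with_reference("wealth", "Rich"))
        alt = self._decompose_under(alt_schema, cfg)
        alt_detail = alt.detail.set_index(["variable", "category"])
        assert alt.E == pytest.approx(base.E, abs=1e-8)
        assert alt.C == pytest.approx(base.C, abs=1e-8)
        for key in base_detail.index:
            for comp in ("E", "C"):
                assert alt_detail.loc[key, comp] == pytest.approx(
                    base_detail.loc[key, comp], abs=1e-8), key


class TestDeltaSE:
    def test_zero_covariances_give_zero_se(self, worked_example):
        d_A, d_B, f_A, f_B = worked_example
        assert delta_se(d_A, d_B, f_A, f_B) == (0.0, 0.0)

    def test_E_gradient_free_of_beta_B(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        gE, _ = _grad_components(f_A.beta, f_B.beta, d_A, d_B)
        np.testing.assert_array_equal(gE[f_A.n_params:], 0.0)

    def test_analytic_gradients_match_finite_differences(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        from nutridecomp.decomposition import _components
        gE, gC = _grad_components(f_A.beta, f_B.beta, d_A, d_B)
        kA = f_A.n_params
        theta = np.concatenate([f_A.beta, f_B.beta])
        h = 1e-6
        for j in range(len(theta)):
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            Eu, Cu = _components(up[:kA], up[kA:], d_A, d_B)
            Ed, Cd = _components(dn[:kA], dn[kA:], d_A, d_B)
            assert (Eu - Ed) / (2 * h) == pytest.approx(gE[j], abs=1e-6)
            assert (Cu - Cd) / (2 * h) == pytest.approx(gC[j], abs=1e-6)

    def test_detail_term_ses_positive_for_estimated_fits(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        r = detailed_decompose(d_A, d_B, f_A, f_B)
        assert (r.detail.loc[r.detail["variable"] != "Constant", "C_se"] > 0).all()

    def test_missing_covariance_rejected(self, fitted_pair):
        d_A, d_B, f_A, f_B = fitted_pair
        broken = make_fit(f_A.beta, f_A.groups, f_A.columns)
        broken.cov = None
        with pytest.raises(ContractError):
            delta_se(d_A, d_B, broken, f_B)


class TestPctContribution:
    def test_printed_component_totals_reproduce_published_shares(self):
        total = -0.01824 + -0.12666
        assert pct_contribution(-0.01824, total) == pytest.approx(12.59, abs=0.05)
        assert pct_contribution(-0.12666, total) == pytest.approx(87.41, abs=0.05)

    def test_full_share_is_hundred(self):
        assert pct_contribution(-0.3, -0.3) == 100.0
        assert pct_contribution(2.5, 2.5) == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedPercentageError):
            pct_contribution(1.0, 0.0)
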