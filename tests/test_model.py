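"""Model structure: theta chain, parameter census, log joint density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qaop._link import inv_logit
from qaop.dataset import DNTDataset, PredictorAssignment, build_design_matrices
from qaop.model import (
    ModelSpec,
    PriorSpec,
    build_model,
    compute_theta_chain,
    count_parameters,
    log_joint_density,
)
from qaop.synthetic import GeneratorConfig, apply_missingness, simulate_dataset

from conftest import make_record

INTERCEPT_ONLY = PredictorAssignment(
    bdnf=("intercept",), syn=("intercept",), nnf=("intercept",)
)

finite = st.floats(-50, 50, allow_nan=False)


class TestThetaChain:
    @pytest.mark.parametrize(
        "c, expected",
        [
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0)),
            ((1.0, 1.0, 1.0), (1.0, 2.0, 3.0, 6.0)),
            ((0.5, -1.0, 0.25), (0.5, -0.5, -0.25, -0.25)),
        ],
    )
    def test_hand_evaluated_chains(self, c, expected):
        assert compute_theta_chain(*c) == pytest.approx(expected)

    def test_zero_chain_gives_half_probability(self):
        thetas = compute_theta_chain(0.0, 0.0, 0.0)
        assert all(inv_logit(t) == 0.5 for t in thetas)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(c1=finite, c2=finite, c3=finite)
    def test_ao_predictor_telescopes(self, c1, c2, c3):
        *_, t_dnt = compute_theta_chain(c1, c2, c3)
        assert t_dnt == pytest.approx(3 * c1 + 2 * c2 + c3, rel=1e-12, abs=1e-9)

    # |theta| kept below ~35 so the logistic has float headroom to move
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c1=st.floats(-5, 5, allow_nan=False),
        c2=st.floats(-5, 5, allow_nan=False),
        c3=st.floats(-5, 5, allow_nan=False),
        bump=st.floats(1e-3, 5, allow_nan=False),
    )
    def test_increasing_c1_increases_every_node_probability(self, c1, c2, c3, bump):
        base = compute_theta_chain(c1, c2, c3)
        up = compute_theta_chain(c1 + bump, c2, c3)
        assert all(inv_logit(u) > inv_logit(b) for u, b in zip(up, base))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_theta_chain(np.nan, 0.0, 0.0)

    def test_vectorized_over_compounds(self):
        c = np.arange(3, dtype=float)
        t = compute_theta_chain(c, c, c)
        np.testing.assert_allclose(t[3], 6 * c)


class TestCensus:
    def test_complete_data_nine_named_blocks(self, complete_8):
        model = build_model(build_design_matrices(complete_8))
        census = count_parameters(model)
        assert census.total_named == 9
        assert (
            census.hyperprior_blocks,
            census.coefficient_blocks,
            census.likelihood_blocks,
        ) == (2, 3, 4)
        assert census.imputation_blocks == 0

    def test_default_dims_sixteen_free_scalars(self, complete_8):
        dm = build_design_matrices(complete_8)
        assert dm.block_dims == (7, 3, 4)
        census = count_parameters(build_model(dm))
        assert census.total_scalar_parameters == 2 + 14

    def test_one_missing_cell_adds_three_scalars(self):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=8, seed=21))
        base = count_parameters(build_model(build_design_matrices(ds)))
        ds.records[3].logd = None
        plus = count_parameters(build_model(build_design_matrices(ds)))
        assert plus.total_scalar_parameters == base.total_scalar_parameters + 3
        assert plus.imputation_blocks == 1
        assert plus.total_named == 9  # named structure independent of n/missingness

    def test_five_missing_cells_one_block(self):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=10, seed=22))
        for i in range(5):
            ds.records[i].syn_viability = None
        model = build_model(build_design_matrices(ds))
        census = count_parameters(model)
        assert census.imputation_blocks == 1
        rows, _ = model.miss_idx["syn"]
        assert rows.size == 5

    def test_scaling_like_the_real_study(self):
        # 88 compounds with heavy missingness: hundreds of free scalars
        from qaop.synthetic import DEFAULT_MISSINGNESS, simulate_study

        cfg = GeneratorConfig(
            n_compounds=88, seed=23, missingness=DEFAULT_MISSINGNESS
        )
        ds, _ = simulate_study(cfg)
        census = count_parameters(build_model(build_design_matrices(ds)))
        assert census.total_scalar_parameters > 50
        assert census.total_named == 9


def _one_compound_dm():
    ds = DNTDataset([make_record(0, dnt_label=1, bdnf_label=0, syn_label=1, nnf_label=0)])
    return build_design_matrices(ds, INTERCEPT_ONLY)


class TestLogJointDensity:
    def test_closed_form_single_compound(self):
        dm = _one_compound_dm()
        params = {
            "mu": 0.0,
            "sigma": 1.0,
            "beta_bdnf": [0.0],
            "beta_syn": [0.0],
            "beta_nnf": [0.0],
        }
        expected = (
            stats.norm.logpdf(0.0, 0.0, 0.1)
            + stats.halfnorm.logpdf(1.0, scale=1.0)
            + 3 * stats.norm.logpdf(0.0, 0.0, 1.0)
            + 4 * np.log(0.5)
        )
        assert log_joint_density(params, dm) == pytest.approx(expected, rel=1e-12)

    def test_duplicating_a_compound_adds_its_likelihood(self):
        rec = make_record(0, dnt_label=1, bdnf_label=0, syn_label=1, nnf_label=0)
        dm1 = build_design_matrices(DNTDataset([rec]), INTERCEPT_ONLY)
        import copy

        rec2 = copy.deepcopy(rec)
        rec2.cas_rn = "other-1"
        dm2 = build_design_matrices(DNTDataset([rec, rec2]), INTERCEPT_ONLY)
        params = {
            "mu": 0.1,
            "sigma": 0.7,
            "beta_bdnf": [0.3],
            "beta_syn": [-0.2],
            "beta_nnf": [0.5],
        }
        lp1 = log_joint_density(params, dm1)
        lp2 = log_joint_density(params, dm2)
        c = (0.3, -0.2, 0.5)
        thetas = compute_theta_chain(*c)
        y = (0, 1, 0, 1)
        lik = sum(
            np.log(inv_logit(t)) if yi else np.log(1 - inv_logit(t))
            for t, yi in zip(thetas, y)
        )
        assert lp2 - lp1 == pytest.approx(lik, rel=1e-10)

    def test_nonpositive_sigma_is_minus_inf(self):
        dm = _one_compound_dm()
        params = {
            "mu": 0.0,
            "sigma": -1.0,
            "beta_bdnf": [0.0],
            "beta_syn": [0.0],
            "beta_nnf": [0.0],
        }
        assert log_joint_density(params, dm) == -np.inf

    def test_missing_parameter_rejected(self):
        dm = _one_compound_dm()
        with pytest.raises(ValueError, match="beta_nnf"):
            log_joint_density(
                {"mu": 0.0, "sigma": 1.0, "beta_bdnf": [0.0], "beta_syn": [0.0]}, dm
            )


class TestGradients:
    @pytest.mark.parametrize("with_missing", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, with_missing):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=12, seed=31))
        if with_missing:
            ds = apply_missingness(
                ds, {"logd": 0.3, "syn_viability": 0.3, "bdnf_label": 0.4}, seed=2
            )
        model = build_model(build_design_matrices(ds))
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 0.4, model.dim)
        _, g = model.logp_grad(x)
        eps = 1e-6
        for i in range(model.dim):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (model.logp_grad(xp)[0] - model.logp_grad(xm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_frozen_parameters_reduce_free_vector(self, complete_8):
        dm = build_design_matrices(complete_8)
        full = build_model(dm)
        frozen = build_model(
            dm, ModelSpec(frozen={"mu": 0.0, "sigma": 1.0, "beta_syn": [0.0] * 3})
        )
        assert frozen.dim == full.dim - 5
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.3, frozen.dim)
        lp, g = frozen.logp_grad(x)
        assert np.isfinite(lp) and np.all(np.isfinite(g))


class TestModelSpecValidation:
    def test_unsupported_link_rejected(self):
        with pytest.raises(ValueError, match="link"):
            ModelSpec(link="probit")

    def test_nonpositive_prior_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PriorSpec(hyper_sigma_scale=0.0)

    def test_shape_mismatch_detected_before_sampling(self, complete_8):
        dm = build_design_matrices(complete_8)
        dm.miss_syn = dm.miss_syn[:, :2]
        with pytest.raises(ValueError, match="mismatch"):
            build_model(dm)
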