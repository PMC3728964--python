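import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalrecon import (
    InvalidInputError,
    InvalidParameterError,
    KernelParams,
    SizeMesh,
    evaluate_kernel,
    fecundity_count_fn,
    growth_fn,
    offspring_size_fn,
    param_count,
    survival_fn,
)
from vitalrecon.kernel_model import PARAM_NAMES


def flat_params(**overrides):
    base = dict.fromkeys(PARAM_NAMES["standard"], 0.0)
    base["grow_sd"] = 0.3
    base["off_sd"] = 0.3
    base.update(overrides)
    return KernelParams(**base)


class TestParamCount:
    def test_counts_match_variant(self):
        assert param_count("standard") == 16
        assert param_count("bounded_survival") == 18

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidInputError):
            param_count("exponential")

    def test_count_matches_flat_vector_length(self, tame_params):
        assert tame_params.to_vector().size == param_count("standard")
        bounded = tame_params.replace(variant="bounded_survival")
        assert bounded.to_vector().size == param_count("bounded_survival")


class TestKernelParams:
    def test_nonpositive_spread_rejected(self):
        with pytest.raises(InvalidParameterError):
            flat_params(grow_sd=0.0)
        with pytest.raises(InvalidParameterError):
            flat_params(off_sd=-0.1)

    def test_vector_round_trip(self, tame_params):
        again = KernelParams.from_vector(tame_params.to_vector())
        assert again == tame_params

    def test_json_round_trip(self, tame_params):
        bounded = tame_params.replace(variant="bounded_survival",
                                      smax_icpt=-1.0, smax_time=0.02)
        again = KernelParams.loads(bounded.dumps())
        assert again == bounded


class TestSurvival:
    def test_all_zero_block_gives_half(self):
        p = flat_params()
        assert survival_fn(2.0, 30.0, p) == pytest.approx(0.5)

    def test_bounded_asymptote_at_zero_coefficients(self):
        # saturated base logistic times s_max(0) = 1/(1+e^0)
        p = flat_params(surv_icpt=40.0, variant="bounded_survival")
        assert survival_fn(1.0, 0.0, p) == pytest.approx(0.5, abs=1e-12)

    def test_logistic_saturation(self):
        p = flat_params(surv_icpt=40.0)
        assert survival_fn(0.0, 0.0, p) == pytest.approx(1.0, abs=1e-10)

    def test_nonfinite_input_rejected(self):
        p = flat_params()
        with pytest.raises(InvalidInputError):
            survival_fn(np.nan, 0.0, p)
        with pytest.raises(InvalidInputError):
            survival_fn(1.0, np.inf, p)

    @settings(derandomize=True, max_examples=50)
    @given(
        theta=st.lists(st.floats(-2, 2), min_size=18, max_size=18),
        x=st.floats(0, 5),
        t=st.floats(0, 100),
    )
    def test_bounded_by_smax(self, theta, x, t):
        theta = np.array(theta)
        theta[[8, 15]] = np.abs(theta[[8, 15]]) + 0.1  # positive spreads
        p = KernelParams.from_vector(theta, variant="bounded_survival")
        smax = 1.0 / (1.0 + np.exp(p.smax_icpt + p.smax_time * t))
        s = survival_fn(x, t, p)
        assert 0.0 <= s <= smax + 1e-12


class TestGrowthAndOffspring:
    def test_gaussian_mode_value(self):
        p = flat_params(grow_size=1.0, grow_sd=0.4)  # mean(y|x) = x
        val = growth_fn(2.0, 2.0, 10.0, p)
        assert val == pytest.approx(1.0 / (0.4 * np.sqrt(2 * np.pi)))

    def test_symmetry_about_mean(self):
        p = flat_params(grow_icpt=0.2, grow_size=0.9, grow_sd=0.3)
        mu = 0.2 + 0.9 * 1.5
        assert growth_fn(mu + 0.37, 1.5, 0.0, p) == pytest.approx(
            growth_fn(mu - 0.37, 1.5, 0.0, p)
        )

    @pytest.mark.parametrize("sd", [0.2, 0.35])
    def test_growth_quadrature_is_one(self, sd):
        # mesh spanning +-8 spreads of the mean
        p = flat_params(grow_icpt=1.0, grow_size=0.0, grow_sd=sd)
        grid = np.linspace(1.0 - 8 * sd, 1.0 + 8 * sd, 4001)
        h = grid[1] - grid[0]
        mass = growth_fn(grid, 0.0, 0.0, p).sum() * h
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_offspring_mode_and_quadrature(self):
        p = flat_params(off_icpt=0.5, off_sd=0.25)
        assert offspring_size_fn(0.5, 0.0, p) == pytest.approx(
            1.0 / (0.25 * np.sqrt(2 * np.pi))
        )
        grid = np.linspace(0.5 - 2.0, 0.5 + 2.0, 4001)
        mass = offspring_size_fn(grid, 0.0, p).sum() * (grid[1] - grid[0])
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_offspring_time_invariant_without_trend(self):
        p = flat_params(off_icpt=0.5, off_sd=0.25)
        y = np.linspace(0, 3, 20)
        np.testing.assert_allclose(
            offspring_size_fn(y, 0.0, p), offspring_size_fn(y, 50.0, p)
        )


class TestFecundity:
    def test_zero_block_gives_one(self):
        assert fecundity_count_fn(3.0, 40.0, flat_params()) == pytest.approx(1.0)

    def test_log_link_intercept(self):
        p = flat_params(fec_icpt=np.log(5.0))
        assert fecundity_count_fn(1.0, 1.0, p) == pytest.approx(5.0)

    def test_monotone_in_size(self):
        p = flat_params(fec_icpt=-1.0, fec_size=0.4)
        x = np.linspace(0, 5, 30)
        vals = fecundity_count_fn(x, 10.0, p)
        assert np.all(np.diff(vals) > 0)

    def test_overflowing_link_is_capped(self):
        p = flat_params(fec_icpt=500.0)
        assert fecundity_count_fn(1.0, 1.0, p) == pytest.approx(np.exp(30.0))


class TestEvaluateKernel:
    def test_dead_sterile_species_gives_zero_kernel(self, mesh):
        p = flat_params(surv_icpt=-1000.0, fec_icpt=-1000.0)
        K = evaluate_kernel(p, mesh, 0.0)
        np.testing.assert_allclose(K.array, 0.0, atol=1e-200)

    def test_growth_mass_conserved_when_survival_is_one(self, mesh):
        # fecundity off, survival saturated: columns sum to 1 (eviction fix)
        p = flat_params(surv_icpt=40.0, fec_icpt=-1000.0,
                        grow_icpt=0.2, grow_size=0.9)
        K = evaluate_kernel(p, mesh, 0.0)
        np.testing.assert_allclose(K.array.sum(axis=0), 1.0, atol=1e-9)

    def test_pointwise_oracle_without_eviction(self, tame_params):
        # wide mesh + interior column: eviction is negligible, so the
        # kernel entry matches direct evaluation of s*g*h + f1*f2*h
        mesh = SizeMesh(-8.0, 13.0, 420)
        t = 12.0
        K = evaluate_kernel(tame_params, mesh, t).array
        i, j = 210, 170
        y, x = mesh.nodes[i], mesh.nodes[j]
        from vitalrecon import growth_fn as g, survival_fn as s
        direct = (
            s(x, t, tame_params) * g(y, x, t, tame_params)
            + fecundity_count_fn(x, t, tame_params)
            * offspring_size_fn(y, t, tame_params)
        ) * mesh.h
        assert K[i, j] == pytest.approx(direct, rel=1e-6)

    def test_survival_subkernel_column_sums(self, mesh, tame_params):
        p = tame_params.replace(fec_icpt=-1000.0)
        K = evaluate_kernel(p, mesh, 7.0)
        s = survival_fn(mesh.nodes, 7.0, p)
        assert np.all(K.array.sum(axis=0) <= s + 1e-9)

    def test_fecundity_subkernel_scales_linearly(self, mesh, tame_params):
        dead = tame_params.replace(surv_icpt=-1000.0)  # fecundity only
        K1 = evaluate_kernel(dead, mesh, 5.0).array
        doubled = dead.replace(fec_icpt=dead.fec_icpt + np.log(2.0))
        K2 = evaluate_kernel(doubled, mesh, 5.0).array
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-12)


class TestSizeMesh:
    def test_invariants(self, mesh):
        assert mesh.nodes[0] > mesh.lower
        assert mesh.nodes[-1] < mesh.upper
        assert np.all(np.diff(mesh.nodes) > 0)
        assert mesh.weights.sum() == pytest.approx(mesh.upper - mesh.lower)

    def test_invalid_meshes_rejected(self):
        with pytest.raises(InvalidInputError):
            SizeMesh(1.0, 1.0, 10)
        with pytest.raises(InvalidInputError):
            SizeMesh(0.0, 5.0, 1)

    def test_cell_index_clips(self, mesh):
        assert mesh.cell_index(-3.0) == 0
        assert mesh.cell_index(99.0) == mesh.n - 1
        assert mesh.cell_index(mesh.nodes[17]) == 17
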