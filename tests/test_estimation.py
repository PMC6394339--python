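import numpy as np
import pytest

import glvkit as g
from glvkit.errors import UnderdeterminedSystemError, ValidationError


def ols_fit(X, y):
    """Independent ordinary-least-squares reference (with intercept)."""
    A = np.column_stack([np.ones(len(y)), X])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((A @ sol - y) ** 2))
    return sol[0], sol[1:], resid


class TestBuildRegressionSystem:
    def test_hand_computed_single_taxon(self):
        # x = [1, 2, 4] at t = [0, 1, 2]: responses ln2, ln2; midpoints 1.5, 3
        table = g.AbundanceTable(times=[0, 1, 2], taxa=["A"], values=[[1], [2], [4]])
        system = g.build_regression_system(table)
        np.testing.assert_allclose(system.responses["A"], [np.log(2)] * 2)
        np.testing.assert_allclose(system.design.ravel(), [1.5, 3.0])
        assert system.interval_times == [(0.0, 1.0), (1.0, 2.0)]

    def test_irregular_spacing_divides_by_dt(self):
        table = g.AbundanceTable(
            times=[0, 2], taxa=["A"], values=[[1], [np.exp(2)]]
        )
        system = g.build_regression_system(table, allow_underdetermined=True)
        np.testing.assert_allclose(system.responses["A"], [1.0])

    def test_zero_endpoint_interval_dropped_and_recorded(self):
        table = g.AbundanceTable(
            times=[0, 1, 2, 3, 4],
            taxa=["A"],
            values=[[1], [0], [2], [4], [8]],
        )
        system = g.build_regression_system(table, allow_underdetermined=True)
        # intervals 0 and 1 touch the zero at t=1
        assert system.dropped_intervals["A"] == [0, 1]
        assert system.responses["A"].size == 2
        assert system.design.shape[0] == system.responses["A"].size + 2

    def test_underdetermined_names_taxon(self):
        table = g.AbundanceTable(
            times=[0, 1, 2],
            taxa=[f"t{i}" for i in range(5)],
            values=np.ones((3, 5)) + np.arange(15).reshape(3, 5) / 10,
        )
        with pytest.raises(UnderdeterminedSystemError, match="t0"):
            g.build_regression_system(table)

    def test_pseudocount_mode_keeps_all_intervals(self):
        table = g.AbundanceTable(
            times=[0, 1, 2, 3, 4],
            taxa=["A"],
            values=[[1], [0], [2], [4], [8]],
        )
        system = g.build_regression_system(
            table, pseudocount=0, allow_underdetermined=True
        )
        assert system.dropped_intervals["A"] == []
        assert system.responses["A"].size == 4


class TestUnconstrained:
    def test_single_taxon_exact_interpolation(self):
        table = g.AbundanceTable(times=[0, 1, 2], taxa=["A"], values=[[1], [2], [4]])
        result = g.estimate_unconstrained(g.build_regression_system(table))
        assert result.model.growth_rates[0] == pytest.approx(np.log(2), abs=1e-10)
        assert result.model.interactions[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert result.model.method_tag == "unconstrained"

    def test_exact_recovery_from_discrete_fixture(self):
        truth = g.random_stable_model(3, seed=7)
        table = g.exact_discrete_fixture(
            truth, [0.5, 0.8, 0.6], np.linspace(0, 10, 21)
        )
        result = g.estimate_unconstrained(g.build_regression_system(table))
        assert np.max(np.abs(result.model.growth_rates - truth.growth_rates)) < 1e-8
        assert np.max(np.abs(result.model.interactions - truth.interactions)) < 1e-8

    def test_full_components_equal_ols(self):
        truth = g.random_stable_model(3, seed=3)
        table = g.generate_dataset(
            truth,
            g.SyntheticSpec(n_taxa=3, times=np.linspace(0, 12, 25), noise_sigma=0.1, seed=3),
        )
        system = g.build_regression_system(table)
        result = g.estimate_unconstrained(system, n_components=3)
        for i, taxon in enumerate(system.taxa):
            r_ols, a_ols, resid = ols_fit(
                system.design[system.masks[taxon]], system.responses[taxon]
            )
            assert result.model.growth_rates[i] == pytest.approx(r_ols, abs=1e-8)
            np.testing.assert_allclose(result.model.interactions[i], a_ols, atol=1e-8)
            assert result.residual_norms[taxon] == pytest.approx(resid, abs=1e-8)

    def test_too_many_components_rejected(self):
        table = g.AbundanceTable(times=[0, 1, 2], taxa=["A"], values=[[1], [2], [4]])
        with pytest.raises(ValidationError):
            g.estimate_unconstrained(g.build_regression_system(table), n_components=5)

    def test_constant_abundances_consistent_and_flagged(self):
        table = g.AbundanceTable(
            times=np.arange(5.0), taxa=["A", "B"], values=np.full((5, 2), 2.0)
        )
        system = g.build_regression_system(table, allow_underdetermined=True)
        result = g.estimate_unconstrained(system)
        # fitted parameters must reproduce the all-zero responses exactly
        c = np.full(2, 2.0)
        recon = result.model.growth_rates + result.model.interactions @ c
        np.testing.assert_allclose(recon, 0.0, atol=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-20) for v in result.residual_norms.values())
        assert result.warnings  # non-uniqueness flagged


class TestConstrained:
    def test_worked_single_taxon_example_vs_grid_oracle(self):
        # decaying series [4, 2, 1]: unconstrained optimum r = -ln2 < 0
        table = g.AbundanceTable(times=[0, 1, 2], taxa=["A"], values=[[4], [2], [1]])
        system = g.build_regression_system(table)
        result = g.estimate_constrained(system)
        assert result.feasible
        r_hat = result.model.growth_rates[0]
        a_hat = result.model.interactions[0, 0]
        assert r_hat == pytest.approx(0.0, abs=1e-10)
        assert a_hat == pytest.approx(-2 * np.log(2) / 5, abs=1e-6)

        # independent oracle: fine grid search over the feasible quadrant
        X = system.design[:, 0]
        y = system.responses["A"]
        rs = np.linspace(0, 1, 2001)
        al = np.linspace(-1, 0, 2001)
        R, A = np.meshgrid(rs, al, indexing="ij")
        sse = ((R[..., None] + A[..., None] * X - y) ** 2).sum(axis=-1)
        k = np.unravel_index(np.argmin(sse), sse.shape)
        assert r_hat == pytest.approx(R[k], abs=1e-3)
        assert a_hat == pytest.approx(A[k], abs=1e-3)
        # the fitted point cannot beat the oracle's best SSE by more than grid slack
        sse_hat = float(((r_hat + a_hat * X - y) ** 2).sum())
        assert sse_hat <= sse[k] + 1e-6

    def test_inactive_constraints_match_ols(self):
        truth = g.random_stable_model(3, seed=13)
        table = g.exact_discrete_fixture(truth, [0.5, 0.7, 0.9], np.linspace(0, 10, 21))
        system = g.build_regression_system(table)
        con = g.estimate_constrained(system)
        unc = g.estimate_unconstrained(system)
        # truth has r > 0 and diag < 0, so constraints are inactive
        np.testing.assert_allclose(
            con.model.growth_rates, unc.model.growth_rates, atol=1e-6
        )
        np.testing.assert_allclose(
            con.model.interactions, unc.model.interactions, atol=1e-6
        )
        assert con.model.method_tag == "constrained"

    def test_residual_never_below_ols(self):
        truth = g.random_stable_model(3, seed=21)
        table = g.generate_dataset(
            truth,
            g.SyntheticSpec(n_taxa=3, times=np.linspace(0, 12, 30), noise_sigma=0.2, seed=21),
        )
        system = g.build_regression_system(table)
        con = g.estimate_constrained(system)
        for taxon in system.taxa:
            _, _, resid_ols = ols_fit(
                system.design[system.masks[taxon]], system.responses[taxon]
            )
            assert con.residual_norms[taxon] >= resid_ols - 1e-10

    def test_constraints_hold_exactly(self):
        truth = g.random_stable_model(4, seed=33)
        table = g.generate_dataset(
            truth,
            g.SyntheticSpec(n_taxa=4, times=np.linspace(0, 15, 40), noise_sigma=0.3, seed=33),
        )
        result = g.estimate_constrained(g.build_regression_system(table))
        assert result.feasible
        assert np.all(result.model.growth_rates >= 0)
        assert np.all(np.diag(result.model.interactions) <= 0)


def test_continuum_limit_error_shrinks_with_step():
    """Halving the ODE sampling step shrinks the discretization bias."""
    truth = g.random_stable_model(3, seed=17)
    x0 = np.array([0.4, 0.9, 0.6])
    errors = {}
    for h in (0.5, 0.25):
        times = np.arange(0.0, 10.0 + h / 2, h)
        values = g.integrate_on(truth, x0, times, rtol=1e-11, atol=1e-13)
        table = g.AbundanceTable(times=times, taxa=truth.taxa, values=values)
        fit = g.estimate_unconstrained(g.build_regression_system(table))
        errors[h] = max(
            np.max(np.abs(fit.model.growth_rates - truth.growth_rates)),
            np.max(np.abs(fit.model.interactions - truth.interactions)),
        )
    assert errors[0.25] < errors[0.5]
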