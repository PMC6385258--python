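"""Binding-kinetics model: closed form, gamma mixture, isotherm fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from qdc3dm import kinetics as K


def reference_ode(params: K.KineticParams, n_r: float, t: float):
    """Independent numerical integration of the three-state rate system."""

    def rhs(_, y):
        r, b, c = y
        kappa = params.kappa
        return [
            -kappa * r + params.k_off * b,
            kappa * r - (params.k_off + params.k_int) * b,
            params.k_int * b,
        ]

    sol = solve_ivp(
        rhs, (0.0, t), [n_r, 0.0, 0.0], rtol=1e-11, atol=1e-12, dense_output=True
    )
    return sol.y[:, -1]


class TestMeanBound:
    def test_no_ligand_means_no_binding(self):
        p = K.KineticParams(k_on=1e6, k_off=1e-3, k_int=1e-4, egf0=0.0, t=300.0)
        assert K.mean_bound(p, 1e5) == 0.0

    def test_irreversible_limit_closed_form(self):
        p = K.KineticParams(k_on=1e6, k_off=0.0, k_int=0.0, egf0=1e-9, t=500.0)
        expected = 1e5 * (1.0 - np.exp(-p.kappa * 500.0))
        assert K.mean_bound(p, 1e5) == pytest.approx(expected, rel=1e-12)

    def test_cold_binding_pulse_matches_two_state_solution(self):
        """4C rates, 0.3 nM ligand, 5 min: ~89 bound per 1e5 receptors."""
        p = K.KineticParams.from_preset("4C", 0.3e-9, 300.0)
        # independent two-state closed form (no internalization at 4C)
        lam = p.kappa + p.k_off
        expected = 1e5 * p.kappa / lam * (1.0 - np.exp(-lam * 300.0))
        got = K.mean_bound(p, 1e5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(89.0, abs=1.0)

    @pytest.mark.parametrize("preset", ["37C", "4C"])
    def test_closed_form_agrees_with_ode_and_conserves_receptors(self, preset):
        p = K.KineticParams.from_preset(preset, 1e-9, 300.0)
        n_r = 1e5
        bound, internal = K.bound_trajectory(p, n_r, 300.0)
        r_ode, b_ode, c_ode = reference_ode(p, n_r, 300.0)
        assert bound == pytest.approx(b_ode, rel=1e-8)
        assert internal == pytest.approx(c_ode, rel=1e-8, abs=1e-8)
        assert r_ode + b_ode + c_ode == pytest.approx(n_r, rel=1e-8)

    def test_negative_time_rejected(self):
        p = K.KineticParams.from_preset("4C", 1e-9, 300.0)
        with pytest.raises(ValueError, match="negative time"):
            K.bound_trajectory(p, 1e5, -1.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            K.KineticParams.from_preset("20C", 1e-9, 1.0)


class TestReceptorDistribution:
    def test_discretized_mean_matches_gamma_moment(self):
        dist = K.ReceptorDistribution()
        nodes, w = K.receptor_pmf(dist, 2000)
        assert nodes @ w == pytest.approx(dist.a * dist.b, rel=1e-3)

    def test_cv_is_inverse_sqrt_shape(self):
        dist = K.ReceptorDistribution(a=3.34)
        assert dist.cv == pytest.approx(0.547, abs=0.003)
        nodes, w = K.receptor_pmf(dist, 4000)
        mean = nodes @ w
        sd = np.sqrt(((nodes - mean) ** 2) @ w)
        assert sd / mean == pytest.approx(dist.cv, rel=5e-3)

    def test_large_shape_concentrates(self):
        assert K.ReceptorDistribution(a=1e6).cv < 1e-2

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            K.receptor_pmf(K.ReceptorDistribution(), 50)


class TestPopulationDistribution:
    def test_degenerate_receptors_give_pure_poisson(self):
        """Near-zero receptor heterogeneity: CV -> 1/sqrt(mean)."""
        p = K.KineticParams.from_preset("4C", 0.3e-9, 300.0)
        dist = K.ReceptorDistribution(a=1e8, mean_nr=1e5)
        pop = K.population_distribution(p, dist)
        assert pop.cv == pytest.approx(1.0 / np.sqrt(pop.mean), rel=1e-3)

    def test_law_of_total_variance(self):
        p = K.KineticParams.from_preset("4C", 0.03e-9, 300.0)
        dist = K.ReceptorDistribution()
        nodes, w = K.receptor_pmf(dist, 2000)
        lam = K.mean_bound(p, nodes)
        mean_ref = lam @ w
        var_ref = lam @ w + ((lam - mean_ref) ** 2) @ w  # E[lam] + Var(lam)
        pop = K.population_distribution(p, dist)
        assert pop.mean == pytest.approx(mean_ref, rel=1e-9)
        assert pop.sd**2 == pytest.approx(var_ref, rel=1e-6)

    def test_cv_decreases_with_ligand_concentration(self):
        dist = K.ReceptorDistribution()
        cvs = []
        for egf0 in (0.03e-9, 0.3e-9, 3e-9):
            p = K.KineticParams.from_preset("4C", egf0, 300.0)
            cvs.append(K.population_distribution(p, dist).cv)
        assert cvs[0] > cvs[1] > cvs[2]

    def test_truncation_guard(self):
        p = K.KineticParams.from_preset("4C", 0.3e-9, 300.0)
        with pytest.raises(ValueError, match="widen support"):
            K.population_distribution(p, K.ReceptorDistribution(), n_max=20)

    @settings(deadline=None, max_examples=20)
    @given(
        egf0=st.floats(1e-12, 1e-8),
        a=st.floats(0.5, 20.0),
        t=st.floats(10.0, 1000.0),
    )
    def test_mixture_mean_is_total_expectation(self, egf0, a, t):
        p = K.KineticParams.from_preset("4C", egf0, t)
        dist = K.ReceptorDistribution(a=a, mean_nr=1e5)
        nodes, w = K.receptor_pmf(dist, 1000)
        mean_ref = K.mean_bound(p, nodes) @ w
        if mean_ref < 1e-3:
            return  # distribution collapses onto zero; nothing to compare
        pop = K.population_distribution(p, dist, n_nodes=1000)
        assert pop.mean == pytest.approx(mean_ref, rel=1e-6)


class TestSampleCells:
    def test_empty_and_deterministic(self):
        p = K.KineticParams.from_preset("4C", 0.3e-9, 300.0)
        dist = K.ReceptorDistribution()
        assert len(K.sample_cells(p, dist, 0, seed=1)) == 0
        a = K.sample_cells(p, dist, 1000, seed=7)
        b = K.sample_cells(p, dist, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_monte_carlo_cv_matches_quadrature(self):
        p = K.KineticParams.from_preset("4C", 0.3e-9, 300.0)
        dist = K.ReceptorDistribution()
        pop = K.population_distribution(p, dist)
        cells = K.sample_cells(p, dist, 100_000, seed=3)
        cv_mc = cells.std() / cells.mean()
        assert cv_mc == pytest.approx(pop.cv, rel=0.02)


class TestIsotherm:
    def test_percent_max_bound_endpoints(self):
        data = K.IsothermData(
            concentrations=np.array([1e-9, 1e-7]),
            total=np.array([50.0, 150.0]),
            nonspecific=np.array([50.0, 50.0]),
        )
        p = K.percent_max_bound(data)
        assert p[0] == 0.0 and p[1] == 100.0

    def test_langmuir_fit_recovers_exact_kd(self):
        c = np.array([0.1, 0.3, 1, 3, 10, 30, 100]) * 1e-9
        kd_true = 3.1e-9
        p = 100.0 * c / (kd_true + c)
        kd, bmax, *_ = K.fit_kd(c, p)
        assert kd == pytest.approx(kd_true, rel=1e-6)
        assert bmax == pytest.approx(100.0, rel=1e-6)
        # half-max property of the fitted curve
        assert bmax * kd / (kd + kd) == pytest.approx(bmax / 2)

    def test_langmuir_fit_under_noise(self):
        c = np.array([0.1, 0.3, 1, 3, 10, 30, 100]) * 1e-9
        kd_true = 3.1e-9
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            p = 100.0 * c / (kd_true + c) * (1 + rng.normal(0, 0.05, len(c)))
            kd, *_ = K.fit_kd(c, p)
            errs.append(abs(kd - kd_true) / kd_true)
        assert np.median(errs) < 0.15

    def test_weak_identifiability_warns(self):
        c = np.array([1, 2, 3, 4]) * 1e-12  # all far below K_D
        p = 100.0 * c / (3.1e-9 + c)
        with pytest.warns(UserWarning, match="weakly identified"):
            K.fit_kd(c, p)
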