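import numpy as np
import pytest

from polarphase._spectral import wrap
from polarphase.phase_dynamics import (
    DensityTable,
    NonGradientCouplingError,
    PhaseModelSpec,
    PhaseSignal,
    PhaseState,
    axial_asymmetry_rates,
    coupling_table,
    elongation_coefficient,
    gle_coupling,
    gle_signal_amplitude,
    harmonic_coupling,
    in_phase_effective_field,
    initial_phases,
    integrate_phase,
    noise_variance,
    order_parameter,
    phase_rhs,
    potential,
    stationary_density,
    two_cell_analysis,
)
from polarphase.reduction import gamma_from_fourier
from polarphase.tissue_geometry import TissueEdge, TissueGraph, chain, hex_sheet, hex_shape, winding

GLE_A = np.sin(np.pi / 3) / (4 * np.pi)
GLE_C = (np.pi / 3) / (4 * np.pi)


def _straight_pair_spec(**kw):
    return PhaseModelSpec(chain(2), gle_coupling(np.pi / 3), **kw)


class TestPhaseRHS:
    def test_in_phase_straight_pair_is_fixed_point(self):
        spec = _straight_pair_spec()
        np.testing.assert_allclose(phase_rhs(PhaseState([0.0, 0.0]), spec), 0.0, atol=1e-15)

    def test_signal_aligned_phase_is_stationary(self):
        spec = PhaseModelSpec(
            chain(2),
            harmonic_coupling(),  # no coupling terms
            signal=PhaseSignal(0.1, 0.8, amplitude=2.0),
        )
        np.testing.assert_allclose(phase_rhs(np.array([0.8, 0.8]), spec), 0.0, atol=1e-15)

    def test_gle_signal_amplitude(self):
        assert gle_signal_amplitude(0.2) == pytest.approx(1.0 / (2 * np.sqrt(0.8)))
        assert gle_signal_amplitude(0.2) == pytest.approx(0.559, abs=1e-3)

    def test_heterogeneity_scales_edge_terms(self):
        from polarphase.tissue_geometry import apply_heterogeneity

        tissue = apply_heterogeneity(chain(2), 0.5, [0.0, np.pi])
        spec = PhaseModelSpec(tissue, gle_coupling(np.pi / 3))
        base = phase_rhs(np.array([0.3, -0.2]), _straight_pair_spec())
        scaled = phase_rhs(np.array([0.3, -0.2]), spec)
        np.testing.assert_allclose(scaled, 1.5 * base, atol=1e-14)

    def test_missing_width_in_coupling_table(self):
        with pytest.raises(KeyError, match="width"):
            PhaseModelSpec(chain(2), {0.5: gle_coupling(0.5)})


class TestIntegratePhase:
    def test_two_cells_converge_to_origin(self):
        spec = _straight_pair_spec()
        traj = integrate_phase(spec, PhaseState([0.2, -0.15]), T=400.0)
        np.testing.assert_allclose(traj.phi[-1], 0.0, atol=1e-5)

    def test_global_rotational_covariance(self):
        chi = 1.1
        phi0 = np.array([0.4, -0.3, 0.9])
        tissue = chain(3)
        rotated_edges = [
            TissueEdge(e.i, e.j, wrap(e.eta + chi), e.d, e.alpha) for e in tissue.edges
        ]
        tissue_rot = TissueGraph(3, rotated_edges, kind="chain")
        g = gle_coupling(np.pi / 3)
        t1 = integrate_phase(
            PhaseModelSpec(tissue, g), PhaseState(phi0), T=100.0, rtol=1e-11, atol=1e-12
        )
        t2 = integrate_phase(
            PhaseModelSpec(tissue_rot, g), PhaseState(phi0 + chi), T=100.0, rtol=1e-11, atol=1e-12
        )
        assert np.max(np.abs(wrap(t2.phi - t1.phi - chi))) < 1e-8

    def test_stochastic_requires_seed(self):
        spec = _straight_pair_spec(noise=1e-3)
        with pytest.raises(ValueError, match="seed"):
            integrate_phase(spec, PhaseState([0.0, 0.0]), T=1.0)

    def test_stochastic_reproducible(self):
        spec = _straight_pair_spec(noise=1e-3)
        t1 = integrate_phase(spec, PhaseState([0.0, 0.0]), T=5.0, dt=0.01, seed=4)
        t2 = integrate_phase(spec, PhaseState([0.0, 0.0]), T=5.0, dt=0.01, seed=4)
        np.testing.assert_array_equal(t1.phi, t2.phi)


class TestOrderParameter:
    def test_aligned(self):
        Q, Phi = order_parameter(np.full(7, 0.3))
        assert Q == pytest.approx(1.0)
        assert Phi == pytest.approx(0.3)

    def test_antipodal_cancellation(self):
        Q, Phi = order_parameter(np.array([0.0, np.pi]), require_direction=False)
        assert Q == pytest.approx(0.0, abs=1e-15)
        assert np.isnan(Phi)
        with pytest.raises(ValueError, match="undefined"):
            order_parameter(np.array([0.0, np.pi]))

    def test_cube_roots_of_unity(self):
        Q, _ = order_parameter(np.array([0.0, 2 * np.pi / 3, -2 * np.pi / 3]), require_direction=False)
        assert Q == pytest.approx(0.0, abs=1e-15)


class TestPotential:
    def _spec(self):
        tissue = hex_sheet(4, 3, "periodic")
        return PhaseModelSpec(
            tissue,
            gle_coupling(np.pi / 3),
            eps=1.0,
            signal=PhaseSignal(0.05, 0.4, amplitude=0.7),
        )

    def test_gradient_identity(self, rng):
        spec = self._spec()
        h = 1e-6
        for _ in range(100):
            phi = rng.uniform(-np.pi, np.pi, size=spec.n_cells)
            rhs = phase_rhs(phi, spec)
            grad = np.empty_like(phi)
            for i in range(phi.size):
                e = np.zeros_like(phi)
                e[i] = h
                grad[i] = (potential(phi + e, spec) - potential(phi - e, spec)) / (2 * h)
            np.testing.assert_allclose(rhs, -grad, atol=1e-6)

    def test_gradient_identity_pure_inhibition_variant(self, ai_fd, rng):
        # b' family from the leading pure-inhibition coefficients
        gamma = gamma_from_fourier(ai_fd, np.pi / 3, kind="pure_inhibition", amp_tol=0.0)
        gamma = harmonic_coupling(a=gamma.a, b_prime=gamma.b_prime, c=gamma.c)
        spec = PhaseModelSpec(chain(3), gamma)
        h = 1e-6
        for _ in range(30):
            phi = rng.uniform(-np.pi, np.pi, size=3)
            rhs = phase_rhs(phi, spec)
            grad = np.array(
                [
                    (potential(phi + h * np.eye(3)[i], spec) - potential(phi - h * np.eye(3)[i], spec))
                    / (2 * h)
                    for i in range(3)
                ]
            )
            np.testing.assert_allclose(rhs, -grad, atol=1e-6)

    def test_xy_limit_rotation_invariance(self):
        spec = PhaseModelSpec(chain(3), harmonic_coupling(a=0.07))
        phi = np.array([0.2, -1.0, 2.2])
        assert potential(phi, spec) == pytest.approx(potential(phi + 0.77, spec), abs=1e-12)

    def test_straight_pair_prefers_axis_alignment(self):
        spec = _straight_pair_spec()
        assert potential(np.zeros(2), spec) < potential(np.array([np.pi / 2, np.pi / 2]), spec)

    def test_non_gradient_coupling_refused(self, ai_fd):
        gamma = gamma_from_fourier(ai_fd, np.pi / 3)  # has higher harmonics
        spec = PhaseModelSpec(chain(2), gamma)
        with pytest.raises(NonGradientCouplingError):
            potential(np.zeros(2), spec)


class TestStationaryDensity:
    def test_normalisation_and_marginals(self):
        spec = _straight_pair_spec(signal=PhaseSignal(2e-4, np.pi, gle_signal_amplitude(0.2)))
        dens = stationary_density(spec, nu=0.05, grid_n=90)
        dphi = 2 * np.pi / 90
        assert np.sum(dens.joint) * dphi**2 == pytest.approx(1.0, abs=1e-8)
        for m in dens.marginals:
            assert np.sum(m) * dphi == pytest.approx(1.0, abs=1e-8)

    def test_small_noise_concentrates_at_minimum(self):
        spec = _straight_pair_spec()
        dens = stationary_density(spec, nu=1e-3, grid_n=180)
        idx = np.unravel_index(np.argmax(dens.joint), dens.joint.shape)
        mode = np.array([dens.phi[idx[0]], dens.phi[idx[1]]])
        # minima of H are the in-phase axis states 0 / pi
        axis_dist = np.minimum(np.abs(wrap(mode)), np.abs(wrap(mode - np.pi)))
        assert np.max(axis_dist) < 2 * np.pi / 180 + 1e-9

    def test_large_systems_guarded(self):
        spec = PhaseModelSpec(chain(4), gle_coupling(np.pi / 3))
        with pytest.raises(ValueError, match="N <= 3"):
            stationary_density(spec, nu=0.1)


class TestTwoCellAnalysis:
    def test_gle_stability_pattern(self):
        res = {tuple(np.round(r["fixed_point"], 6)): r for r in two_cell_analysis(GLE_A, GLE_A, GLE_C)}
        assert res[(0.0, 0.0)]["stability"] == "stable"
        assert res[(round(np.pi, 6),) * 2]["stability"] == "stable"
        assert res[(round(np.pi / 2, 6),) * 2]["stability"] == "unstable"

    def test_sign_reversal_flips_stability(self):
        # a != b keeps all eigenvalues away from zero
        plus = two_cell_analysis(0.07, 0.05, GLE_C, eps=1.0)
        minus = two_cell_analysis(0.07, 0.05, GLE_C, eps=-1.0)
        for p, m in zip(plus, minus):
            np.testing.assert_allclose(p["eigenvalues"], [-x for x in m["eigenvalues"]])
            # eigenvalues negate: stable nodes become unstable and vice versa
            # (saddles remain unstable)
            if p["stability"] == "stable":
                assert m["stability"] == "unstable"
            if m["stability"] == "stable":
                assert p["stability"] == "unstable"
        assert any(p["stability"] == "stable" for p in plus)

    def test_pure_inhibition_limit(self):
        # b = 0: stability of (0,0) requires eps*a > 0 and eps*c > 0
        res = two_cell_analysis(GLE_A, 0.0, GLE_C)[0]
        np.testing.assert_allclose(res["eigenvalues"], [-2 * GLE_C, -2 * GLE_A])
        assert res["stability"] == "stable"

    def test_agrees_with_numerical_jacobian(self):
        spec = _straight_pair_spec()
        h = 1e-7
        for r in two_cell_analysis(GLE_A, GLE_A, GLE_C):
            phi_star = np.array(r["fixed_point"])
            J = np.empty((2, 2))
            for i in range(2):
                e = np.zeros(2)
                e[i] = h
                J[:, i] = (phase_rhs(phi_star + e, spec) - phase_rhs(phi_star - e, spec)) / (2 * h)
            np.testing.assert_allclose(
                np.sort(np.linalg.eigvals(J).real), np.sort(r["eigenvalues"]), atol=1e-6
            )


class TestInPhaseEffectiveField:
    def test_regular_bulk_vanishes(self):
        t = hex_sheet(4, 4, "periodic")
        R, _ = in_phase_effective_field(t, coupling_table(t, gle_coupling))
        np.testing.assert_allclose(R, 0.0, atol=1e-14)

    def test_elongated_bulk(self):
        delta = np.pi / 3 - np.pi / 10
        t = hex_sheet(4, 4, "periodic", hex_shape(delta))
        R, eta_bar = in_phase_effective_field(t, coupling_table(t, gle_coupling))
        lam = elongation_coefficient(delta)
        assert lam < 0
        np.testing.assert_allclose(R, 2 * abs(lam), atol=1e-12)
        # axis defined modulo pi: +-pi/2 is the same axis
        np.testing.assert_allclose(np.abs(wrap(2 * (eta_bar - np.pi / 2))) / 2, 0.0, atol=1e-12)

    def test_strip_boundary_cell_parallel_to_boundary(self):
        # one open row: every cell misses its three upper/lower neighbours
        t = hex_sheet(1, 6, "open")
        R, eta_bar = in_phase_effective_field(t, coupling_table(t, gle_coupling))
        interior = [i for i in range(6) if len(t.neighbors(i)) == 2]
        for i in interior:
            assert R[i] > 0
            assert eta_bar[i] == pytest.approx(0.0, abs=1e-12)


class TestAxialAsymmetryRates:
    def test_regular_hexagon_is_neutral(self):
        assert abs(elongation_coefficient(np.pi / 3)) < 1e-12

    def test_shrunk_axis_edges_give_negative_lambda(self):
        assert elongation_coefficient(np.pi / 3 - np.pi / 10) < 0
        assert elongation_coefficient(np.pi / 3 + np.pi / 10) > 0

    def test_heterogeneity_rate_value(self):
        rate = axial_asymmetry_rates(alpha=0.1, b=np.sqrt(3) / (8 * np.pi), c=1.0 / 12.0)
        assert rate["heterogeneity_rate"] == pytest.approx(0.0305, abs=2e-4)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            axial_asymmetry_rates()
        with pytest.raises(ValueError):
            axial_asymmetry_rates(alpha=0.1)


class TestNoiseVariance:
    def test_gle_closed_form(self):
        from polarphase.models import make_model
        from polarphase.reduction import reduce_cell

        cell = reduce_cell(make_model("gle", D0=0.2), n_theta=128)
        nu = noise_variance([0.005, 0.005], cell.Z0)
        assert nu == pytest.approx(0.005 / (2 * np.pi * 0.8), rel=1e-8)
        assert nu == pytest.approx(9.947e-4, abs=1e-6)

    def test_zero_and_linearity(self, gle_cell):
        assert noise_variance([0.0, 0.0], gle_cell.Z0) == 0.0
        nu1 = noise_variance([0.003, 0.001], gle_cell.Z0)
        nu2 = noise_variance([0.006, 0.002], gle_cell.Z0)
        assert nu2 == pytest.approx(2 * nu1, rel=1e-12)


class TestInitialPhases:
    def test_uniform_reproducible_and_centred(self):
        s1 = initial_phases("uniform", 1200, seed=9, lo=-0.5, hi=0.5)
        s2 = initial_phases("uniform", 1200, seed=9, lo=-0.5, hi=0.5)
        np.testing.assert_array_equal(s1.phi, s2.phi)
        assert abs(np.mean(s1.phi)) < 0.05
        assert np.all((s1.phi >= -0.5) & (s1.phi < 0.5))

    def test_constant(self):
        np.testing.assert_array_equal(initial_phases("constant", 4, phi0=np.pi / 4).phi, np.pi / 4)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            initial_phases("uniform", 3, seed=0, lo=0.5, hi=0.5)


class TestChainInPhaseStability:
    @pytest.mark.parametrize("n", [3, 5, 10])
    @pytest.mark.parametrize("boundary", ["open", "periodic"])
    def test_all_eigenvalues_negative(self, n, boundary):
        spec = PhaseModelSpec(chain(n, boundary), gle_coupling(np.pi / 3))
        J = _numerical_jacobian(spec, np.zeros(n))
        assert np.max(np.linalg.eigvals(J).real) < -1e-6

    def test_xy_limit_has_single_neutral_mode(self):
        spec = PhaseModelSpec(chain(5, "periodic"), harmonic_coupling(a=GLE_A))
        eigs = np.sort(np.linalg.eigvals(_numerical_jacobian(spec, np.zeros(5))).real)
        assert abs(eigs[-1]) < 1e-7  # global rotation
        assert eigs[-2] < -1e-6


def _numerical_jacobian(spec, phi_star, h=1e-7):
    n = phi_star.size
    J = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        J[:, i] = (phase_rhs(phi_star + e, spec) - phase_rhs(phi_star - e, spec)) / (2 * h)
    return J


class TestNoiseValidation:
    def test_single_cell_phase_diffusion_variance(self):
        # Var[phi(t)] = nu * t for an uncoupled noisy phase, 2000 replicas
        nu = 9.947e-4
        t_final, dt = 50.0, 0.01
        rng = np.random.default_rng(123)
        n_steps = int(round(t_final / dt))
        phi = np.zeros(2000)
        for _ in range(n_steps):
            phi += np.sqrt(nu * dt) * rng.standard_normal(2000)
        assert np.var(phi) == pytest.approx(nu * t_final, rel=0.05)


class TestWindingAlignment:
    def test_boundary_phases_follow_local_tangent(self):
        path = ["E"] * 6 + ["NE"] * 6 + ["E"] * 6 + ["SE"] * 6 + ["E"] * 5
        tissue = winding(path)
        spec = PhaseModelSpec(tissue, gle_coupling(np.pi / 3))
        init = initial_phases("uniform", tissue.n_cells, seed=3, lo=-np.pi / 2, hi=np.pi / 2)
        traj = integrate_phase(spec, init, T=1000.0, rtol=1e-8, t_eval=np.array([0.0, 1000.0]))
        phi = traj.phi[-1]
        for i in range(tissue.n_cells):
            z = sum(np.exp(2j * e.eta) for e in tissue.neighbors(i))
            tangent = np.angle(z) / 2
            axial_dev = abs(wrap(2 * (phi[i] - tangent))) / 2
            assert np.degrees(axial_dev) < 15.0
        # defect-free: no large jump between consecutive cells
        assert np.max(np.abs(wrap(np.diff(phi)))) < np.pi / 2
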