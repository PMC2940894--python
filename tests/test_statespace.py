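"""State-space construction, eigen-analysis, equilibria and Euler simulation."""

import numpy as np
import pytest

from grncontrol import statespace
from grncontrol.fixtures import load_fixture_network
from grncontrol.statespace import (
    DivergenceError,
    StateSpaceModel,
    build_negative_feedback,
    build_simple_regulation,
    build_six_node,
    eigen_analysis,
    equilibrium,
    from_network,
    simulate,
    vector_field,
)
from grncontrol.tf import reduce_network


@pytest.fixture
def nf_model():
    """Negative feedback loop with the standard rates (equilibrium (200, 800))."""
    return build_negative_feedback(d_y=0.01, d_z=0.01, f_yz=0.04, f_zy=0.01, drive=10.0)


class TestBuilders:
    def test_simple_regulation_matches_closed_form(self):
        model = build_simple_regulation(f=0.04, d=0.01, x=250.0)
        res = simulate(model, [0.0], t_end=400.0, h=0.01)
        closed = (0.04 * 250 / 0.01) * (1 - np.exp(-0.01 * res.t))
        assert np.allclose(res["y"], closed, rtol=1e-3, atol=0.05)

    def test_stepped_production_is_causal(self):
        f = lambda t: 0.0 if t < 100.0 else 0.05
        model = build_simple_regulation(f=f, d=0.01, x=200.0)
        res = simulate(model, [0.0], t_end=300.0, h=0.5)
        assert np.all(res["y"][res.t <= 100.0] == 0.0)
        assert res["y"][-1] > 0

    def test_zero_degradation_is_pure_integrator(self):
        model = build_simple_regulation(f=0.05, d=0.0, x=100.0)
        res = simulate(model, [0.0], t_end=100.0, h=0.1)
        assert np.allclose(res["y"], 5.0 * res.t, rtol=1e-9)

    def test_decoupled_cascade_has_real_eigenvalues(self):
        A = np.array([[-0.01, 0.0], [0.04, -0.02]])
        model = StateSpaceModel(A=A, B=np.eye(2), u=np.array([1.0, 0.0]), labels=("y", "z"))
        ana = eigen_analysis(model)
        assert not ana.oscillatory
        assert np.allclose(sorted(ana.eigenvalues.real), [-0.02, -0.01])

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            StateSpaceModel(A=np.eye(2), B=np.eye(3), u=np.zeros(3), labels=("a", "b"))


class TestEigenAnalysis:
    def test_negative_feedback_is_underdamped_and_stable(self, nf_model):
        ana = eigen_analysis(nf_model)
        assert np.allclose(np.sort_complex(ana.eigenvalues), [-0.01 - 0.02j, -0.01 + 0.02j])
        assert ana.stable and ana.oscillatory
        assert "underdamped" in ana.verdict and "stable" in ana.verdict

    def test_eigenpairs_satisfy_definition(self, nf_model):
        ana = eigen_analysis(nf_model)
        A = nf_model.A_at(0.0)
        for lam, phi in zip(ana.eigenvalues, ana.eigenvectors.T):
            assert np.allclose(A @ phi, lam * phi, atol=1e-9)

    def test_diagonal_matrix_eigenvalues(self):
        d = np.array([0.01, 0.03, 0.2])
        model = StateSpaceModel(A=np.diag(-d), B=np.eye(3), u=np.zeros(3), labels=("a", "b", "c"))
        assert np.allclose(sorted(eigen_analysis(model).eigenvalues.real), sorted(-d))

    @pytest.mark.parametrize("fixture_name", ["negative_feedback", "oscillator", "irma4"])
    def test_eigenvalues_equal_reduced_tf_poles(self, fixture_name):
        spec = load_fixture_network(fixture_name)
        ana = eigen_analysis(from_network(spec))
        p = reduce_network(spec).poles()
        assert np.allclose(np.sort_complex(ana.eigenvalues), np.sort_complex(p), atol=1e-8)


class TestEquilibrium:
    def test_negative_feedback_converges_to_200_800(self, nf_model):
        eq = equilibrium(nf_model)
        assert np.allclose(eq.concentrations, [200.0, 800.0])
        assert eq.as_dict() == {"y": pytest.approx(200.0), "z": pytest.approx(800.0)}

    def test_zero_input_equilibrium_is_origin(self):
        model = build_negative_feedback(0.01, 0.01, 0.04, 0.01, drive=0.0)
        assert np.allclose(equilibrium(model).concentrations, [0.0, 0.0])

    def test_invariant_under_state_reordering(self, nf_model):
        A = nf_model.A_at(0.0)
        perm = np.array([[0, 1], [1, 0]])
        swapped = StateSpaceModel(A=perm @ A @ perm, B=np.eye(2), u=perm @ nf_model.u, labels=("z", "y"))
        eq = equilibrium(swapped)
        assert eq.as_dict()["y"] == pytest.approx(200.0)
        assert eq.as_dict()["z"] == pytest.approx(800.0)

    def test_singular_matrix_rejected(self):
        model = StateSpaceModel(A=np.zeros((1, 1)), B=np.eye(1), u=np.array([1.0]), labels=("y",))
        with pytest.raises(ValueError, match="singular"):
            equilibrium(model)


class TestSimulate:
    def test_converges_from_400_400_with_damped_oscillation(self, nf_model):
        res = simulate(nf_model, [400.0, 400.0], t_end=1500.0, h=0.1)
        assert np.allclose(res.states[-1], [200.0, 800.0], rtol=5e-3)
        # damped oscillation: both trajectories cross their equilibrium value
        assert res["y"].min() < 200.0 < res["y"].max()
        assert res["z"].min() < 800.0 or res["z"].max() > 800.0

    def test_first_order_convergence_in_step_size(self, nf_model):
        exact = _modal_solution(nf_model, np.array([400.0, 400.0]), np.array([200.0]))[0]
        errs = []
        for h in (0.8, 0.4, 0.2):
            res = simulate(nf_model, [400.0, 400.0], t_end=200.0, h=h)
            errs.append(np.abs(res.states[-1] - exact).max())
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all((1.6 < ratios) & (ratios < 2.4))

    def test_matches_modal_solution(self, nf_model):
        """Trajectories equal the eigen-mode expansion C1 e^{l1 t} phi1 + C2 e^{l2 t} phi2 + s_eq."""
        t_grid = np.linspace(0.0, 600.0, 61)
        modal = _modal_solution(nf_model, np.array([400.0, 400.0]), t_grid)
        res = simulate(nf_model, [400.0, 400.0], t_end=600.0, h=0.01)
        sim_at = np.array([res.states[np.searchsorted(res.t, tv)] for tv in t_grid])
        assert np.allclose(sim_at, modal, rtol=0, atol=1e-4 * np.abs(modal).max())

    def test_superposition(self, nf_model):
        A = nf_model.A_at(0.0)
        u1, u2 = np.array([10.0, 0.0]), np.array([0.0, 3.0])
        out = []
        for u in (u1, u2, u1 + u2):
            m = StateSpaceModel(A=A, B=np.eye(2), u=u, labels=("y", "z"))
            out.append(simulate(m, [0.0, 0.0], t_end=300.0, h=0.5).states)
        assert np.allclose(out[0] + out[1], out[2], rtol=1e-9, atol=1e-9)

    def test_unstable_step_warns_and_divergence_raises(self):
        model = build_simple_regulation(f=0.05, d=2.0, x=100.0)
        with pytest.warns(RuntimeWarning, match="stability bound"):
            with pytest.raises(DivergenceError):
                simulate(model, [1e300], t_end=1e4, h=10.0)

    def test_negative_states_flagged_not_clamped(self):
        model = build_negative_feedback(0.01, 0.01, 0.04, 0.01, drive=0.0)
        res = simulate(model, [0.0, 500.0], t_end=200.0, h=0.1)
        assert res.went_negative
        assert res["y"].min() < 0.0


class TestSixNode:
    def test_c_rises_after_b(self):
        spec = load_fixture_network("six_node")
        model = build_six_node(spec)
        res = simulate(model, np.zeros(6), t_end=2000.0, h=0.5)
        from grncontrol.fixtures import half_rise_time

        assert half_rise_time(res.t, res["C"]) > half_rise_time(res.t, res["B"])

    def test_zero_input_stays_at_zero(self):
        spec = load_fixture_network("six_node")
        model = build_six_node(spec, drive=0.0)
        res = simulate(model, np.zeros(6), t_end=200.0, h=1.0)
        assert np.all(res.states == 0.0)

    def test_removing_direct_ffl_edge_changes_c_not_b(self):
        spec = load_fixture_network("six_node")
        pruned = spec.model_dump()
        pruned["edges"] = [
            e for e in pruned["edges"] if not (e["source"] == "A" and e["target"] == "C")
        ]
        from grncontrol.network import NetworkSpec

        base = simulate(from_network(spec), np.zeros(6), t_end=500.0, h=1.0)
        cut = simulate(from_network(NetworkSpec.model_validate(pruned)), np.zeros(6), t_end=500.0, h=1.0)
        assert np.allclose(base["B"], cut["B"])
        assert not np.allclose(base["C"], cut["C"])

    def test_wiring_without_ffl_rejected(self):
        spec = load_fixture_network("six_node")
        data = spec.model_dump()
        data["edges"] = [e for e in data["edges"] if e["source"] != "B"]
        from grncontrol.network import NetworkSpec

        with pytest.raises(ValueError, match="feedforward"):
            build_six_node(NetworkSpec.model_validate(data))


class TestVectorField:
    def test_arrow_vanishes_at_equilibrium(self, nf_model):
        X, Y, U, V = vector_field(nf_model, [200.0], [800.0])
        assert abs(U[0, 0]) < 1e-12 and abs(V[0, 0]) < 1e-12

    def test_arrows_tangent_to_trajectory(self, nf_model):
        res = simulate(nf_model, [400.0, 400.0], t_end=400.0, h=0.05)
        idx = np.arange(200, 7000, 400)
        for i in idx:
            tangent = res.states[i + 1] - res.states[i - 1]
            field = nf_model.derivative(res.t[i], res.states[i])
            cos = np.dot(tangent, field) / (np.linalg.norm(tangent) * np.linalg.norm(field))
            assert cos > 0.99

    def test_all_trajectories_share_endpoint(self, nf_model):
        finals = []
        for s0 in ([400.0, 400.0], [0.0, 0.0], [900.0, 100.0]):
            res = simulate(nf_model, s0, t_end=3000.0, h=0.25)
            finals.append(res.states[-1])
        assert np.allclose(finals, [200.0, 800.0], rtol=1e-3)


def _modal_solution(model, s0, t_grid):
    """Independent oracle: eigen-expansion of the affine linear system."""
    A = model.A_at(0.0)
    b = model.B @ model.u_at(0.0)
    s_eq = np.linalg.solve(A, -b)
    lam, phi = np.linalg.eig(A)
    coeffs = np.linalg.solve(phi, s0 - s_eq)
    out = np.array(
        [np.real(phi @ (coeffs * np.exp(lam * tv))) + s_eq for tv in np.atleast_1d(t_grid)]
    )
    return out
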