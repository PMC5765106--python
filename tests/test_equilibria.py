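"""Fixed-point enumeration, closed-form spectra, and winner points."""

from math import comb

import numpy as np
import pytest

from starwta import (CouplingParams, ModelParams, ReducedState,
                     enumerate_Pk, eigenvalues_Pk, jacobian, phi_star_bound,
                     saddle_Slj, solve_Ql, stability_conditions)
from starwta.dynamics import rhs_reduced
from starwta.equilibria import (ExistenceRegionError, classify_spectrum,
                                neutral_line_P0)


@pytest.mark.parametrize("n", [1, 2, 3])
def test_enumeration_counts_and_residuals(n, coupling_default):
    p = ModelParams(omega=np.full(n, 5.0), b=-1.0, coupling=coupling_default)
    points = enumerate_Pk(p)
    assert len(points) == 2 ** n
    for k in range(n + 1):
        assert sum(1 for q in points if q.k == k) == comb(n, k)
    # exact up to sin(float(pi)) ~ 1e-16 times the amplitudes
    assert all(q.residual < 1e-14 for q in points)
    for q in points:
        assert set(np.round(q.state.phi, 12)) <= {0.0, round(np.pi, 12)}
        assert set(q.state.a) <= {p.c, p.c + p.gamma}


def test_enumeration_requires_identical_frequencies(params_n3):
    with pytest.raises(ValueError):
        enumerate_Pk(params_n3)


def test_no_winner_spectrum(params_n3_identical):
    # one neutral direction, n contracting phase directions at rate -b*g'(pi),
    # n amplitude directions at rate -beta
    rep = eigenvalues_Pk(0, params_n3_identical)
    lam = np.sort(rep.eigenvalues.real)
    assert np.allclose(lam, [-1, -1, -1, -0.05, -0.05, -0.05, 0.0])
    assert rep.classification == "neutral"


def test_single_winner_spectrum(params_n3_identical):
    rep = eigenvalues_Pk(1, params_n3_identical)
    lam = np.sort(rep.eigenvalues.real)
    # quadratic pair from sigma_1 = (c+gamma)*nu = 240 with n*b*g'(0) = -3
    expected_pair = sorted(
        -(1 / 6) * (237 + s * np.sqrt(237 ** 2 - 4 * 3 * 240)) for s in (1, -1))
    assert lam[0] == pytest.approx(expected_pair[0])          # ~ -77.974
    assert lam[0] == pytest.approx(-77.974, abs=1e-3)
    assert lam[1] == pytest.approx(-1.0260, abs=1e-4)
    assert rep.classification == "stable"


def test_intermediate_points_are_saddles(params_n3_identical):
    rep = eigenvalues_Pk(2, params_n3_identical)
    re = rep.eigenvalues.real
    assert np.any(np.isclose(re, 1.0))    # -b*g'(0) with b = -1
    assert np.any(np.isclose(re, -1.0))   # -b*g'(pi)
    assert rep.classification == "saddle"


def test_stability_conditions_match_printed_inequalities(coupling_default):
    # b < 0, n small: the winner point is stable since (c+gamma)*nu > n|b|
    p = ModelParams(omega=np.full(3, 5.0), b=-1.0, coupling=coupling_default)
    assert stability_conditions(1, p)["stable"]
    assert not stability_conditions(3, p)["stable"]
    assert stability_conditions(0, p)["neutral"]
    # too many POs: n >= (c+gamma)*nu/|b| = 240 destroys the winner point
    p_big = ModelParams(omega=np.full(240, 5.0), b=-1.0,
                        coupling=coupling_default)
    assert not stability_conditions(1, p_big)["stable"]
    # b > 0: full synchrony is the stable point instead
    p_pos = ModelParams(omega=np.full(3, 5.0), b=1.0, coupling=coupling_default)
    assert stability_conditions(3, p_pos)["stable"]
    assert not stability_conditions(1, p_pos)["stable"]


def test_conditions_agree_with_spectra_for_small_networks(coupling_default):
    # exhaustive agreement between the algebraic verdict and the spectrum
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(2, 6))
        p = ModelParams(omega=np.full(n, rng.uniform(1, 9)),
                        b=rng.choice([-1, 1]) * rng.uniform(0.1, 3),
                        alpha=rng.uniform(0.1, 2), beta=rng.uniform(0.01, 1),
                        gamma=rng.uniform(1, 12), c=rng.uniform(0.5, 4),
                        coupling=CouplingParams(nu=rng.uniform(2, 40)))
        stable_ks = [k for k in range(n + 1)
                     if eigenvalues_Pk(k, p).classification == "stable"]
        for k in (0, 1, n):
            rep = stability_conditions(k, p)
            assert rep["stable"] == (k in stable_ks), (k, p)
        for k in range(2, n):
            assert eigenvalues_Pk(k, p).classification == "saddle"


def test_jacobian_matches_finite_differences(coupling_default):
    rng = np.random.default_rng(7)
    n = 4
    p = ModelParams(omega=rng.uniform(4, 6, n), b=-1.3, alpha=0.8, beta=0.1,
                    gamma=8.0, c=1.5, coupling=coupling_default)
    state = ReducedState(phi=rng.uniform(-3, 3, n), omega0=5.1,
                         a=rng.uniform(1, 10, n))
    J = jacobian(state, p)
    assert J.shape == (2 * n + 1, 2 * n + 1)
    y0 = state.to_array()
    step = 1e-7
    J_num = np.empty_like(J)
    for j in range(y0.size):
        yp, ym = y0.copy(), y0.copy()
        yp[j] += step
        ym[j] -= step
        J_num[:, j] = (rhs_reduced(ReducedState.from_array(yp, n), p).to_array()
                       - rhs_reduced(ReducedState.from_array(ym, n), p).to_array()
                       ) / (2 * step)
    assert np.max(np.abs(J - J_num)) < 1e-6
    # amplitude block is -beta * identity at any state
    assert np.allclose(np.diag(J[n + 1:, n + 1:]), -p.beta)


def test_closed_form_spectra_match_numerical_jacobian(coupling_default):
    # randomized parameters, all winner counts, n up to 8
    rng = np.random.default_rng(42)
    for _ in range(8):
        n = int(rng.integers(2, 9))
        p = ModelParams(omega=np.full(n, rng.uniform(2, 8)),
                        b=rng.choice([-1, 1]) * rng.uniform(0.2, 2),
                        alpha=rng.uniform(0.2, 2), beta=rng.uniform(0.02, 0.5),
                        gamma=rng.uniform(2, 12), c=rng.uniform(0.5, 4),
                        coupling=CouplingParams(nu=rng.uniform(2, 30)))
        for k in range(n + 1):
            winners = tuple(range(k))
            phi = np.where(np.arange(n) < k, 0.0, np.pi)
            a = np.where(np.arange(n) < k, p.c + p.gamma, p.c)
            state = ReducedState(phi=phi, omega0=p.omega[0], a=a)
            numeric = np.sort_complex(np.linalg.eigvals(jacobian(state, p)))
            closed = np.sort_complex(eigenvalues_Pk(k, p).eigenvalues)
            assert np.max(np.abs(numeric - closed)) < 1e-8, (n, k)


def test_winner_point_with_identical_frequencies_is_symmetric(
        params_n3_identical):
    q = solve_Ql(params_n3_identical, 1)
    c, g = params_n3_identical.c, params_n3_identical.gamma
    assert np.allclose(q.state.phi, [np.pi, 0.0, np.pi], atol=1e-9)
    assert np.allclose(q.state.a, [c, c + g, c], atol=1e-9)
    assert q.state.omega0 == pytest.approx(5.0, abs=1e-9)


def test_perturbed_winner_point(params_n3):
    q = solve_Ql(params_n3, 0)
    assert q.residual < 1e-10
    # loser phases near pi - arcsin(detuning/b); winner phase ~ 0
    assert abs(q.state.phi[0]) < 1e-5
    assert q.state.phi[1] == pytest.approx(np.pi + np.arcsin(0.5), abs=0.01)
    assert q.state.phi[2] == pytest.approx(np.pi - np.arcsin(0.8), abs=0.01)
    assert q.state.omega0 == pytest.approx(5.0, abs=0.01)
    assert np.allclose(q.state.a, [12.0, 2.0, 2.0], atol=0.01)
    assert q.stability.classification == "stable"
    # the a-priori bound on the winner phase holds at the solved point
    assert abs(q.state.phi[0]) <= q.phi_star


def test_winner_phase_bound_for_large_networks(coupling_default):
    rng = np.random.default_rng(5)
    omega = 5.0 + rng.uniform(-0.45, 0.45, 100)
    omega[0] = 5.0
    p = ModelParams(omega=omega, b=-1.0, coupling=coupling_default)
    q = solve_Ql(p, 0)
    assert abs(q.state.phi[0]) < 1e-5
    assert q.stability.classification == "stable"


@pytest.mark.parametrize("n, nu, expected", [
    (2, 2.0, np.pi * (1 - np.sqrt(3) / 2)),   # closed form of the bisection
    (100, 20.0, 1.483e-5),
    (1, 20.0, 0.0),
])
def test_phi_star_bound(n, nu, expected, coupling_default):
    p = ModelParams(omega=np.full(n, 5.0), b=-1.0,
                    coupling=CouplingParams(nu=nu))
    assert phi_star_bound(p) == pytest.approx(expected, rel=1e-3, abs=1e-12)


def test_existence_region_violation_names_the_pair(coupling_default):
    p = ModelParams(omega=np.array([5.0, 5.5, 3.5]), b=-1.0,
                    coupling=coupling_default)
    with pytest.raises(ExistenceRegionError, match="omega_3"):
        solve_Ql(p, 0)


def test_saddle_companion_has_one_unstable_direction(params_n3):
    s = saddle_Slj(params_n3, 0, 2)
    assert s.residual < 1e-10
    # the flipped coordinate sits on the arcsin branch near 0
    assert s.state.phi[2] == pytest.approx(np.arcsin(0.8), abs=0.01)
    re = s.stability.eigenvalues.real
    tol = 1e-9 * np.max(np.abs(s.stability.eigenvalues))
    assert np.sum(re > tol) == 1
    # the unstable eigenvalue is -b*cos(phi_j)
    assert np.max(re) == pytest.approx(np.cos(np.arcsin(0.8)), abs=0.01)


def test_winner_and_saddle_merge_at_the_existence_boundary(coupling_default):
    # as the detuning approaches |b| the two points collide (saddle-node)
    gaps = []
    for eps in (0.2, 0.1, 0.05):
        omega = np.array([5.0, 5.0 - (1.0 - eps)])
        p = ModelParams(omega=omega, b=-1.0, coupling=coupling_default)
        q = solve_Ql(p, 0)
        s = saddle_Slj(p, 0, 1)
        gaps.append(abs(q.state.phi[1] - s.state.phi[1]))
    assert gaps[0] > gaps[1] > gaps[2]


def test_neutral_line_through_no_winner_point(params_n3_identical):
    p = params_n3_identical
    on_point = neutral_line_P0(p, 5.0)
    assert np.allclose(on_point.phi, np.pi)
    # near the no-winner point the f-tail is below machine precision and
    # the line is stationary in phase and frequency; amplitude velocity is
    # exactly zero wherever h vanishes at the line's phase
    for omega0 in (5.0, 4.7, 5.3):
        state = neutral_line_P0(p, omega0)
        ds = rhs_reduced(state, p)
        assert np.max(np.abs(ds.phi)) < 1e-12
        assert abs(ds.omega0) < 1e-12
        assert np.max(np.abs(ds.a)) == 0.0
    # toward the end of the segment the tail of f grows but stays small
    far = rhs_reduced(neutral_line_P0(p, 4.01), p)
    assert np.max(np.abs(far.phi)) < 1e-4
    assert np.max(np.abs(far.a)) == 0.0
    with pytest.raises(ValueError):
        neutral_line_P0(p, 2.0)


def test_spectrum_classifier_thresholds():
    assert classify_spectrum(np.array([-1.0, -2.0])) == "stable"
    assert classify_spectrum(np.array([-1.0, 1e-12])) == "neutral"
    assert classify_spectrum(np.array([-1.0, 0.5])) == "saddle"
    assert classify_spectrum(np.array([2.0, 0.5])) == "unstable"
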