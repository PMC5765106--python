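"""Fixed points of the phase-difference system and their stability.

With identical PO frequencies the system has 2**n fixed points P_k: any
subset of k POs in phase with the CO (amplitude c + gamma), the rest in
antiphase (amplitude c).  Their spectra are known in closed form, and the
classification is sharp: P_n (full synchrony) is the stable point for
b > 0, the n points P_1 (winner-take-all) are stable for b < 0 in the
band -(c+gamma)*f'(0)/n < b < 0, P_0 (no winner) is neutrally stable
along one direction, and every other P_k is a saddle.

Perturbing the frequencies (|omega_i - omega_l| < |b|) deforms each P_1
into a winner point Q_l with loser phases pi - arcsin((omega_i-omega_l)/b),
accompanied by saddles S_lj on the other arcsin branch; their collision
at |omega_i - omega_l| = |b| is the saddle-node that sets a loser phase
running (SNIC/SNIT bifurcations, see `starwta.regimes`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize

from .coupling import f_deriv, f_eval, g_deriv, h_deriv, x_extrema
from .dynamics import ModelParams, ReducedState, integrate, rhs_reduced

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "enumerate_Pk",
    "eigenvalues_Pk",
    "stability_conditions",
    "jacobian",
    "solve_Ql",
    "saddle_Slj",
    "phi_star_bound",
    "neutral_line_P0",
    "classify_spectrum",
    "ExistenceRegionError",
    "SolverError",
]

ZERO_EIG_RTOL = 1e-9


class ExistenceRegionError(ValueError):
    """A frequency detuning violates the |omega_l - omega_i| < |b| region."""


class SolverError(RuntimeError):
    """The fixed-point solver failed to converge."""


@dataclass
class StabilityReport:
    """Spectrum of the (2n+1)-dim Jacobian and its sign classification."""

    eigenvalues: np.ndarray
    classification: str          # stable | saddle | unstable | neutral
    p: float                     # f'(0)
    q0: float                    # g'(0)
    qpi: float                   # g'(pi)
    sigma_k: float | None = None  # f'(0) * sum of in-phase amplitudes

    @property
    def n_unstable(self) -> int:
        tol = ZERO_EIG_RTOL * max(1.0, np.max(np.abs(self.eigenvalues)))
        return int(np.sum(self.eigenvalues.real > tol))


@dataclass
class Equilibrium:
    """A located fixed point of the phase-difference system."""

    label: str                   # e.g. "P_1", "Q_2", "S_1,3", "P0_perturbed"
    state: ReducedState
    residual: float
    k: int | None = None         # winner count for P_k points
    winner: int | None = None    # 0-based winner index for Q_l / S_lj
    phi_star: float | None = None  # a-priori winner-phase bound when applicable
    stability: StabilityReport | None = None


def classify_spectrum(eigenvalues: np.ndarray) -> str:
    """Sign-pattern classification with a relative zero threshold.

    Any eigenvalue within ``1e-9 * spectral_radius`` of the imaginary
    axis makes the point ``neutral`` (never ``stable``): the no-winner
    point P_0 must classify as neutral despite all other directions
    being contracting.
    """
    lam = np.asarray(eigenvalues)
    tol = ZERO_EIG_RTOL * max(1.0, float(np.max(np.abs(lam))))
    re = lam.real
    if np.any(np.abs(re) <= tol):
        return "neutral"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def _require_identical(p: ModelParams) -> float:
    if not np.allclose(p.omega, p.omega[0], rtol=0, atol=0):
        raise ValueError("operation requires identical PO frequencies")
    return float(p.omega[0])


def _pk_state(p: ModelParams, winners: tuple[int, ...], omega: float) -> ReducedState:
    phi = np.full(p.n, np.pi)
    a = np.full(p.n, p.c)
    for i in winners:
        phi[i] = 0.0
        a[i] = p.c + p.gamma
    return ReducedState(phi=phi, omega0=omega, a=a)


def _residual(state: ReducedState, p: ModelParams) -> float:
    return float(np.max(np.abs(rhs_reduced(state, p).to_array())))


def enumerate_Pk(p: ModelParams, max_n: int = 16) -> list[Equilibrium]:
    """All 2**n symmetric fixed points, grouped by winner count k.

    Each subset of POs sits at phase 0 with amplitude c + gamma, the
    complement at pi with amplitude c, and omega0 equals the common
    natural frequency.  Requires identical PO frequencies.
    """
    omega = _require_identical(p)
    if p.n > max_n:
        raise ValueError(f"enumeration of 2^{p.n} points refused (max_n={max_n})")
    points = []
    for k in range(p.n + 1):
        for winners in combinations(range(p.n), k):
            state = _pk_state(p, winners, omega)
            points.append(Equilibrium(
                label=f"P_{k}", state=state, k=k,
                residual=_residual(state, p),
                stability=eigenvalues_Pk(k, p)))
    return points


def eigenvalues_Pk(k: int, p: ModelParams) -> StabilityReport:
    """Closed-form spectrum of P_k.

    For k >= 1: (k-1) copies of -b*g'(0), (n-k) copies of -b*g'(pi), the
    quadratic pair

        -(1/2n) * (s + n*b*g'(0) +- sqrt((s + n*b*g'(0))**2 - 4*n*alpha*s)),

    with s = k*(c+gamma)*f'(0), and n copies of -beta.  For k = 0 the
    pair degenerates to one zero eigenvalue (the neutral direction of the
    no-winner point) plus n copies of -b*g'(pi).
    """
    _require_identical(p)
    n = p.n
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pf = p.coupling.nu            # f'(0)
    q0 = 1.0                      # g'(0) for g = sin
    qpi = -1.0                    # g'(pi)
    b = p.b
    lam = [-p.beta] * n
    if k == 0:
        lam += [0.0] + [-b * qpi] * n
        sigma_k = 0.0
    else:
        sigma_k = k * (p.c + p.gamma) * pf
        disc = (sigma_k + n * b * q0) ** 2 - 4 * n * p.alpha * sigma_k
        root = np.sqrt(complex(disc))
        pair = [(-1.0 / (2 * n)) * ((sigma_k + n * b * q0) + s * root)
                for s in (+1.0, -1.0)]
        lam += [-b * q0] * (k - 1) + [-b * qpi] * (n - k) + pair
    eig = np.array(lam, dtype=complex)
    return StabilityReport(eigenvalues=eig, classification=classify_spectrum(eig),
                           p=pf, q0=q0, qpi=qpi, sigma_k=sigma_k)


def stability_conditions(k: int, p: ModelParams) -> dict:
    """Evaluate the printed stability inequalities for P_k.

    P_n (full synchrony) is stable iff n >= 2, b > 0,
    (c+gamma)*f'(0) + b*g'(0) > 0 and alpha*(c+gamma)*f'(0) > 0; P_1
    (winner-take-all) iff b < 0, (c+gamma)*f'(0) + n*b*g'(0) > 0 and
    alpha*(c+gamma)*f'(0) > 0.  Intermediate P_k are saddles always;
    P_0 is neutral for b < 0.  The verdict here is algebraic and agrees
    with the sign pattern of `eigenvalues_Pk` off the bifurcation sets.
    """
    _require_identical(p)
    n, b = p.n, p.b
    pf, q0 = p.coupling.nu, 1.0
    cg = p.c + p.gamma
    report = {"k": k, "n": n}
    if k == n == 1:
        # single PO: in-phase locking is possible for either sign of b
        conds = {"coupling_dominates": cg * pf + b * q0 > 0,
                 "adaptation_positive": p.alpha * cg * pf > 0}
    elif k == n and n >= 2:
        conds = {"b_positive": b > 0,
                 "coupling_dominates": cg * pf + b * q0 > 0,
                 "adaptation_positive": p.alpha * cg * pf > 0}
    elif k == 1:
        conds = {"b_negative": b < 0,
                 "coupling_dominates": cg * pf + n * b * q0 > 0,
                 "adaptation_positive": p.alpha * cg * pf > 0}
    elif k == 0:
        conds = {"b_negative": b < 0}
        report["note"] = "neutral along one direction when stable"
    else:
        conds = {"never_stable": False}
        report["note"] = "saddle for any parameter values"
    report["conditions"] = conds
    report["stable"] = all(conds.values()) and not (k == 0)
    report["neutral"] = (k == 0) and all(conds.values())
    return report


def jacobian(state: ReducedState, p: ModelParams) -> np.ndarray:
    """Analytic (2n+1) x (2n+1) Jacobian of the phase-difference system."""
    n = p.n
    cp = p.coupling
    phi, a = state.phi, state.a
    fv = np.array([f_eval(x, cp) for x in phi])
    fpv = np.array([f_deriv(x, cp) for x in phi])
    gpv = np.cos(phi)
    hpv = np.array([h_deriv(x, cp) for x in phi])

    J = np.zeros((2 * n + 1, 2 * n + 1))
    # phase rows: - delta_ij * b*g'(phi_i) - a_j f'(phi_j)/n ; d/domega0 = -1
    J[:n, :n] = -np.tile(a * fpv / n, (n, 1))
    J[np.arange(n), np.arange(n)] += -p.b * gpv
    J[:n, n] = -1.0
    J[:n, n + 1:] = -np.tile(fv / n, (n, 1))
    # omega0 row
    J[n, :n] = p.alpha * a * fpv / n
    J[n, n + 1:] = p.alpha * fv / n
    # amplitude rows
    J[n + 1:, :n][np.arange(n), np.arange(n)] = p.beta * p.gamma * hpv
    J[n + 1:, n + 1:][np.arange(n), np.arange(n)] = -p.beta
    return J


def _report_from_jacobian(state: ReducedState, p: ModelParams) -> StabilityReport:
    eig = np.linalg.eigvals(jacobian(state, p))
    return StabilityReport(eigenvalues=eig, classification=classify_spectrum(eig),
                           p=p.coupling.nu, q0=1.0, qpi=-1.0)


def _check_existence(p: ModelParams, l: int) -> None:
    if p.b >= 0:
        raise ValueError("winner points require b < 0")
    det = np.abs(p.omega - p.omega[l])
    worst = int(np.argmax(det))
    if det[worst] >= abs(p.b):
        raise ExistenceRegionError(
            f"|omega_{l + 1} - omega_{worst + 1}| = {det[worst]:.6g} >= |b| = "
            f"{abs(p.b):.6g}: the stationary winner point does not exist")


def _ql_seed(p: ModelParams, l: int, saddle_j: int | None = None) -> ReducedState:
    phi = np.pi - np.arcsin((p.omega - p.omega[l]) / p.b)
    phi[l] = 0.0
    if saddle_j is not None:
        phi[saddle_j] = np.arcsin((p.omega[saddle_j] - p.omega[l]) / p.b)
    a = np.full(p.n, p.c)
    a[l] = p.c + p.gamma
    return ReducedState(phi=phi, omega0=float(p.omega[l]), a=a)


def _solve_fixed_point(p: ModelParams, seed: ReducedState,
                       tol: float = 1e-10) -> ReducedState:
    n = p.n

    def fun(y):
        return rhs_reduced(ReducedState.from_array(y, n), p).to_array()

    def jac(y):
        return jacobian(ReducedState.from_array(y, n), p)

    y0 = seed.to_array()
    sol = optimize.root(fun, y0, jac=jac, method="hybr", tol=1e-13)
    state = ReducedState.from_array(sol.x, n)
    if _residual(state, p) > tol:
        # fall back: relax toward the attractor, then re-solve
        traj = integrate(p, seed, 50.0)
        sol = optimize.root(fun, traj.state_at(-1).to_array(), jac=jac,
                            method="hybr", tol=1e-13)
        state = ReducedState.from_array(sol.x, n)
        if _residual(state, p) > tol:
            raise SolverError(
                f"fixed-point residual {_residual(state, p):.3g} above {tol:.1g}")
    state.phi = np.asarray(_wrap_near(state.phi, seed.phi))
    return state


def _wrap_near(phi: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Shift each phase by multiples of 2pi to land nearest the reference."""
    return phi - 2 * np.pi * np.round((phi - ref) / (2 * np.pi))


def solve_Ql(p: ModelParams, l: int) -> Equilibrium:
    """Solve for the stationary winner point Q_l (PO ``l`` wins, 0-based).

    Newton-type iteration on the fixed-point equations, seeded from the
    perturbative approximation (winner phase 0, loser phases
    ``pi - arcsin((omega_i - omega_l)/b)``, omega0 = omega_l, amplitudes
    c + gamma / c).  Requires b < 0 and every detuning inside the
    existence region |omega_i - omega_l| < |b|.
    """
    _check_existence(p, l)
    state = _solve_fixed_point(p, _ql_seed(p, l))
    report = _report_from_jacobian(state, p)
    return Equilibrium(label=f"Q_{l + 1}", state=state,
                       residual=_residual(state, p), winner=l,
                       phi_star=phi_star_bound(p), stability=report)


def saddle_Slj(p: ModelParams, l: int, j: int) -> Equilibrium:
    """Solve for the saddle companion S_l,j of the winner point Q_l.

    Identical to Q_l except the j-th loser phase sits on the other
    arcsin branch (``arcsin((omega_j - omega_l)/b)``, near 0 rather than
    near pi).  In the stability region of Q_l it has exactly one
    unstable direction, along phi_j, with eigenvalue -b*cos(phi_j).
    """
    if j == l:
        raise ValueError("saddle index j must differ from winner l")
    _check_existence(p, l)
    state = _solve_fixed_point(p, _ql_seed(p, l, saddle_j=j))
    report = _report_from_jacobian(state, p)
    return Equilibrium(label=f"S_{l + 1},{j + 1}", state=state,
                       residual=_residual(state, p), winner=l,
                       stability=report)


def phi_star_bound(p: ModelParams) -> float:
    """A-priori bound on the winner phase |phi_l| of any Q_l.

    Solves f(x) = (n-1)*sin(2**(-nu) * pi) on the increasing branch
    [0, x_max] by bracketing.  If the right side exceeds 1 the bound is
    vacuous and x_max is returned.  For n = 1 the loser sum is empty and
    the bound is 0.
    """
    nu = p.coupling.nu
    if p.n == 1:
        return 0.0
    target = (p.n - 1) * np.sin(2.0 ** (-nu) * np.pi)
    x_max, _ = x_extrema(p.coupling)
    if target >= 1.0:
        return float(x_max)
    cp = p.coupling
    return float(optimize.brentq(lambda x: f_eval(x, cp) - target,
                                 0.0, x_max, xtol=1e-15))


def neutral_line_P0(p: ModelParams, omega0_tilde: float) -> ReducedState:
    """A point of the neutral line L(omega0~) through the no-winner state.

    With identical frequencies omega, the set phi_i = pi - arcsin((omega
    - omega0~)/b), omega0 = omega0~, a_i = c is stationary in the phase
    and frequency components wherever h vanishes (|phi - pi| < pi - mu),
    so simulations perceive it as a line of fixed points.  Requires
    |(omega - omega0~)/b| <= 1.
    """
    omega = _require_identical(p)
    r = (omega - omega0_tilde) / p.b
    if abs(r) > 1.0:
        raise ValueError(f"|(omega - omega0)/b| = {abs(r):.6g} > 1: "
                         "no antiphase-locked solution")
    phi = np.full(p.n, np.pi - np.arcsin(r))
    return ReducedState(phi=phi, omega0=float(omega0_tilde),
                        a=np.full(p.n, p.c))
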