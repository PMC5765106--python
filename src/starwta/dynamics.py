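"""Model definition and trajectory integration.

The network is a star: one central oscillator (CO) with phase ``theta0``
and adaptive natural frequency ``omega0``, and ``n`` peripheral
oscillators (POs) with phases ``theta_i`` and natural frequencies
``omega_i``.  The CO is driven by the POs through adaptive amplitudes
``a_i`` and the odd coupling ``f``; each PO is pulled by the CO with
fixed strength ``b`` through ``g = sin``; amplitudes relax at rate
``beta`` toward ``c + gamma*h(theta_i - theta0)``, so phase proximity to
the CO is rewarded; ``omega0`` drifts at rate ``alpha`` toward the CO's
instantaneous frequency.

Winner-take-all competition requires ``b < 0`` (desynchronizing pull):
exactly one PO can then lock in phase with the CO and saturate its
amplitude at ``c + gamma`` while the others are pushed toward antiphase
and decay to ``c``.

Because the system is invariant under a common phase shift, analysis is
done in the phase differences ``phi_i = theta_i - theta0``, which yields
a (2n+1)-dimensional autonomous system.  Both forms are available and
integrate to matching trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .coupling import CouplingParams

__all__ = [
    "ModelParams",
    "FullState",
    "ReducedState",
    "Trajectory",
    "rhs_full",
    "rhs_reduced",
    "integrate",
    "torus_flow_rhs",
    "torus_fixed_points",
    "torus_rotation_frequency",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the adaptive stepper cannot continue."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (at t = {t:.6g})")
        self.t = t


@dataclass(frozen=True)
class ModelParams:
    """Everything defining the ODE system.

    Parameters
    ----------
    omega : array of float
        Natural frequencies of the n POs (rad/time).
    b : float
        CO-to-PO coupling strength; negative for WTA competition.
    alpha : float
        Frequency-adaptation rate of the CO (> 0).
    beta : float
        Amplitude-adaptation rate of the POs (> 0).
    gamma : float
        Resonance gain; the winning amplitude saturates at ``c + gamma``.
    c : float
        Baseline amplitude of non-resonant POs (> 0).
    coupling : CouplingParams
        Shape parameters of (f, g, h).
    """

    omega: np.ndarray
    b: float
    alpha: float = 1.0
    beta: float = 0.05
    gamma: float = 10.0
    c: float = 2.0
    coupling: CouplingParams = field(default_factory=lambda: CouplingParams(nu=20.0))

    def __post_init__(self) -> None:
        omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if omega.ndim != 1 or omega.size < 1 or not np.all(np.isfinite(omega)):
            raise ValueError("omega must be a finite vector with n >= 1 entries")
        object.__setattr__(self, "omega", omega)
        for name in ("alpha", "beta", "gamma", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")

    @property
    def n(self) -> int:
        return int(self.omega.size)

    def with_omega(self, omega) -> "ModelParams":
        return replace(self, omega=np.asarray(omega, dtype=float))

    def _kernel_args(self):
        cp = self.coupling
        return (self.omega, self.b, self.alpha, self.beta, self.gamma,
                self.c, cp.nu, cp.mu, cp.sigma)


@dataclass
class FullState:
    """State of the full (2n+2)-dimensional system."""

    theta0: float
    theta: np.ndarray
    omega0: float
    a: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.theta0], self.theta, [self.omega0], self.a))

    @classmethod
    def from_array(cls, y: np.ndarray, n: int) -> "FullState":
        return cls(theta0=float(y[0]), theta=y[1:n + 1].copy(),
                   omega0=float(y[n + 1]), a=y[n + 2:].copy())

    def reduce(self) -> "ReducedState":
        """Pass to phase differences phi_i = theta_i - theta0."""
        return ReducedState(phi=self.theta - self.theta0,
                            omega0=self.omega0, a=self.a.copy())


@dataclass
class ReducedState:
    """State of the phase-difference system: (phi, omega0, a)."""

    phi: np.ndarray
    omega0: float
    a: np.ndarray

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))

    def to_array(self) -> np.ndarray:
        return np.concatenate((self.phi, [self.omega0], self.a))

    @classmethod
    def from_array(cls, y: np.ndarray, n: int) -> "ReducedState":
        return cls(phi=y[:n].copy(), omega0=float(y[n]), a=y[n + 1:].copy())


@dataclass
class Trajectory:
    """Densely sampled solution in phase-difference coordinates.

    ``phi`` is unwrapped (accumulated on the real line) so that winding
    of loser phases can be detected; ``phi_wrapped`` reduces it to
    ``[-pi, pi)``.  For full-system runs the CO phase is retained in
    ``theta0``.
    """

    times: np.ndarray
    phi: np.ndarray          # shape (m, n), unwrapped
    omega0: np.ndarray       # shape (m,)
    a: np.ndarray            # shape (m, n)
    theta0: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.phi.shape[1]

    @property
    def phi_wrapped(self) -> np.ndarray:
        return _kernels.reduce_angle(self.phi)

    def state_at(self, index: int) -> ReducedState:
        return ReducedState(phi=self.phi[index].copy(),
                            omega0=float(self.omega0[index]),
                            a=self.a[index].copy())

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean sample mask for t in [t_start, t_end]."""
        return (self.times >= t_start) & (self.times <= t_end)

    def to_text(self, path, params: ModelParams | None = None) -> None:
        """Export as a delimited table with a commented header."""
        n = self.n
        cols = (["t"]
                + [f"phi_wrapped_{i + 1}" for i in range(n)]
                + [f"phi_unwrapped_{i + 1}" for i in range(n)]
                + ["omega0"]
                + [f"a_{i + 1}" for i in range(n)])
        data = np.column_stack([self.times, self.phi_wrapped, self.phi,
                                self.omega0, self.a])
        header = ""
        if params is not None:
            cp = params.coupling
            header += (f"model: n={params.n} b={params.b!r} alpha={params.alpha!r} "
                       f"beta={params.beta!r} gamma={params.gamma!r} c={params.c!r}\n")
            header += (f"coupling: nu={cp.nu!r} mu={cp.mu!r} sigma={cp.sigma!r}\n")
            header += "omega: " + " ".join(repr(w) for w in params.omega) + "\n"
        header += "\t".join(cols)
        np.savetxt(path, data, delimiter="\t", header=header,
                   fmt="%.12g")


def _check_state(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")


def rhs_reduced(state: ReducedState, p: ModelParams) -> ReducedState:
    """Time derivative of the phase-difference system.

    dphi_i/dt  = omega_i - omega0 - b*g(phi_i) - (1/n) sum_j a_j f(phi_j)
    domega0/dt = (alpha/n) sum_j a_j f(phi_j)
    da_i/dt    = beta*(-a_i + c + gamma*h(phi_i))
    """
    y = state.to_array()
    _check_state(y)
    out = np.empty_like(y)
    _kernels.rhs_reduced(y, out, *p._kernel_args())
    return ReducedState.from_array(out, p.n)


def rhs_full(state: FullState, p: ModelParams) -> FullState:
    """Time derivative of the full system in oscillator phases.

    dtheta0/dt = omega0 + (1/n) sum_j a_j f(theta_j - theta0)
    dtheta_i/dt = omega_i + b*g(theta0 - theta_i)
    domega0/dt = (alpha/n) sum_j a_j f(theta_j - theta0)
    da_i/dt    = beta*(-a_i + c + gamma*h(theta_i - theta0))
    """
    y = state.to_array()
    _check_state(y)
    out = np.empty_like(y)
    _kernels.rhs_full(y, out, *p._kernel_args())
    return FullState.from_array(out, p.n)


def integrate(p: ModelParams, s0, t_end: float, *,
              rtol: float = 1e-8, atol: float = 1e-10,
              sample_dt: float = 0.1) -> Trajectory:
    """Integrate from ``s0`` to ``t_end`` with dense sampling.

    The system (full or reduced) is selected by the type of ``s0``.
    Phases are integrated unwrapped; the adaptive Dormand-Prince stepper
    lands exactly on the sample grid, so runs with identical inputs are
    bit-identical.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be positive")

    if isinstance(s0, FullState):
        kind, dim_extra = 1, 2
    elif isinstance(s0, ReducedState):
        kind, dim_extra = 0, 1
    else:
        raise TypeError("s0 must be a FullState or ReducedState")
    y0 = s0.to_array()
    _check_state(y0)
    n = p.n
    if y0.size != 2 * n + dim_extra:
        raise ValueError("state dimension does not match params")

    if t_end == 0.0:
        times = np.array([0.0])
    else:
        m = int(np.floor(t_end / sample_dt + 1e-9))
        times = np.linspace(0.0, m * sample_dt, m + 1)
        if times[-1] < t_end - 1e-9:
            times = np.append(times, t_end)

    Y, status, t_fail = _kernels.integrate_rk45(
        kind, y0, times, *p._kernel_args(), rtol, atol)
    if status == _kernels.STEP_UNDERFLOW:
        raise IntegrationError("step size underflow", t_fail)
    if status == _kernels.MAX_STEPS:
        raise IntegrationError("maximum step count exceeded", t_fail)

    if kind == 1:
        theta0 = Y[:, 0]
        phi = Y[:, 1:n + 1] - theta0[:, None]
        return Trajectory(times=times, phi=phi, omega0=Y[:, n + 1],
                          a=Y[:, n + 2:], theta0=theta0.copy())
    return Trajectory(times=times, phi=Y[:, :n], omega0=Y[:, n],
                      a=Y[:, n + 1:])


# ---------------------------------------------------------------------------
# Approximate flow on the loser torus
# ---------------------------------------------------------------------------

def torus_flow_rhs(phi, detuning, b: float):
    """Decoupled circle flow for loser phases: dphi_i/dt = Omega_i - b*sin(phi_i).

    ``detuning`` holds Omega_i = omega_i - omega_l relative to the winner l
    (the winner's own coordinate is excluded).  Valid once the winner has
    locked and amplitudes have relaxed, so each loser phase obeys an
    independent sine circle flow.
    """
    phi = np.asarray(phi, dtype=float)
    detuning = np.asarray(detuning, dtype=float)
    return detuning - b * np.sin(phi)


def torus_fixed_points(detuning: float, b: float):
    """Fixed points of one circle-flow coordinate, or None if it runs.

    For |Omega/b| <= 1 returns ``(arcsin(Omega/b), pi - arcsin(Omega/b))``
    (the saddle-side and node-side roots of Omega = b*sin(phi)).
    """
    r = detuning / b
    if abs(r) > 1.0:
        return None
    s = float(np.arcsin(r))
    return (s, np.pi - s)


def torus_rotation_frequency(detuning: float, b: float) -> float:
    """Mean winding rate of a running circle-flow coordinate.

    Zero in the locked regime |Omega| <= |b|; otherwise the classical
    ``sign(Omega) * sqrt(Omega**2 - b**2)``.
    """
    if abs(detuning) <= abs(b):
        return 0.0
    return float(np.sign(detuning) * np.sqrt(detuning ** 2 - b ** 2))
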