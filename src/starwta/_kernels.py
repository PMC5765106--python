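"""Compiled numeric kernels: coupling functions, right-hand sides, RK45 stepper.

Everything here operates on flat float64 arrays so the whole integration loop
stays inside compiled code.  The public modules (`coupling`, `dynamics`) wrap
these kernels with validation and structured types.

State packing conventions:

* reduced system (dimension 2n+1): ``y = [phi_1..phi_n, omega0, a_1..a_n]``
* full system (dimension 2n+2): ``y = [theta0, theta_1..theta_n, omega0, a_1..a_n]``

Phases are kept unwrapped (on the real line); the coupling kernels reduce
their arguments to one period internally.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
LOG_PI = np.log(np.pi)

# integration status codes
OK = 0
STEP_UNDERFLOW = 1
MAX_STEPS = 2


@njit(cache=True)
def reduce_angle(x):
    """Map a real angle to the principal interval [-pi, pi)."""
    return x - TWO_PI * np.floor((x + np.pi) / TWO_PI)


@njit(cache=True)
def f_scalar(x, nu):
    """Odd 2pi-periodic interaction function with steepness nu at 0.

    On [0, pi] it is sin(|x - pi|^nu / pi^(nu-1)); the power term is
    evaluated in log form so steepness up to several hundred neither
    overflows nor underflows.  Exact zeros are returned at the seams.
    """
    y = reduce_angle(x)
    s = 1.0
    if y < 0.0:
        s = -1.0
        y = -y
    if y == 0.0:
        return 0.0
    d = np.pi - y
    if d <= 0.0:
        return 0.0
    u = np.exp(nu * np.log(d) - (nu - 1.0) * LOG_PI)
    return s * np.sin(u)


@njit(cache=True)
def fp_scalar(x, nu):
    """Analytic derivative of ``f_scalar`` (even function of x)."""
    y = reduce_angle(x)
    if y < 0.0:
        y = -y
    if y == 0.0:
        return nu
    d = np.pi - y
    if d <= 0.0:
        # one-sided limits at |x| = pi agree and vanish for nu > 1
        return 0.0
    u = np.exp(nu * np.log(d) - (nu - 1.0) * LOG_PI)
    dudy = -nu * np.exp((nu - 1.0) * (np.log(d) - LOG_PI))
    return np.cos(u) * dudy


@njit(cache=True)
def h_scalar(x, mu, sigma):
    """Even resonance window: ((mu^2-x^2)/mu^2)^sigma inside |x|<mu, else 0."""
    y = reduce_angle(x)
    if y < 0.0:
        y = -y
    if y >= mu:
        return 0.0
    t = (mu * mu - y * y) / (mu * mu)
    return t ** sigma


@njit(cache=True)
def hp_scalar(x, mu, sigma):
    """Analytic derivative of ``h_scalar`` (odd function of x)."""
    y = reduce_angle(x)
    ay = abs(y)
    if ay >= mu:
        return 0.0
    if y == 0.0:
        return 0.0
    t = (mu * mu - y * y) / (mu * mu)
    return -2.0 * sigma * y / (mu * mu) * t ** (sigma - 1.0)


@njit(cache=True)
def rhs_reduced(y, out, omega, b, alpha, beta, gamma, c, nu, mu, sigma):
    """Phase-difference system: d/dt of [phi, omega0, a]."""
    n = omega.shape[0]
    mean_drive = 0.0
    for j in range(n):
        mean_drive += y[n + 1 + j] * f_scalar(y[j], nu)
    mean_drive /= n
    omega0 = y[n]
    for i in range(n):
        out[i] = omega[i] - omega0 - b * np.sin(y[i]) - mean_drive
    out[n] = alpha * mean_drive
    for i in range(n):
        out[n + 1 + i] = beta * (-y[n + 1 + i] + c
                                 + gamma * h_scalar(y[i], mu, sigma))


@njit(cache=True)
def rhs_full(y, out, omega, b, alpha, beta, gamma, c, nu, mu, sigma):
    """Full system in oscillator phases: d/dt of [theta0, theta, omega0, a]."""
    n = omega.shape[0]
    theta0 = y[0]
    mean_drive = 0.0
    for j in range(n):
        mean_drive += y[n + 2 + j] * f_scalar(y[1 + j] - theta0, nu)
    mean_drive /= n
    omega0 = y[n + 1]
    out[0] = omega0 + mean_drive
    for i in range(n):
        out[1 + i] = omega[i] + b * np.sin(theta0 - y[1 + i])
    out[n + 1] = alpha * mean_drive
    for i in range(n):
        out[n + 2 + i] = beta * (-y[n + 2 + i] + c
                                 + gamma * h_scalar(y[1 + i] - theta0, mu, sigma))


@njit(cache=True)
def _eval_rhs(kind, y, out, omega, b, alpha, beta, gamma, c, nu, mu, sigma):
    if kind == 0:
        rhs_reduced(y, out, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
    else:
        rhs_full(y, out, omega, b, alpha, beta, gamma, c, nu, mu, sigma)


@njit(cache=True)
def integrate_rk45(kind, y0, sample_times, omega, b, alpha, beta, gamma, c,
                   nu, mu, sigma, rtol, atol):
    """Adaptive Dormand-Prince 5(4) integration with exact sample landing.

    Steps are clipped so the solver lands exactly on every requested sample
    time (no interpolation), which keeps repeated runs bit-identical.
    Returns ``(Y, status, t_fail)`` where ``Y[k]`` is the state at
    ``sample_times[k]``.
    """
    dim = y0.shape[0]
    m = sample_times.shape[0]
    Y = np.empty((m, dim))
    y = y0.copy()
    t = sample_times[0]
    Y[0] = y

    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    k5 = np.empty(dim)
    k6 = np.empty(dim)
    k7 = np.empty(dim)
    ytmp = np.empty(dim)
    ynew = np.empty(dim)

    _eval_rhs(kind, y, k1, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
    h = 1e-4
    max_steps = 50_000_000
    steps = 0

    for idx in range(1, m):
        t_target = sample_times[idx]
        while t < t_target:
            steps += 1
            if steps > max_steps:
                return Y, MAX_STEPS, t
            if h < 1e-13:
                return Y, STEP_UNDERFLOW, t
            clipped = False
            if t + h >= t_target:
                h = t_target - t
                clipped = True

            # Dormand-Prince stages (k1 is FSAL from previous step)
            for i in range(dim):
                ytmp[i] = y[i] + h * (0.2 * k1[i])
            _eval_rhs(kind, ytmp, k2, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
            for i in range(dim):
                ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
            _eval_rhs(kind, ytmp, k3, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
            for i in range(dim):
                ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                      + 32.0 / 9.0 * k3[i])
            _eval_rhs(kind, ytmp, k4, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
            for i in range(dim):
                ytmp[i] = y[i] + h * (19372.0 / 6561.0 * k1[i]
                                      - 25360.0 / 2187.0 * k2[i]
                                      + 64448.0 / 6561.0 * k3[i]
                                      - 212.0 / 729.0 * k4[i])
            _eval_rhs(kind, ytmp, k5, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
            for i in range(dim):
                ytmp[i] = y[i] + h * (9017.0 / 3168.0 * k1[i]
                                      - 355.0 / 33.0 * k2[i]
                                      + 46732.0 / 5247.0 * k3[i]
                                      + 49.0 / 176.0 * k4[i]
                                      - 5103.0 / 18656.0 * k5[i])
            _eval_rhs(kind, ytmp, k6, omega, b, alpha, beta, gamma, c, nu, mu, sigma)
            for i in range(dim):
                ynew[i] = y[i] + h * (35.0 / 384.0 * k1[i]
                                      + 500.0 / 1113.0 * k3[i]
                                      + 125.0 / 192.0 * k4[i]
                                      - 2187.0 / 6784.0 * k5[i]
                                      + 11.0 / 84.0 * k6[i])
            _eval_rhs(kind, ynew, k7, omega, b, alpha, beta, gamma, c, nu, mu, sigma)

            # embedded 4th-order error estimate
            err = 0.0
            for i in range(dim):
                e = h * (71.0 / 57600.0 * k1[i]
                         - 71.0 / 16695.0 * k3[i]
                         + 71.0 / 1920.0 * k4[i]
                         - 17253.0 / 339200.0 * k5[i]
                         + 22.0 / 525.0 * k6[i]
                         - 1.0 / 40.0 * k7[i])
                sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
                err += (e / sc) ** 2
            err = np.sqrt(err / dim)

            if err <= 1.0:
                if clipped:
                    t = t_target
                else:
                    t += h
                for i in range(dim):
                    y[i] = ynew[i]
                    k1[i] = k7[i]
                if err == 0.0:
                    fac = 5.0
                else:
                    fac = min(5.0, max(0.2, 0.9 * err ** -0.2))
                h *= fac
            else:
                h *= max(0.2, 0.9 * err ** -0.2)
        Y[idx] = y
    return Y, OK, t
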