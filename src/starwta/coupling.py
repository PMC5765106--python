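"""The 2pi-periodic interaction functions of the star network.

Three functions shape the interaction between the central oscillator (CO)
and the peripheral oscillators (POs):

* ``f`` — odd, drives the CO and its frequency adaptation; a single maximum
  at ``x_max = pi*(1 - 2**(-1/nu))`` with ``f(x_max) = 1`` and slope
  ``f'(0) = nu``.  Large ``nu`` pushes the extremum toward 0 and flattens
  ``f`` around the antiphase point pi, which is what lets loser POs sit
  near antiphase without disturbing the CO.
* ``g`` — odd, the sine; mediates the CO's pull on each PO.
* ``h`` — even, a compactly supported window of half-width ``mu`` and
  sharpness ``sigma``; rewards phase proximity to the CO by raising the
  PO's coupling amplitude toward ``c + gamma``.

All evaluators accept scalars or arrays, reduce their argument to
``[-pi, pi)``, and are numerically safe for exponents up to several
hundred (log-form powering; exact zeros at the piecewise seams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "CouplingParams",
    "f_eval",
    "f_deriv",
    "g_eval",
    "g_deriv",
    "h_eval",
    "h_deriv",
    "x_extrema",
    "validate_coupling",
    "AxiomReport",
]


@dataclass(frozen=True)
class CouplingParams:
    """Shape parameters of the interaction functions.

    Parameters
    ----------
    nu : float
        Steepness of ``f`` at 0 (also its slope there).  Must exceed 1 so
        that ``f'(pi) = 0``.
    mu : float
        Half-width of the support of ``h``, in radians, in (0, pi).
    sigma : float
        Sharpness exponent of ``h``; at least 1 so ``h'(+-mu) = 0``.
        The regime of interest has ``sigma >> 1``.
    """

    nu: float
    mu: float = 1.0
    sigma: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.nu) or self.nu <= 1.0:
            raise ValueError(f"nu must be finite and > 1, got {self.nu}")
        if not np.isfinite(self.mu) or not 0.0 < self.mu < np.pi:
            raise ValueError(f"mu must lie in (0, pi), got {self.mu}")
        if not np.isfinite(self.sigma) or self.sigma < 1.0:
            raise ValueError(f"sigma must be >= 1, got {self.sigma}")


def _apply(kernel, x, *args):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angle argument must be finite")
    if x.ndim == 0:
        return float(kernel(float(x), *args))
    out = np.empty_like(x)
    flat_in = x.ravel()
    flat_out = out.ravel()
    for i in range(flat_in.size):
        flat_out[i] = kernel(flat_in[i], *args)
    return out


def f_eval(x, p: CouplingParams):
    """Evaluate the interaction function ``f`` at angle(s) ``x``."""
    return _apply(_kernels.f_scalar, x, p.nu)


def f_deriv(x, p: CouplingParams):
    """Analytic derivative ``f'``; seam values are one-sided limits."""
    return _apply(_kernels.fp_scalar, x, p.nu)


def g_eval(x):
    """The PO phase-pulling function, ``g(x) = sin x``."""
    return np.sin(x)


def g_deriv(x):
    """``g'(x) = cos x``; in particular g'(0) = 1 and g'(pi) = -1."""
    return np.cos(x)


def h_eval(x, p: CouplingParams):
    """Evaluate the resonance window ``h`` at angle(s) ``x``."""
    return _apply(_kernels.h_scalar, x, p.mu, p.sigma)


def h_deriv(x, p: CouplingParams):
    """Analytic derivative ``h'``; zero outside the support ``|x| < mu``."""
    return _apply(_kernels.hp_scalar, x, p.mu, p.sigma)


def x_extrema(p: CouplingParams) -> tuple[float, float]:
    """Locations of the maximum and minimum of ``f``.

    Returns ``(x_max, x_min) = (pi*(1 - 2**(-1/nu)), -x_max)``;
    ``f(x_max) = 1`` exactly and ``x_max`` decreases to 0 as nu grows.
    """
    x_max = np.pi * (1.0 - 2.0 ** (-1.0 / p.nu))
    return x_max, -x_max


@dataclass
class AxiomReport:
    """Pass/fail record of the numeric axiom checks on (f, g, h)."""

    checks: dict[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


def validate_coupling(p: CouplingParams, grid_size: int = 1024, *,
                      f=None, g=None, h=None,
                      tol: float = 1e-9) -> AxiomReport:
    """Numerically verify the structural axioms of the coupling triplet.

    Checks, on a fixed symmetric grid plus the analytic seam points:
    oddness of f and g, evenness of h, the boundary slopes
    (f'(0) > 0, f'(pi) = 0, g'(0) > 0, g'(pi) < 0, h'(0) = h'(pi) = 0),
    the normalization h(0) = 1, h(pi) = 0, absence of interior zeros of
    f and g on (0, pi), and monotonicity of h on [0, pi].

    ``f``, ``g``, ``h`` may be overridden (callables of one angle) to
    audit externally supplied functions; defaults are the package's own.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8")
    if f is None:
        f = lambda x: f_eval(x, p)  # noqa: E731
    if g is None:
        g = g_eval
    if h is None:
        h = lambda x: h_eval(x, p)  # noqa: E731

    x = np.linspace(-np.pi, np.pi, grid_size)
    interior = x[(x > 0) & (x < np.pi)]
    eps = 1e-7

    def num_deriv(fn, x0):
        return (fn(x0 + eps) - fn(x0 - eps)) / (2 * eps)

    fx = np.asarray(f(x))
    gx = np.asarray(g(x))
    hx = np.asarray(h(x))
    # h on the closed half-period, seam points included
    xh = np.linspace(0.0, np.pi, grid_size)
    hxh = np.asarray(h(xh))

    checks = {
        "f_odd": bool(np.max(np.abs(fx + np.asarray(f(-x)))) < tol),
        "g_odd": bool(np.max(np.abs(gx + np.asarray(g(-x)))) < tol),
        "h_even": bool(np.max(np.abs(hx - np.asarray(h(-x)))) < tol),
        "f_slope_0_positive": bool(num_deriv(f, 0.0) > 0),
        "f_slope_pi_zero": bool(abs(num_deriv(f, np.pi - eps)) < 1e-3),
        "g_slope_0_positive": bool(num_deriv(g, 0.0) > 0),
        "g_slope_pi_negative": bool(num_deriv(g, np.pi) < 0),
        "h_at_0_is_1": bool(abs(float(h(0.0)) - 1.0) < tol),
        "h_at_pi_is_0": bool(abs(float(h(np.pi))) < tol),
        "h_slope_0_zero": bool(abs(num_deriv(h, 0.0)) < 1e-3),
        "h_slope_pi_zero": bool(abs(num_deriv(h, np.pi - eps)) < 1e-3),
        "f_no_interior_zeros": bool(np.all(np.asarray(f(interior)) > 0)),
        "g_no_interior_zeros": bool(np.all(np.asarray(g(interior)) > 0)),
        "h_monotone_decreasing": bool(np.all(np.diff(hxh) <= tol)),
    }
    return AxiomReport(checks=checks)
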