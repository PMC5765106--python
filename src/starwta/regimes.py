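"""Attractor-type prediction and detection.

Once a winner l has locked with the CO, each loser phase obeys (to
leading order) an independent sine circle flow with detuning
Omega_i = omega_i - omega_l.  A loser with |Omega_i| < |b| stays locked
near antiphase; a loser with |Omega_i| > |b| runs indefinitely with mean
winding rate sign(Omega_i)*sqrt(Omega_i**2 - b**2).  The attractor is
therefore a point (stationary winner-take-all), a limit cycle (one
running loser), or an m-torus (m running losers); crossing
|Omega_i| = |b| is the saddle-node on the invariant circle/torus that
raises the attractor dimension by one.

`classify_regime` predicts the label from parameters alone;
`detect_attractor` measures it from a simulated trajectory; the two are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ModelParams, Trajectory, torus_rotation_frequency

__all__ = [
    "RegimeLabel",
    "RotationStats",
    "classify_regime",
    "detect_attractor",
    "regime_map",
    "MultipleWinnersError",
]


class MultipleWinnersError(RuntimeError):
    """Two amplitudes stayed above the winner corridor: contradicts the
    single-winner property and is surfaced as an anomaly."""


@dataclass
class RegimeLabel:
    """Qualitative attractor description.

    ``m`` is the torus dimension: 0 for a stationary winner point, 1 for
    a limit cycle, >= 2 for a limit torus.  ``running`` maps each
    unbounded loser index (0-based, input ordering) to its signed
    predicted mean rotation frequency.
    """

    kind: str                       # stationary_WTA | nonstationary_WTA | no_winner | boundary
    winner: int | None
    m: int
    running: dict[int, float] = field(default_factory=dict)

    @property
    def directions(self) -> dict[int, int]:
        return {i: int(np.sign(w)) for i, w in self.running.items()}


@dataclass
class RotationStats:
    """Measured per-PO statistics over the analysis window."""

    slopes: np.ndarray              # mean d(phi_i)/dt of the unwrapped phases
    bounded: np.ndarray             # bool per PO
    osc_amplitude: np.ndarray       # peak-to-peak of wrapped phi per PO
    winner_margin: float | None     # c + gamma - min winner amplitude


def classify_regime(p: ModelParams, l: int, *, eta: float = 1e-3) -> RegimeLabel:
    """Predict the attractor type for candidate winner ``l`` (0-based).

    Counts the losers whose detuning exceeds |b|; any detuning within
    ``eta`` of |b| puts the parameters on the bifurcation locus and the
    label is ``boundary``.  Requires b < 0.
    """
    if p.b >= 0:
        raise ValueError("winner-take-all regimes require b < 0")
    det = p.omega - p.omega[l]
    absb = abs(p.b)
    gap = np.abs(det) - absb
    others = np.arange(p.n) != l
    if np.any(np.abs(gap[others]) <= eta):
        return RegimeLabel(kind="boundary", winner=l, m=0)
    gap[l] = -absb  # the winner itself never runs
    running = {int(i): torus_rotation_frequency(float(det[i]), p.b)
               for i in np.nonzero(gap > eta)[0]}
    m = len(running)
    kind = "stationary_WTA" if m == 0 else "nonstationary_WTA"
    return RegimeLabel(kind=kind, winner=l, m=m, running=running)


def detect_attractor(traj: Trajectory, p: ModelParams,
                     window: tuple[float, float] = (80.0, 100.0), *,
                     delta: float = 1.0, slope_tol: float = 0.05,
                     ) -> tuple[RegimeLabel, RotationStats]:
    """Measure the attractor type from a trajectory.

    The winner is the unique PO whose amplitude stays above
    ``c + gamma - delta`` over the window; running losers are those
    whose unwrapped phase drifts faster than ``slope_tol`` rad/time.
    Raises `MultipleWinnersError` if two amplitudes qualify; returns a
    ``no_winner`` label if none does.
    """
    t0, t1 = window
    mask = traj.window(t0, t1)
    if mask.sum() < 4:
        raise ValueError("analysis window contains too few samples")
    t = traj.times[mask]
    a = traj.a[mask]
    phi = traj.phi[mask]
    phi_w = traj.phi_wrapped[mask]

    high = p.c + p.gamma - delta
    winner_mask = np.all(a > high, axis=0)
    slopes = np.polyfit(t, phi, 1)[0]
    osc = phi_w.max(axis=0) - phi_w.min(axis=0)

    if winner_mask.sum() > 1:
        raise MultipleWinnersError(
            f"amplitudes {np.nonzero(winner_mask)[0] + 1} all stayed above "
            f"{high:.3g} over the window")
    if winner_mask.sum() == 0:
        stats = RotationStats(slopes=slopes, bounded=np.abs(slopes) <= slope_tol,
                              osc_amplitude=osc, winner_margin=None)
        return RegimeLabel(kind="no_winner", winner=None, m=0), stats

    winner = int(np.nonzero(winner_mask)[0][0])
    bounded = np.abs(slopes) <= slope_tol
    bounded[winner] = True
    running = {int(i): float(slopes[i]) for i in np.nonzero(~bounded)[0]}
    m = len(running)
    kind = "stationary_WTA" if m == 0 else "nonstationary_WTA"
    label = RegimeLabel(kind=kind, winner=winner, m=m, running=running)
    stats = RotationStats(slopes=slopes, bounded=bounded, osc_amplitude=osc,
                          winner_margin=float(p.c + p.gamma - a[:, winner].min()))
    return label, stats


def regime_map(p: ModelParams, l: int, diff_grids: list[np.ndarray], *,
               omega_ref: float | None = None,
               eta: float = 1e-3) -> np.ndarray:
    """Classify the attractor over a grid of normalized detunings.

    ``diff_grids`` holds n-1 axes of normalized frequency differences
    ``(omega_l - omega_i)/|b|`` for the POs other than ``l`` (in input
    order); the classification is evaluated on their Cartesian product.
    Returns an object array of `RegimeLabel` of shape
    ``(len(axis_1), ..., len(axis_{n-1}))``.  Entries with any axis value
    within ``eta`` of 1 in magnitude are the SNIC/SNIT boundary.
    """
    if len(diff_grids) != p.n - 1:
        raise ValueError(f"need {p.n - 1} difference axes for n = {p.n}")
    if omega_ref is None:
        omega_ref = float(p.omega[l])
    others = [i for i in range(p.n) if i != l]
    shape = tuple(len(g) for g in diff_grids)
    out = np.empty(shape, dtype=object)
    absb = abs(p.b)
    for idx in np.ndindex(shape):
        omega = np.empty(p.n)
        omega[l] = omega_ref
        for ax, i in enumerate(others):
            omega[i] = omega_ref - diff_grids[ax][idx[ax]] * absb
        out[idx] = classify_regime(p.with_omega(omega), l, eta=eta)
    return out


def regime_map_to_text(labels: np.ndarray, diff_grids: list[np.ndarray],
                       path) -> None:
    """Write a regime map as a delimited grid file for contour plotting."""
    kind_code = {"stationary_WTA": 0, "nonstationary_WTA": 1,
                 "no_winner": 2, "boundary": 3}
    rows = []
    for idx in np.ndindex(labels.shape):
        lab: RegimeLabel = labels[idx]
        axes = [diff_grids[ax][i] for ax, i in enumerate(idx)]
        rows.append(axes + [kind_code[lab.kind],
                            -1 if lab.winner is None else lab.winner + 1,
                            lab.m])
    n_axes = len(diff_grids)
    header = "\t".join([f"diff_{i + 1}" for i in range(n_axes)]
                       + ["kind_code", "winner", "m"])
    np.savetxt(path, np.asarray(rows, dtype=float), delimiter="\t",
               header=header, fmt="%.12g")
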