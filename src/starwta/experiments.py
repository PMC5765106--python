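"""The Monte-Carlo experiment protocol.

Each experiment integrates the full system from randomized initial
conditions (PO natural frequencies drawn uniformly, optionally also the
initial PO phases) with PO 1 given an initial amplitude advantage, and
classifies the outcome on the analysis window (T1, T2) against two
amplitude thresholds H_low < H_high:

* **A** — PO 1 is the sole oscillator whose amplitude stays above
  H_high: the favoured PO won the competition.
* **B** — exactly one other PO stays above H_high: the advantage was
  overturned.
* **C** — every amplitude stays below H_low: no winner emerged.
* **indeterminate** — anything else (mixed corridor occupancy or an
  integration failure); retained as a first-class outcome rather than
  silently folded into A/B/C.

The five presets (``ex3`` .. ``ex7``) sweep, respectively, the initial
advantage a_1(0), the steepness nu (narrow and wide frequency ranges),
the initial-phase spread, and the amplitude-adaptation rate beta, around
the common operating point n = 10, b = -1, alpha = 1, beta = 0.05,
c = 2, gamma = 10, nu = 20, mu = 1, sigma = 100, thresholds 10/3,
window (80, 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coupling import CouplingParams
from .dynamics import FullState, IntegrationError, ModelParams, Trajectory, integrate

__all__ = [
    "ExperimentConfig",
    "RunRecord",
    "OutcomeTally",
    "draw_initial_conditions",
    "classify_outcome",
    "run_experiment",
    "example_preset",
    "PRESET_VARIANTS",
]

OUTCOMES = ("A", "B", "C", "indeterminate")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol for one Monte-Carlo condition."""

    n: int = 10
    omega_dist: tuple[float, float] = (4.9, 5.1)
    phase_range: tuple[float, float] = (0.0, 0.0)
    theta0_init: float = 0.0
    omega0_init: float = 5.0
    a1_init: float = 8.0
    a_other_init: float = 2.0
    coupling: CouplingParams = field(default_factory=lambda: CouplingParams(nu=20.0))
    b: float = -1.0
    alpha: float = 1.0
    beta: float = 0.05
    c: float = 2.0
    gamma: float = 10.0
    T1: float = 80.0
    T2: float = 100.0
    H_high: float = 10.0
    H_low: float = 3.0
    n_runs: int = 1000
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.omega_dist[1] < self.omega_dist[0]:
            raise ValueError("empty omega interval")
        if self.phase_range[1] < self.phase_range[0]:
            raise ValueError("empty phase interval")
        if not self.c < self.H_low < self.H_high < self.c + self.gamma:
            raise ValueError(
                f"thresholds must satisfy c < H_low < H_high < c + gamma, got "
                f"{self.c} < {self.H_low} < {self.H_high} < {self.c + self.gamma}")
        if not self.T1 < self.T2:
            raise ValueError("need T1 < T2")
        if self.n_runs < 0:
            raise ValueError("n_runs must be >= 0")

    def model_params(self, omega: np.ndarray) -> ModelParams:
        return ModelParams(omega=omega, b=self.b, alpha=self.alpha,
                           beta=self.beta, gamma=self.gamma, c=self.c,
                           coupling=self.coupling)


@dataclass
class RunRecord:
    """Per-run provenance: draw, outcome, winner."""

    run_index: int
    omega: np.ndarray
    theta_init: np.ndarray
    outcome: str
    winner: int | None           # 0-based PO index, None for C/indeterminate
    note: str = ""


@dataclass
class OutcomeTally:
    """Aggregated outcome counts with binomial standard errors."""

    config: ExperimentConfig
    records: list[RunRecord]

    @property
    def n_runs(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> dict[str, int]:
        counts = {k: 0 for k in OUTCOMES}
        for r in self.records:
            counts[r.outcome] += 1
        return counts

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_runs
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    @property
    def standard_errors(self) -> dict[str, float]:
        n = self.n_runs
        out = {}
        for k, frac in self.fractions.items():
            out[k] = float(np.sqrt(frac * (1 - frac) / n)) if n else 0.0
        return out

    def percent(self, outcome: str) -> float:
        return 100.0 * self.fractions[outcome]

    def summary(self) -> str:
        lines = [f"runs: {self.n_runs}"]
        se = self.standard_errors
        for k in OUTCOMES:
            lines.append(f"{k}: {self.counts[k]:6d}  "
                         f"{100 * self.fractions[k]:6.2f}%  "
                         f"(SE {100 * se[k]:.2f} pts)")
        return "\n".join(lines)


def draw_initial_conditions(cfg: ExperimentConfig, run_index: int,
                            ) -> tuple[ModelParams, FullState]:
    """Randomized parameters and initial state for one run.

    A child random stream is derived from ``(seed, run_index)``, so any
    run is reproducible in isolation and extending ``n_runs`` never
    reshuffles earlier draws.  Frequencies are drawn first, then the
    initial phases (all zero when the phase range is degenerate).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(run_index,)))
    omega = rng.uniform(cfg.omega_dist[0], cfg.omega_dist[1], cfg.n)
    lo, hi = cfg.phase_range
    theta = np.zeros(cfg.n) if hi == lo else rng.uniform(lo, hi, cfg.n)
    a = np.full(cfg.n, cfg.a_other_init)
    a[0] = cfg.a1_init
    state = FullState(theta0=cfg.theta0_init, theta=theta,
                      omega0=cfg.omega0_init, a=a)
    return cfg.model_params(omega), state


def classify_outcome(traj: Trajectory, cfg: ExperimentConfig) -> tuple[str, int | None]:
    """Outcome class over the analysis window, from the dense samples.

    "Stays above/below" a threshold means every sample in [T1, T2] does.
    Returns ``(outcome, winner_index)``.
    """
    if traj.times[-1] < cfg.T2 - 1e-9:
        raise ValueError("trajectory does not cover the analysis window")
    mask = traj.window(cfg.T1, cfg.T2)
    a = traj.a[mask]
    above = np.all(a > cfg.H_high, axis=0)
    below = np.all(a < cfg.H_low, axis=0)
    if above.sum() == 1:
        winner = int(np.nonzero(above)[0][0])
        return ("A" if winner == 0 else "B"), winner
    if above.sum() == 0 and below.all():
        return "C", None
    return "indeterminate", None


def run_experiment(cfg: ExperimentConfig) -> OutcomeTally:
    """Execute the full protocol: draw, integrate, classify, tally.

    Runs are independent (per-run child seeds), so the tally does not
    depend on execution order.  Integration failures are recorded as
    ``indeterminate`` with a diagnostic note, never dropped.
    """
    records = []
    for k in range(cfg.n_runs):
        params, state = draw_initial_conditions(cfg, k)
        note = ""
        try:
            traj = integrate(params, state, cfg.T2, rtol=cfg.rtol,
                             atol=cfg.atol, sample_dt=cfg.sample_dt)
            outcome, winner = classify_outcome(traj, cfg)
        except IntegrationError as exc:
            outcome, winner, note = "indeterminate", None, str(exc)
        records.append(RunRecord(run_index=k, omega=params.omega,
                                 theta_init=state.theta, outcome=outcome,
                                 winner=winner, note=note))
    return OutcomeTally(config=cfg, records=records)


_EX6_RANGES = {
    "pi/8": (-np.pi / 8, np.pi / 8),
    "pi/4": (-np.pi / 4, np.pi / 4),
    "pi/2": (-np.pi / 2, np.pi / 2),
    "pi": (-np.pi, np.pi),
}

PRESET_VARIANTS = {
    "ex3": [4.0, 6.0, 8.0, 10.0, 12.0],          # a_1(0)
    "ex4": [5.0, 10.0, 15.0, 20.0],              # nu, narrow frequency range
    "ex5": [5.0, 10.0, 15.0, 20.0],              # nu, wide frequency range
    "ex6": list(_EX6_RANGES),                    # initial-phase half-width
    "ex7": [0.05, 0.1, 0.15, 0.02],              # beta
}


def example_preset(preset_id: str, variant, *, n_runs: int = 1000,
                   seed: int = 0) -> ExperimentConfig:
    """The preset Monte-Carlo conditions, by swept-parameter value.

    ``ex3`` sweeps a_1(0) in {4, 6, 8, 10, 12}; ``ex4``/``ex5`` sweep
    nu in {5, 10, 15, 20} with the narrow (4.9, 5.1) and wide
    (4.25, 5.75) frequency intervals; ``ex6`` sweeps the initial-phase
    range in {pi/8, pi/4, pi/2, pi} (half-widths); ``ex7`` sweeps beta
    in {0.05, 0.1, 0.15, 0.02}.
    """
    base = ExperimentConfig(n_runs=n_runs, seed=seed)
    if preset_id == "ex3":
        if variant not in PRESET_VARIANTS["ex3"]:
            raise ValueError(f"unknown ex3 variant {variant!r}")
        return replace(base, a1_init=float(variant))
    if preset_id in ("ex4", "ex5"):
        if variant not in PRESET_VARIANTS[preset_id]:
            raise ValueError(f"unknown {preset_id} variant {variant!r}")
        omega_dist = (4.9, 5.1) if preset_id == "ex4" else (4.25, 5.75)
        return replace(base, coupling=CouplingParams(nu=float(variant)),
                       omega_dist=omega_dist)
    if preset_id == "ex6":
        if variant not in _EX6_RANGES:
            raise ValueError(f"unknown ex6 variant {variant!r}; "
                             f"choose one of {list(_EX6_RANGES)}")
        return replace(base, phase_range=_EX6_RANGES[variant])
    if preset_id == "ex7":
        if variant not in PRESET_VARIANTS["ex7"]:
            raise ValueError(f"unknown ex7 variant {variant!r}")
        return replace(base, beta=float(variant))
    raise ValueError(f"unknown preset {preset_id!r}")
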