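# Methods

## Model and assumptions

The network is a star: a central oscillator (CO) coupled bidirectionally
to n peripheral oscillators (POs), with no PO–PO connections.  Beyond
the phases, two quantities adapt: the CO's natural frequency ω₀ relaxes
at rate α toward the CO's instantaneous frequency (equivalently,
dω₀/dt = α(dθ₀/dt − ω₀)), and each PO→CO amplitude aᵢ relaxes at rate β
toward c + γ·h(φᵢ), so a PO is rewarded for phase proximity to the CO.
The model is deterministic and noise-free; stochasticity enters only
through randomized initial conditions in the experiment protocol.

The coupling functions satisfy structural axioms rather than being
arbitrary: f and g odd with f′(0) > 0, f′(π) = 0, g′(0) > 0, g′(π) < 0,
no further zeros on (0, π); h even, monotone on [0, π], h(0) = 1,
h(π) = 0, h′(0) = h′(π) = 0.  The concrete family used throughout is

- f(x) = sin(|x − π|^ν / π^(ν−1)) on [0, π], odd-extended, ν > 1;
- g(x) = sin x;
- h(x) = ((μ² − x²)/μ²)^σ for |x| < μ, else 0, with 0 < μ < π, σ ≥ 1.

The flat zero of f at π is what makes the winner-take-all states robust:
losers parked near antiphase exert (almost) no drive on the CO.
`validate_coupling` re-checks all axioms numerically on a fixed grid and
accepts callable overrides, so an externally supplied triplet can be
audited before use.

## Parameters, units, defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| n | number of POs | — | experiments use 10 |
| ωᵢ | PO natural frequencies (rad/time) | — | drawn U(4.9, 5.1) or U(4.25, 5.75) in experiments |
| b | CO→PO coupling | −1 | b < 0 required for WTA |
| α | frequency-adaptation rate | 1 | |
| β | amplitude-adaptation rate | 0.05 | slowest timescale; small β favours the initial leader |
| γ | resonance gain | 10 | winner amplitude → c + γ |
| c | baseline amplitude | 2 | loser amplitude → c |
| ν | steepness f′(0) | 20 | x_max = π(1 − 2^(−1/ν)) |
| μ | half-width of h (rad) | 1 | must satisfy μ < π/2 for the winner-point analysis |
| σ | sharpness of h | 100 | σ ≫ 1 regime |

These defaults are the operating point of the Monte-Carlo protocol and
of most worked examples.

## Numerical choices

**Evaluation of f at large ν.**  The power term |x∓π|^ν/π^(ν−1) is
computed as exp(ν·log|x∓π| − (ν−1)·log π); naive powering underflows
near the seams already for ν ≈ 200.  Exact zeros are returned at x = 0
and |x| = π, and f′(0) returns ν exactly; elsewhere derivatives are
analytic (finite differences appear only as test oracles).  Arguments
are reduced to [−π, π) before piecewise evaluation.

**Integration.**  The production integrator is an adaptive
Dormand–Prince 5(4) stepper compiled with numba, with the whole
trajectory loop in compiled code; this is what makes the 4000-run
Monte-Carlo protocol a ~20 s computation on one CPU.  Defaults
rtol = 1e−8, atol = 1e−10, dense sampling at Δt = 0.1.  The stepper
clips steps to land exactly on the sample grid instead of
interpolating, so repeated runs are bit-identical.  Phases are
integrated unwrapped (the coupling kernels reduce arguments
internally), which preserves winding counts for rotation detection.
The vector field is smooth — h with σ = 100 is sharp but not stiff, and
β = 0.05 sets the slowest scale — so an explicit method is appropriate.
The integrator is validated in the test suite against scipy's RK45 on
the same vector field at tighter tolerance.

**Fixed-point solving.**  Winner points Q_l and saddles S_l,j are
solved from the stationarity equations with scipy's Powell-hybrid root
finder and the analytic Jacobian, seeded at the perturbative
approximation (winner phase 0, loser phases π − arcsin((ωᵢ − ωₗ)/b),
ω₀ = ωₗ, amplitudes c+γ/c; the saddle seed flips coordinate j to the
arcsin branch near 0).  Acceptance requires residual < 1e−10; on
failure the solver falls back to a short relaxation integration toward
the attractor and re-solves.  Loser-phase branches follow the two
arcsin domains: (π/2, 3π/2) for losers of Q_l, (−π/2, π/2) for the
flipped saddle coordinate.

**Spectra and classification.**  Eigenvalues at the symmetric points
P_k use the closed forms ((k−1) copies of −b·g′(0), (n−k) copies of
−b·g′(π), n copies of −β, and a quadratic pair driven by
σ_k = k(c+γ)f′(0); for k = 0 the pair degenerates to a zero eigenvalue).
An eigenvalue whose real part is within 1e−9 of zero relative to the
spectral radius classifies the point as *neutral*, never stable — the
no-winner point P₀ is the canonical case: attracting in 2n directions
but neutral along a line of near-equilibria L(ω̃₀) with
φ = π − arcsin((ω − ω̃₀)/b), aᵢ = c, which simulations perceive as
fixed points wherever the f- and h-tails vanish.

**Regime thresholds.**  With winner l, a loser i is predicted to run
iff |ωᵢ − ωₗ| > |b|; each boundary |ωᵢ − ωₗ| = |b| is a saddle-node on
the invariant circle/torus, and the attractor is a limit m-torus with m
the number of running losers (m = 0 point, m = 1 cycle).  Detunings
within η = 1e−3 of the threshold are labelled `boundary`.  Detection
uses winner margin δ = 1.0 (a tenth of γ, well inside the gap between c
and c+γ) and slope tolerance 0.05 rad/time on the unwrapped phases; the
smallest running rate in the tested configurations is ≈ 0.46 rad/time,
an order of magnitude above the tolerance.  Mode-locked versus
quasi-periodic flow on a torus is not distinguished — the label records
only m.

## The experiment protocol

Each run draws ωᵢ independently and uniformly, optionally draws initial
PO phases uniformly (otherwise all start at 0 with the CO), gives PO 1
an initial amplitude a₁(0) ∈ [4, 12] against 2 for the rest, integrates
the full system to T₂ = 100, and classifies on (T₁, T₂) = (80, 100)
with thresholds H_high = 10, H_low = 3: **A** if a₁ alone stays above
H_high at every sample, **B** if exactly one other PO does, **C** if
all stay below H_low, and **indeterminate** otherwise (kept as a
first-class outcome and reported separately).  "Stays above" is
evaluated at the dense Δt = 0.1 samples.  Per-run random streams are
children of (root seed, run index), so runs are independent,
order-invariant, and individually reproducible, and growing the run
count never reshuffles earlier draws.

Because the favourite's advantage is an *initial condition*, not a
parameter, the outcome statistics measure basins of attraction: the
fraction of draws falling into the basin of each winner state.  In the
zero-phase-spread conditions the draw of ω is the only randomness, so
outcomes are a deterministic function of the drawn frequency vector.

The synthetic draws emulate the stated study conditions only — i.i.d.
uniform frequency detunings and phase spreads around a symmetric
operating point.  They do not probe structured frequency distributions,
noise during the dynamics, or parameter heterogeneity across POs, so
passing statistics say nothing about robustness to those.

## Design choices on open points

- The analytic claim that both |f(π/2)| and |f′(π/2)| fall below 1e−5
  at ν = 20 is only two-thirds right: |f′(π/2)| = ν·2^(1−ν)/2 ≈ 3.8e−5.
  The package reports analytic values and does not round them toward
  the looser claim.
- Attractor labels carry the winner index in the *input* ordering plus
  the explicit running-loser set, rather than a frequency-sorted
  subscript; sorted conventions are ambiguous once several losers run.
- The empirical growth law for running-loser amplitude maxima is not
  implemented (its constant is unspecified); only the qualitative
  corridor (losers between c and c + δ) is asserted.
- The regime map is parameterized by explicit normalized-detuning axes
  (ωₗ − ωᵢ)/|b| per loser, sidestepping any fixed two-axis convention.
- Histogram rendering of tallies is left to the caller (the exported
  per-run tables load directly into pandas/matplotlib); the package
  writes text artifacts only.
- `n = 1` winner-stability is handled as its own case (stable iff
  (c+γ)ν + b > 0, either sign of b), since the n ≥ 2 inequalities do
  not specialize to it.

## Known limitations

- Equilibrium continuation/arclength tracking through the saddle-node
  loci is not provided; the solver simply fails (with a named detuning
  pair) outside the existence region.
- No Lyapunov-exponent machinery: no chaotic behaviour was observed at
  the protocol's operating point, and the package does not certify its
  absence elsewhere in parameter space.
- The enumeration of all 2ⁿ symmetric points is refused above n = 16 by
  default (it is exponential by construction).
- Amplitude trapping in [c − ε, c + γ + ε] holds after a burn-in set by
  the slowest rate: overshoot decays like e^(−βt), so reaching ε = 0.01
  from one unit of overshoot takes t ≈ 92 at β = 0.05.
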