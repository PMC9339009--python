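# Methods

## Model

The package simulates continual memory storage in a sparse recurrent
attractor network.  Time is measured in units of the (constant) interval
between the arrival of two consecutive memories; one new memory enters at
every integer time with initial efficacy A(0) (default 1).  The state of
the mean-field model is the vector of memory efficacies A_l(t), which

* decay exponentially with the synaptic decay time τ,
* receive increments b at rehearsal events, modeled as an inhomogeneous
  Poisson process of rate λ·F(A_l/A_c), and
* jointly determine the interference noise Δ² = (f/N)·Σ A² and hence the
  critical efficacy A_c = a(f)·Δ below which a memory stops being an
  attractor (and stops being rehearsed: F = 0 below A_c).

The basin function F and the critical ratio a(f) come from a
one-dimensional mean-field overlap map.  Writing f± for the activation
probability of pattern-active/-inactive neurons and M = f₊ − f₋ for the
overlap, one update of the network maps M to

    G(M, A/Δ) = H(H⁻¹(f(1−M)) − (A/Δ)·M) − f(1−M)

in the fixed-activity setting (threshold adjusted so the population
activity is exactly f), where H is the Gaussian upper-tail function.
Stable/unstable fixed-point pairs of G exist above a critical ratio
a(f); the basin size is approximated by the distance M_s − M_us between
the stable retrieval point and the unstable point below it.  When the
zero state itself destabilizes (large A/Δ) the basin extends to zero
overlap and the width is M_s.

## Key parameters

| parameter | meaning | default / typical |
|---|---|---|
| f | coding sparseness | 0.01 |
| τ | synaptic decay time (memory-arrival units) | 160 (pure-forgetting demos: 2240) |
| λ | maximal rehearsal rate; λτ is the mean number of rehearsals per decay time | λτ = 5 or 10 |
| b | efficacy increment per rehearsal (< 1, i.e. weaker than initial encoding) | 0.25–0.3 |
| N | number of neurons | 8000 (network checks: 2000–4000) |
| dt | integration step | 0.05/λ |
| T | simulated duration | 400τ |
| θ | firing threshold (fixed-threshold mode) | 0.36 |

The product bλτ sets the consolidation fixed point A_fp = bλτ·F(A_fp/A_c)
(≈ bλτ because F saturates); the regime bλτ ≈ 1 maximizes the fraction of
memories that consolidate.

## Numerical choices

**Overlap fixed points.**  The map residual G(M) − M is evaluated on a
dense grid (2000 uniform points joined with a logarithmic ramp down to
10⁻⁷, because the unstable fixed point scales like Δ/A and escapes any
uniform grid at large ratios) and sign changes are refined by bisection
to ~10⁻¹⁰.  Stability is classified by the sign of the residual's slope.
The critical ratio a(f) is found by bisection on the existence of a
stable nonzero fixed point.

**Basin table.**  F is tabulated on 400 log-spaced points of A/A_c in
[1, 50] (exactly zero below 1) and normalized by its value at A/A_c = 50,
where it has long saturated, so that λ·F is a rate with ceiling λ.  The
raw widths are kept alongside.  Between nodes F is interpolated
piecewise-linearly.

**Stochastic integration.**  Decay uses the exact factor exp(−dt/τ)
(no Euler bias); a rehearsal occurs for each eligible memory (A ≥ A_c)
with probability λ·F·dt per step (Poisson thinning; λ·dt ≤ 0.1 enforced
at most 0.05 by default).  Event order within a step: decay, rehearsal
draws against the previous step's A_c, insertion of new memories at the
integer times inside the step, then the Δ/A_c update.  A memory inserted
mid-step is initialized with the exact decay from its birth instant, so
the no-rehearsal limit reproduces A(t) = exp(−(t−l)/τ) to machine
precision.  Before any interference exists (Δ = 0) the rehearsal rate of
extant memories takes its limiting value λ.

**Truncation.**  Memories with A < 10⁻⁶·A_c that are older than 10τ are
dropped from the active arrays; their noise contribution is negligible
and the cost stays proportional to the retrievable pool.  Dropped
memories still enter forgetting-curve denominators (below).

**Equilibrium detection.**  A_c is averaged over consecutive 10τ windows;
equilibrium is declared when two consecutive window means agree within
2%.  Observables (capacity, A_c, histogram, forgetting curve) are
accumulated from that point on, at snapshots every τ/2.

**Forgetting curve.**  The curve pools (memory, snapshot) samples over
all post-equilibrium snapshots, but only for memories *born at
equilibrium*: cohorts that consolidated under the early, low-A_c
transient retain better and would contaminate the tail.  Per-age-bin
denominators are computed from the birth schedule, so truncated
(long-forgotten) memories count as non-retrievable rather than silently
leaving the sample — otherwise the measured curve converges to
P(retrievable | not yet forgotten) and flattens.  Default bin width τ/2.

**Consolidation probability.**  A memory counts as consolidated when its
peak efficacy ever exceeded A_c + 0.8·(A_fp − A_c); demanding exact
attainment of A_fp is ill-posed under rehearsal fluctuations.  The
cohort is restricted to memories born at equilibrium with at least 5τ of
subsequent simulated time.

**Fits.**  Retention fits are unweighted least squares on log
probability (binomial weighting is available), with time constants in
units of τ.  The exponential tail uses ages > 5τ; the double exponential
(fast unconsolidated drop + slow consolidated tail) fits the full range
with multi-start nonlinear least squares on log-parameters.  Bins with
fewer than four expected successes are excluded: deeper bins cannot
enter a log fit at all, and keeping only their lucky nonzero neighbours
biases the tail upward.  The power law fits log p against log age; R² of
competing models is always compared in log-probability space.

## Fixed threshold and perturbations

With a fixed firing threshold θ the critical efficacy is no longer
proportional to Δ.  The map for f± is evaluated at fixed θ with the
population activity q solved self-consistently (damped iteration of
q = f f₊ + (1−f) f₋), with the noise scaled by √(q/f) since only active
presynaptic units transmit.  A_c(Δ; θ) is tabulated by bisecting, per Δ,
the smallest efficacy with a stable retrieval state; it has a floor
≈ θ/(1−f) at small Δ, climbs with Δ, rises abruptly when over-activation
amplifies the noise, and is recorded as infinite above the critical
noise level.  The consolidation simulator interpolates this table
instead of re-solving the map each step.

*Additive synaptic noise* with diffusion coefficient D contributes an
Ornstein–Uhlenbeck variance term f·(τD²/2N)(1 − e^{−2(t−t₀)/τ}) to Δ².
The activity factor f keeps the term commensurate with the
activity-weighted interference variance; without it, a moderate D would
permanently exceed the critical noise and erase all memories, which
contradicts the transient, recoverable deficits this perturbation is
known to produce.  After a transient window ends, the accumulated
variance relaxes back with the same time constant τ/2.

*Synaptic dilution* (a fraction p of synapses silenced, symmetric mask)
scales signals by (1−p) and the noise by √(1−p); the simulator folds
both into an effective criticality A_c(√(1−p)·Δ)/(1−p).

**Known limitation.**  In this formulation the unperturbed
fixed-threshold equilibrium self-organizes onto the steep segment of
A_c(Δ; θ) (only there can memory death balance memory arrival).  On that
segment the noise relief from mild dilution outweighs the signal loss,
so simulated dilution *increases* capacity at small p instead of
producing the all-ages deficit expected from the signal-to-noise
argument; the additive-noise phenomenology (temporally graded
retrograde/anterograde amnesia centered on onset-encoded memories, with
recovery for post-onset encodings) is reproduced.  The corresponding
regression test asserts the expected deficit and currently fails; see
the test suite.

*Threshold adaptation* is a grid search (step 0.01) over θ with common
random numbers, maximizing post-perturbation capacity.

## Heterogeneous decay times

Each synapse owns a decay rate drawn from a Pareto distribution of
characteristic times, P(τ₀) = α·τ₀^{−(α+1)} on [1, ∞), scaled so the
minimal time is ω (default 20).  The maximal rehearsal rate is
calibrated as λ = R₀ / mean(τ) from the empirical mean of a large sample
— for α ≤ 1 the mean diverges and the calibration is flagged.  Per-memory
efficacies are tracked per decay-time *bin*: retrievability is governed
by the bin-averaged efficacy and the interference by the bin-averaged
second moment; a rehearsal adds b to every bin of the rehearsed memory.

The 50 bins are **log-spaced in decay time with exact Pareto masses**
out to the 0.9999 quantile (conditional-median representatives), not
equal-probability quantile slices: equal-mass bins cap the largest
represented time near the top-bin median (~20× the minimum at α = 1.5),
which imposes an artificial exponential cutoff on exactly the
heavy-tail regime the distribution exists to produce.  With the
log-spaced bins the retention curve follows a power law over two and a
half decades of age at intermediate α and reverts to exponential at
large α.  For α < 2 the second moment of effectively non-decaying
synapses grows as t^{2−α}, so there is no strict equilibrium; runs use a
burn-in fraction (default 30–40% of T) before measuring, and T ~ 300–400
mean decay times.

## What the simulations do and do not emulate

The synthetic memory streams are the model's own study conditions: one
memory per time unit, i.i.d. Bernoulli(f) patterns, constant (or simply
distributed) encoding strengths, stationary rehearsal statistics.  Real
memory systems violate most of these — correlated and clustered
experiences, salience-dependent encoding, non-stationary rehearsal
(sleep), structured connectivity.  Passing tests therefore demonstrate
the internal consistency of the theory and simulators, not fits to
behavioral retention data.  The rehearsal process itself is imposed via
its rate law rather than generated by a circuit mechanism (e.g.
adaptation-driven attractor hopping).

## Problem sizes

Library defaults target a single core: N = 8000 with 8–10 realizations
of T = 400τ for the headline forgetting-curve numbers (the histogram,
capacity, and A_c stabilize with far less), N = 1000–8000 with 2
realizations for the capacity-vs-N scan, N = 2000–4000 for full-network
checks, and T ≈ 300–400 mean decay times for the heterogeneous-decay
curves.  Each number in the test suite and acceptance script is
recomputed at these sizes.

## Further limitations

* The saddle-node of the printed overlap map at f = 0.01 merges at
  overlap ≈ 0.77; retrievability in network simulations is nevertheless
  declared at the conventional overlap cut of 0.85.
* The slow tail constant at strong drive (λτ = 10) is exponentially
  sensitive to the basin function near threshold; its absolute value
  should be treated as order-of-magnitude, while the moderate-drive
  (λτ = 5) tail and the equilibrium A_c are robust.
* Full-network retrieval at fN ≲ 40 active units suffers binomial
  pattern-size artifacts (patterns with unusually many active units
  cannot reach a 0.85 overlap under exact-fN dynamics); network checks
  use fN ≥ 20 and tolerate a sub-unity young-age plateau.  The
  pure-forgetting retrieval step is likewise smeared by quenched
  per-memory interference fluctuations, with a width scaling like
  1/√(fN): ≈0.4τ at fN = 20, ≈0.28τ at fN = 40.
* Excitatory/inhibitory separation (Dale's law), bounded synapses, and
  bimodal decay-time distributions are out of scope.
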