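# Methods

## The model

Each gene's expression rate is a difference of two power-law products
(an S-system), extended with per-regulator integer delays and
complex-valued rate constants:

dX_i/dt = α_i ∏_j X_j(t−τ_ij)^{g_ij} − β_i ∏_j X_j(t−τ_ij)^{h_ij}

* **α_i, β_i ∈ ℂ** — production/degradation rate constants. Complex
  constants give the fit two extra degrees of freedom per term; on purely
  real data the optimum is real and the imaginary parts act as slack that
  absorbs residual structure rather than distorting the kinetic orders.
* **g_ij, h_ij ∈ ℝ** — kinetic orders. Sign encodes activation (+) or
  repression (−); magnitude encodes strength. A regulator with
  |order| ≈ 0 contributes a factor ≈ 1, i.e. no regulation — this is what
  edge pruning keys on.
* **τ_ij ∈ ℕ** — delays in sampling steps. The regulator is always read
  in the past (t − τ): the printed form X(t+τ) of such models is a
  notational variant; a causal reading is the only one that can be
  evaluated on a recorded time course.

Observed expression values are real and are embedded as complex numbers
with zero imaginary part; only the parameters are genuinely complex.
Powers use the principal branch, z^g = exp(g·Log z), so |z^g| = |z|^g;
0^g = 0 for g > 0 and is a domain error otherwise.

## Two-step inference

**Step 1 — time-delayed correlation screen.** For every ordered pair
(regulator j, target i) the Pearson correlation between X_j(t) and
X_i(t+τ) is computed over the overlap window (window-local means and
variances) for τ = 0…τ_max and the lag with the largest |r| is kept; ties
break toward the smallest lag (the most parsimonious delay). Thresholding
|r| gives the initial directed network, with weight |r| and the winning
lag per edge. The screen is deliberately permissive — on short smooth
time courses many pairs correlate, and the role of Step 1 is to bound the
per-gene candidate sets, not to decide the topology. The matrix diagonal
is a cc = 1 / lag = 0 display convention and never produces an edge;
self-loops can be screened explicitly via the delayed (lag ≥ 1)
autocorrelation when enabled.

**Step 2 — per-gene equation fitting and pruning.** Each target gene is
fitted independently (decoupled estimation): the target's numerical
derivative is estimated once (central differences inside, one-sided at
the boundaries, honoring the time grid), and a candidate equation's
fitness is the slope-matching SSE Σ_t |RHS(t) − slope(t)|² over
t = (largest lag)…T−1, with every factor reading the observed (floored)
value at t − τ. This avoids integrating a delay system inside the search
loop, the standard decoupling used in S-system inference.

The search is memetic:

* **Structure chromosome** — a restricted additive tree: fixed
  subtraction root, two product-node branches (arity 1…max_arity), leaves
  carrying (regulator, order, lag), complex constants on the branches.
  Regulators may not repeat within a term (powers would merge); the same
  regulator may appear in both terms. Structure identity for caching is
  the per-term regulator membership.
* **Structure evolution** — tournament selection (k = 3), subtree/leaf
  swap crossover at compatible positions (leaf swaps that would duplicate
  a regulator are retried, falling back to the always-grammatical branch
  swap), pointwise mutation (regulator replacement, Gaussian order steps,
  branch regeneration, constant perturbation), elitism.
* **Parameter fitting** — for a fixed structure, differential evolution
  (rand/1/bin) over the kinetic orders and the leaf lags; lags are
  bounded real components rounded to integers at evaluation time and are
  *initialized* from the screened lags. The rate constants are not
  searched at all: for fixed orders and lags the RHS is linear in (α, β),
  so they are profiled out by exact complex least squares at every
  fitness call. Profiling removes four real dimensions and, empirically,
  is the difference between the structure ranking being reliable and
  being noise: un-profiled 900-evaluation runs stalled an order of
  magnitude above the optimum often enough to randomize which structure
  won. The evolutionary search still fits the real kinetic orders and
  delays; complex components of the optimizer are exercised wherever a
  caller supplies them (see `cvde`).
* **Parsimony** — structures compete on SSE × (1 + γ)^(#distinct
  regulators), γ = 0.2 by default. Raw SSE rewards every extra regulator
  (more parameters always soak up some discretization error), so without
  complexity pressure pruning could never remove a false positive. γ is
  scale-free (multiplicative), and 0.2 sits well below the SSE jump
  caused by dropping a true regulator on informative data.
* **Leader re-optimization** — after evolution, the five best structures
  are re-fitted at the full parameter budget and the winner is chosen
  from the re-fitted penalized scores, guarding against a single unlucky
  short run misranking the leaders.

A regulator survives pruning when it appears in the best equation with
|kinetic order| > ε (default 0.05). Final edges keep the weight and lag
from Step 1; the final network is a subset of the initial one by
construction.

**Lags: screened vs dynamical.** The correlation-optimal lag of a true
edge is the regulator→target *phase shift*, which for integrating
dynamics differs systematically from the model delay τ (a plain
integrator trails its drive by a quarter period). Pinning leaf lags to
the screened value therefore handicaps exactly the true structures; this
is why lags are freed during parameter fitting and the screened lag is
only the starting point.

## Tunable parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `tau_max` | min(5, T−3) | largest screened lag, in samples; bounded so ≥3 points overlap |
| `tdcc_threshold` | 0.7 | minimum |r| for an initial edge; lower it (0.3–0.5) when recall matters more than candidate-set size |
| `prune_eps` | 0.05 | order magnitude below which a regulator counts as absent |
| `cvrat.pop_size / generations` | 30 / 30 | structure-evolution budget |
| `cvrat.max_arity` | 4 | regulators per product term |
| `cvrat.mutation_rate / crossover_rate` | 0.15 / 0.7 | per-site mutation probability; crossover probability |
| `cvrat.parsimony` | 0.2 | multiplicative complexity pressure per distinct regulator |
| `cvde.np_pop / f_weight / cr / generations` | 40 / 0.5 / 0.9 / 150 | rand/1/bin settings; early stop after 30 stalled generations (<1e−10 improvement) |
| `struct_de_generations` | 30 | short parameter budget used while ranking structures |
| `order_bound / const_bound` | 4 / 30 | search boxes for orders and for re/im of the constants |

Out-of-box trials are reflected back into bounds. All randomness flows
from a single seed through one `numpy` generator, so identical
(data, config, seed) gives byte-identical results.

## Numerical choices

* moduli are floored at 1e−6 before exponentiation (negative orders on a
  zero would otherwise overflow); domain errors inside fitness map to a
  finite 1e12 penalty so evolution stays total;
* simulation is forward Euler with a lag ring-buffer at `substeps`
  resolution (default 10 per sample interval); the history is linearly
  interpolated onto the Euler grid; any state with modulus above 1e6
  raises a divergence error naming the step;
* slope estimation is `numpy.gradient` on the sample grid: second-order
  central differences at interior points, first-order one-sided at the
  boundaries;
* lag components round half away from the search center only through
  plain `round`, and the profiled least squares uses `numpy.linalg.lstsq`
  (rank-deficient designs are handled by the minimum-norm solution).

## Synthetic data

`random_ground_truth` draws bounded-by-construction systems: every gene
carries a positive-order self-degradation factor (guaranteeing damping
and one self-edge per gene in the gold standard) plus up to three
non-self regulators split between the two terms. Rate constants have
real parts in [1, 20] (drawn from the slow end so transients span a
short time course) and imaginary parts in [−1, 1], shared between α and
β — with independent imaginary parts the imaginary state drifts and the
observable real trajectory stops obeying the real dynamics, making the
generated "truth" unlearnable in principle. Orders have magnitudes in
[0.3, 3]; non-self lags are uniform on [0, τ_max]. `simulate_dataset`
integrates the truth from a constant positive history, takes real parts,
adds Gaussian noise scaled per gene (σ = noise_sd × trajectory sd),
floors at 1e−6, and redraws the initial state up to 20 times on
divergence.

Two deterministic fixtures mirror the classic benchmark circuits in gene
names and topology size only — the *E. coli* SOS repair regulon (8
genes, 9 edges: lexA fanning out to seven targets plus the lexA
self-loop and recA→lexA) and a canonical reconstruction of the yeast
IRMA circuit (5 genes, 8 edges, no self-loops). Their kinetics are
synthetic and designed, not measured: an IRMA-like wiring with no
self-edges is a network of pure integrators, so boundedness and
informativeness have to be engineered. The design uses the SWI5/GAL80
negative two-gene loop as a harmonic pacemaker (two integrators in a
negative cycle oscillate at a period set by the loop gain — here ~9
samples), weak follower couplings, per-gene Im(α) = Im(β) and
Re(α) = Re(β) so neither the imaginary component nor the equilibrium
flux drifts, and an initial state ~15% off the all-ones equilibrium.
The SOS fixture analogously runs a damped lexA/recA relaxation
oscillator (lexA has true self-degradation) driving six followers with
lags 1–2.

`recovery_benchmark` is a fixed three-gene damped ring for
parameter-recovery experiments. Identifiability drove every choice:
production and degradation of one equation never read the same gene
(α z^g − β z^h over a low-amplitude trajectory determines only a
combination of g and h), the three trajectories are phase-shifted rather
than collinear, and sampling is fine (60 points at dt = 0.25) because
the finite-difference slope bias otherwise shifts the SSE optimum away
from the true orders by several tenths — an effect verified by refitting
against exact model derivatives.

**What passing tests show — and don't.** The generator produces smooth,
low-noise, regularly sampled, fully observed data from the model family
the fitter assumes. Success on it demonstrates that the screen, the
optimizers and the pruning logic do their jobs, not that the method
handles real microarray data: measurement noise there is heavier-tailed
and correlated, sampling is sparser, the true dynamics are not power
laws, and hidden regulators violate the closed-world candidate
assumption. Conclusions about real-data accuracy require the real
benchmarks, which ship with neither this package nor its inputs.

## Problem sizes

The shipped end-to-end experiments run the five-gene fixture at reduced
budgets (structure population 20 × 20 generations; parameter runs 30 × 30)
with `tau_max` 2 and screen threshold 0.3 — the scale a desk check of a
5–10 gene benchmark warrants; the defaults above are for real use.
Recovery experiments use the full default parameter budget (40 × 150) on
the fixed three-gene benchmark.

## Known limitations

* Forward Euler is first order; stiff parameterizations need small
  `substeps` budgets to stay faithful, and no implicit solver is
  provided.
* Decoupled fitting trusts the estimated slopes; with noisy or sparse
  sampling the slope error, not the optimizer, bounds the attainable
  accuracy.
* Single-time-course identifiability is weak by nature: equations whose
  two terms read the same regulator, or regulators with nearly collinear
  trajectories, cannot be resolved regardless of search budget. The
  pruning decision (which regulators appear) is more robust than the
  fitted parameter values.
* Edge direction for lag-0 pairs rests entirely on Step 2; the
  correlation statistic is symmetric at zero lag.
* Weights and lags of final edges are inherited from the screen, not
  refit from the fitted equations.
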