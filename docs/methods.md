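# Methods

## Model

A linear habitat of `L` demes holds two types competing for one limited
resource: wild type (counts `N1`) and a mutant (counts `N0`) that uses the
resource more economically.  The only intrinsic difference between the
types is the local carrying capacity, which depends on the mutant
frequency `f = N0/(N0+N1)`:

    K_c(f) = K (1 + eps f),          |eps| < 1.

One generation consists of

1. **Migration** — every individual independently hops to the left or
   right neighbouring deme with probability `m/2` each.  The continuum
   limit of this kernel is diffusion with `D = m a^2 / 2` (deme spacing
   `a = 1` by default).
2. **Reproduction** — the expected composition of each deme is

       E[N0'] = N0 (1 + g) - s N0 N1 / N,
       E[N1'] = N1 (1 + g) + s N0 N1 / N,
       g = r0 (1 - N / K_c(f)),

   a shared logistic factor plus an antisymmetric selection term (the two
   `s`-terms cancel in the total, so selection acts on the ratio of the
   types and the expected frequency change from selection alone is
   `-s f (1-f)`).  The realised total is a Poisson draw around the
   expected total, and conditional on the total the mutant count is a
   binomial (Wright-Fisher) draw.  The per-generation frequency variance
   is `lam f (1-f) / N`; offspring variance above the Wright-Fisher value
   (`lam > 1`) is produced by a beta-binomial composition draw whose
   overdispersion parameter `theta = (N - lam)/(lam - 1)` gives that
   variance exactly.  Frequencies 0 and 1 are absorbing; there is no
   mutation.

`measure_offspring_variance` calibrates the realised `lam` of whatever
scheme is configured by converting the one-generation frequency variance
of replicate equilibrium demes back to an offspring variance; data sets
are labelled with this measured value rather than the nominal one.

### Boundary conditions and front tracking

Speed measurements use *reservoir* boundaries: the leftmost deme is
re-pinned all-mutant at capacity `K(1+eps)` and the rightmost all-wild at
`K` after every sub-step, which keeps a single front in frame.
*Reflecting* boundaries conserve both types exactly and are used for
martingale and calibration checks.  Runs abort if mutants intrude within
10 demes of the advancing edge, because the pinned boundary would
otherwise truncate the front tip, which is the dynamically relevant
region of a pulled front.  The front coordinate is the mass integral
`x0 = sum_x f(x) dx` measured from the left edge — translation
equivariant and insensitive to front shape; a threshold-crossing variant
(`f = 1/2`) serves for width diagnostics.

The tug-of-war initial condition is a step (all-mutant left half,
all-wild right half) or a logistic profile of chosen width.  Smoothed
profiles are truncated at `f < 0.02`: for large `K` the rounded logistic
tail would otherwise seed isolated pioneer individuals tens of demes
ahead of the front, which a founding population does not contain.

## Continuum limit and the Cole-Hopf map

For small `m`, the density relaxes to the capacity much faster than the
frequency field evolves, so `n ~ K_c(f)` (quasi-static closure; the
package checks this numerically rather than formally: the time-averaged
deme size tracks `K_c(f)` to within a few percent at small `m`).  The
closed frequency equation is

    df/dt = D f_xx + 2 D eps f_x^2 / (1 + eps f) - s f (1 - f).

The gradient-squared term is removed exactly by the Cole-Hopf field

    h(f) = [(1 + eps f)^3 - 1] / [(1 + eps)^3 - 1],

the unique monotone [0,1] -> [0,1] transformation that turns the
`s = 0` equation into pure diffusion (`h = f + O(eps)`).  Deterministic
dynamics therefore admit *no* traveling wave: a step initial condition
only broadens, with front displacement growing like `sqrt(D t)` — the
mutants cannot invade without noise.

With genetic drift, `f` obeys the Ito SPDE with noise amplitude
`sqrt(lam f (1-f) / n)` per deme per generation.  The noise `n` is
evaluated at the quasi-static value `K_c(f)` (using the dynamic density
instead changes the amplitude at `O(m)`).  Transforming pathwise to `h`
generates a spurious Ito drift

    (1/2) h''(f) Var(df) = s_eff h (1 - h) + O(eps^3),
    s_eff = (eps lam / K) * C(eps),   C(eps) = 3 eps / ((1+eps)^3 - 1),

a *logistic growth term favouring the mutants* with rate `s_eff ~
eps lam / K` at leading order.  `compute_theory` keeps the exact
finite-`eps` coefficient `C(eps)` (`C -> 1` as `eps -> 0`; `C(0.2) =
0.82`), because the well-mixed drift measurement resolves the
difference.  After rescaling space by `sqrt(D/s_eff)` and time by
`1/s_eff`, the transformed equation is a stochastic Fisher-Kolmogorov
equation whose noise variance coefficient is `Gamma^(-1/2)` with

    Gamma = D K eps / lam,

the single control parameter of the problem.  Its two limits give the
wave-speed law: `v -> m eps` for small `Gamma` (renewal regime) and
`v -> 2 sqrt(D s_eff)`, i.e. `v/(m eps) -> Gamma^(-1/2)`, for large
`Gamma`.

### Measuring the Ito drift

`measure_ito_drift` runs well-mixed (zero-dimensional) sampling-noise
trajectories, transforms them pathwise, and estimates the drift from the
statistic `q = h(f') - h(f) - h'(f)(f' - f)`.  Subtracting the
martingale part `h'(f) df` is a zero-mean control variate: `E[q]` is
exactly the Ito correction (h is cubic, so no higher-order remainder
survives in expectation for Gaussian increments), while the estimator
variance drops by a factor of order `dt` relative to the naive mean of
`dh`.  A direct mean-drift estimate at the same precision would need
roughly 10^6 replicate trajectories.

## Renewal oracle

For `m K << 1` the front is a step between two demes and advances by
single migrant-fixation events, so the speed has an exact expression:

    v = (m/2) [ K(1+eps) P_fix(1 mutant | K wilds)
                - K P_fix(1 wild | K(1+eps) mutants) ].

Fixation probabilities come from an exact absorbing-Markov-chain solve
of the within-deme dynamics on states `(n0, n1)` with the expected total
rounded deterministically (this keeps the reachable state space small;
for `s = 0` the frequency is a bounded martingale, so `P_fix` equals the
initial frequency exactly under either total-size rule, a closed form
the tests verify to 1e-7).  The two `eps`-biases — a larger migrant flux
out of mutant demes and a higher fixation probability in the smaller
wild-type demes — each contribute `m eps / 2`; equalising the fixation
probabilities in the oracle isolates the flux bias and halves the speed.

## Wave-speed estimation and the scaling collapse

Speeds are per-seed OLS slopes of the mass-integral front position after
discarding a 25% burn-in; the quoted stderr is the between-seed standard
error (HAC-corrected OLS for single trajectories).  Replicate lattices
run simultaneously through a numba kernel that implements the identical
sampling scheme as the public NumPy operations; one-generation moments
of both paths are tested against the shared deterministic expectation.

The collapse experiment uses six parameter sets at `eps = 0.2`,
`lam = 1`: matched-Gamma pairs with different `(m, K)` at `Gamma =
0.35, 3.5, 35`.  Lattice lengths (200-380 demes) and run lengths
(4000-6000 generations) were sized from theory — mean drift plus three
standard deviations of front wandering plus the occupied tail length
`~ sqrt(D/s_eff) ln K` must fit between the initial front position and
the edge guard — and initial profiles are logistic with the predicted
steady width to shorten the relaxation transient.  The report checks
(i) matched-Gamma agreement in units of the joint stderr, (ii)
monotonicity of the master curve, (iii) the log-log slope over the
largest Gamma decade, for which the asymptote is -1/2.

## Selection-drift balance and the ESS

With a growth-rate cost `s > 0` the mapped equation's growth term
becomes `s_eff - s`: mutants invade only while `s < s_eff`.  Under a
linear rate-yield trade-off `eps = c s`, the marginal capacity is

    K* = c lam

(to leading order in `eps`): above `K*` the noise-induced advantage is
too weak to pay for the growth-rate cost, so `K*` is the evolutionarily
stable capacity.  `find_ess` locates the sign change of the measured
`v(s)` by bisection, resolving the sign at each point at 2 sigma with up
to a configurable replicate cap; a point whose sign stays unresolved at
the cap is statistically zero and is reported as the root.  `v(s)` is
shallow near the crossing, so the searches need long runs (1.6-3 x 10^4
generations) and up to 64 seeds per point; the balance point is measured
at `m K ~ 1` where the renewal picture is clean, and its predicted
independence of `m` is checked across a 4x range.

## Numerical choices

* Explicit Euler / Euler-Maruyama with `dt = 0.2 dx^2 / (2D)` capped at
  `0.5/r0`; steppers refuse `dt` beyond the diffusive CFL limit or the
  logistic stability limit `2/r0`.
* `dx = 1` deme by default, so continuum and lattice runs share
  coordinates.
* Cole-Hopf and its inverse are written in cancellation-free form
  (`expm1`/`log1p`), stable down to `eps = 0` with round-trip error
  below 1e-12.
* The mapped stochastic FKPP stepper generates its noise by binomial
  resampling with per-cell population `N = dx sqrt(Gamma) / dt`, which
  has exactly the Wright-Fisher variance and keeps `u = 0` absorbing.
  Gaussian increments clipped to [0,1] are *not* used for fronts: at the
  absorbing tip, clipping rectifies the noise and inflates pulled-front
  speeds many-fold.
* `sqrt(f(1-f))` arguments are clamped at 0; absorbing states are exact.
* Total-size noise is Poisson at every size (no Gaussian switch-over),
  keeping one deterministic code path per seed.

## What the synthetic conditions do and do not show

All experiments are generated internally (step or logistic tug-of-war
profiles, parameter sweeps); there is no external data.  The model
emulates the core mechanism — drift-generated frequency gradients
feeding a gradient-squared growth term — in one dimension with
nearest-neighbour dispersal, two types, and no mutation, environmental
structure, or age structure.  Passing tests therefore demonstrate the
internal consistency of simulation and theory (speed laws, collapse,
balance point), not the quantitative behaviour of any real microbial
system; in structured natural populations the effective drift is
stronger and `K*` should be read as a lower bound.

## Known limitations

* The front-speed equality between the mapped stochastic FKPP equation
  and the deme model at matched `Gamma` holds only up to pulled-front
  cutoff corrections, which are `O(1)` and scheme-dependent at
  desk-scale `Gamma` (effective populations of a few per rescaled length
  unit).  The package checks same-order agreement (measured ratio ~1.4
  at `Gamma = 35`), with both speeds well below the deterministic
  `2 sqrt(D s_eff)`; the quantitative speed law is validated within the
  deme model itself via the collapse.
* `s_eff` uses the exact one-deme Ito coefficient but neglects `O(eps)`
  corrections from the transformed noise amplitude and the rescaling;
  at `eps = 0.2` measured balance points sit within ~10% of the
  prediction at `m K ~ 1` and deviate more (~25%) at `m K ~ 10`.
* The ESS bisection reports the midpoint when the replicate cap cannot
  resolve the sign; its resolution is therefore bounded by the
  configured tolerance (default `s_eff/8`), not by the quoted stderr.
* Two or more spatial dimensions are out of scope; the balance-point
  prediction is dimension-independent in theory but only the 1-D case is
  simulated.
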