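"""Individual-based stepping-stone simulator.

One generation = migration followed by within-deme reproduction:

* migration: each individual independently jumps to the left or right
  neighbouring deme with probability ``m/2`` each;
* reproduction: the deme's expected composition is given by
  :func:`driftwave.core.growth_expectation`; the realised total is a
  Poisson draw around the expected total (demographic number fluctuations)
  and, conditional on the total, the mutant count is a Wright-Fisher
  binomial draw.  The resulting per-generation variance of the mutant
  frequency is ``lam * f(1-f) / N`` to leading order; offspring-number
  variance beyond the Wright-Fisher value (``lam > 1``) is generated with a
  beta-binomial composition draw whose overdispersion is chosen so the
  frequency variance is exactly ``lam * f(1-f) / N``.

Frequencies 0 and 1 are absorbing (no mutation).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import LatticeState, ModelParams, growth_expectation, tug_of_war

__all__ = [
    "migrate",
    "reproduce_deme",
    "step_generation",
    "run_sim",
    "SimTrajectory",
    "measure_offspring_variance",
]

#: demes of clearance the front must keep from a lattice edge
EDGE_GUARD = 10


def _pin_reservoirs(N0: np.ndarray, N1: np.ndarray, params: ModelParams) -> None:
    """Re-pin the edge demes: left all-mutant at K(1+eps), right all-wild at K."""
    N0[..., 0] = params.K_mut
    N1[..., 0] = 0
    N0[..., -1] = 0
    N1[..., -1] = params.K


def migrate(state: LatticeState, params: ModelParams, rng: np.random.Generator) -> LatticeState:
    """One migration sweep.

    Each individual moves left or right with probability ``m/2`` each
    (joint binomial draws per deme per type).  Under reflecting boundaries
    would-be emigrants at the edges stay put, so the totals of each type
    are conserved exactly; under reservoir boundaries the edge demes are
    re-pinned after migration.
    """
    m = params.m
    if m == 0.0:
        out = state.copy()
        out.t = state.t
        return out
    new = []
    for A in (state.N0, state.N1):
        movers = rng.binomial(A, m)
        left = rng.binomial(movers, 0.5)
        right = movers - left
        B = A - movers
        # arrivals; edge handling below
        B[:-1] += left[1:]
        B[1:] += right[:-1]
        if params.boundary == "reflecting":
            B[0] += left[0]
            B[-1] += right[-1]
        new.append(B)
    N0, N1 = new
    if params.boundary == "reservoir":
        _pin_reservoirs(N0, N1, params)
    return LatticeState(N0, N1, t=state.t)


def _sample_composition(total, p, lam: float, rng: np.random.Generator):
    """Mutant count out of ``total`` with frequency variance ``lam*p(1-p)/total``.

    ``lam == 1`` is a plain binomial (Wright-Fisher).  For ``lam > 1`` a
    beta-binomial with ``theta = (n - lam)/(lam - 1)`` gives variance
    ``lam * n * p * (1-p)`` exactly; demes too small for that overdispersion
    (n <= lam + 1) fall back to the binomial.
    """
    total = np.asarray(total)
    p = np.asarray(p, dtype=float)
    if lam <= 1.0:
        return rng.binomial(total, p)
    q = p.copy()
    mask = (total > lam + 1.0) & (p > 0.0) & (p < 1.0)
    if mask.any():
        theta = (total[mask] - lam) / (lam - 1.0)
        q[mask] = rng.beta(p[mask] * theta, (1.0 - p[mask]) * theta)
    return rng.binomial(total, q)


def _reproduce_lattice(
    N0: np.ndarray, N1: np.ndarray, params: ModelParams, rng: np.random.Generator
):
    """Vectorised reproduction of every deme of a lattice (or batch of lattices)."""
    e0, e1 = growth_expectation((N0, N1), params)
    etot = e0 + e1
    if np.any(etot > 1e12):
        raise OverflowError(
            f"expected deme size {etot.max():.3g} exceeds the integer-safe range; "
            "check r0/K settings"
        )
    total = rng.poisson(etot)
    occupied = total > 0
    p = np.where(occupied, e0 / np.where(etot > 0, etot, 1.0), 0.0)
    n0 = np.where(occupied, _sample_composition(total, p, params.lam, rng), 0)
    return n0.astype(np.int64), (total - n0).astype(np.int64)


def reproduce_deme(counts, params: ModelParams, rng: np.random.Generator):
    """Sampled next-generation counts ``(N0', N1')`` of a single deme.

    Expectation matches :func:`growth_expectation`; see the module
    docstring for the sampling scheme.
    """
    n0 = np.asarray([counts[0]], dtype=np.int64)
    n1 = np.asarray([counts[1]], dtype=np.int64)
    r0, r1 = _reproduce_lattice(n0, n1, params, rng)
    return int(r0[0]), int(r1[0])


def step_generation(state: LatticeState, params: ModelParams, rng: np.random.Generator) -> LatticeState:
    """Advance one full generation: migration, then reproduction."""
    mig = migrate(state, params, rng)
    N0, N1 = _reproduce_lattice(mig.N0, mig.N1, params, rng)
    if params.boundary == "reservoir":
        _pin_reservoirs(N0, N1, params)
    return LatticeState(N0, N1, t=state.t + 1)


@dataclass
class SimTrajectory:
    """Recorded states of one stochastic run plus reproducibility metadata."""

    times: np.ndarray
    states: list
    params: ModelParams
    seed: int
    wallclock: float = 0.0
    meta: dict = field(default_factory=dict)


def _front_in_guard(state: LatticeState, params: ModelParams) -> bool:
    """True if mutants intrude into the right-edge guard band (left edge is
    the mutant home under the tug-of-war setup, so only the advancing side
    is checked; reflecting runs check both edges)."""
    g = EDGE_GUARD
    right = state.N0[-g - 1 : -1].sum() > 0
    if params.boundary == "reflecting":
        left = state.N1[1 : g + 1].sum() > 0
        return bool(right or left)
    return bool(right)


def run_sim(
    params: ModelParams,
    init: LatticeState | None = None,
    record_every: int = 1,
    check_front: bool = True,
) -> SimTrajectory:
    """Run the individual-based simulator for ``params.generations``.

    Deterministic given ``params.seed``.  Aborts with a diagnostic if the
    front comes within ``EDGE_GUARD`` demes of a lattice edge (enlarge the
    lattice or shorten the run) or if counts overflow.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(params.seed)
    state = init.copy() if init is not None else tug_of_war(params)
    if state.N0.shape != (params.L,):
        raise ValueError("initial state shape does not match params.L")
    times = [state.t]
    states = [state.copy()]
    for _ in range(params.generations):
        state = step_generation(state, params, rng)
        if state.t % record_every == 0:
            times.append(state.t)
            states.append(state.copy())
            if check_front and _front_in_guard(state, params):
                raise RuntimeError(
                    f"front reached within {EDGE_GUARD} demes of a lattice edge at "
                    f"t={state.t}; increase L ({params.L}) or reduce generations"
                )
    return SimTrajectory(
        times=np.asarray(times),
        states=states,
        params=params,
        seed=params.seed,
        wallclock=time.perf_counter() - t0,
    )


def measure_offspring_variance(
    params: ModelParams,
    replicates: int = 20_000,
    f: float = 0.5,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical per-capita offspring-number variance of the sampling scheme.

    Starts ``replicates`` independent demes at demographic equilibrium
    (N = K_c(f), mutant fraction ``f``), applies one reproduction step to
    each, and converts the observed variance of the mutant frequency into
    the effective offspring variance via ``lam_hat = N Var(f') / (f(1-f))``.
    Used to label data sets with their effective ``lam``.
    """
    if replicates < 1000:
        warnings.warn(
            f"replicates={replicates} < 1000: offspring-variance estimate will be noisy",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    Kc = params.K * (1.0 + params.eps * f)
    n0 = int(round(Kc * f))
    n1 = int(round(Kc)) - n0
    N = n0 + n1
    f0 = n0 / N
    N0 = np.full(replicates, n0, dtype=np.int64)
    N1 = np.full(replicates, n1, dtype=np.int64)
    # selection would bias the mean, not the variance, but keep it off so the
    # estimator stays a pure variance calibration
    p = params.with_(s=0.0)
    r0, r1 = _reproduce_lattice(N0, N1, p, rng)
    tot = np.maximum(r0 + r1, 1)
    fprime = r0 / tot
    return float(N * fprime.var(ddof=1) / (f0 * (1.0 - f0)))
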