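"""Front tracking, wave-speed estimation, theory predictions, and the ESS.

The quantities derived here summarise the physics of noise-driven waves:

* ``v_small = m eps`` - net front drift in the low-migration renewal
  regime, where the front is a step between two demes and advances by
  single migrant-fixation events.  Mutant demes both export more migrants
  (capacity ``K(1+eps)`` vs ``K``) and offer their invaders a higher
  fixation probability (smaller target deme); each bias contributes
  ``m eps / 2``.
* ``s_eff = eps lam / K`` (times an exact finite-eps Ito factor) - the
  noise-induced effective growth-rate advantage of mutants revealed by the
  Cole-Hopf transformation of the frequency SPDE.
* ``Gamma = D K eps / lam`` - the single control parameter of the rescaled
  stochastic Fisher-Kolmogorov equation.  Rescaled speeds ``v / v_small``
  collapse onto one master curve in Gamma, saturating at 1 for small Gamma
  and falling off as ``Gamma^(-1/2)`` (i.e. ``v -> v_large = 2 sqrt(D s_eff)``)
  for large Gamma.
* ``K* = c lam`` - the evolutionarily stable carrying capacity under a
  linear rate-yield trade-off ``eps = c s``: mutations cannot invade once
  the growth-rate cost exceeds ``s_eff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .core import LatticeState, ModelParams, growth_expectation

__all__ = [
    "FrontTrajectory",
    "SpeedEstimate",
    "TheoryBundle",
    "front_position",
    "front_position_threshold",
    "front_width",
    "estimate_speed",
    "compute_theory",
    "invasion_condition",
    "wf_fixation_probability",
    "deme_fixation_probability",
    "renewal_speed_oracle",
    "measure_front_speed",
    "scaling_collapse",
    "CollapseReport",
    "find_ess",
    "ESSResult",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class FrontTrajectory:
    """Front position time series; ``positions`` may be (n,) or (seeds, n)."""

    times: np.ndarray
    positions: np.ndarray
    widths: np.ndarray | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_seeds(self) -> int:
        return self.positions.shape[0]


@dataclass
class SpeedEstimate:
    v: float
    stderr: float
    window: tuple[float, float]
    n_seeds: int

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass
class TheoryBundle:
    """Derived quantities for one parameter set (see module docstring)."""

    D: float
    Gamma: float
    s_eff: float
    v_small: float
    v_large: float
    s_net: float
    ito_factor: float
    c: float | None = None
    K_star: float | None = None


# --------------------------------------------------------------------------
# front tracking
# --------------------------------------------------------------------------


def _as_frequency_profile(obj) -> tuple[np.ndarray, float]:
    if isinstance(obj, LatticeState):
        return obj.frequency(empty=0.0), 1.0
    if hasattr(obj, "f") and hasattr(obj, "dx"):
        return np.asarray(obj.f, dtype=float), float(obj.dx)
    return np.asarray(obj, dtype=float), 1.0


def front_position(obj, dx: float | None = None, warn: bool = True) -> float:
    """Mass-integral front position ``x0 = sum_x f(x) dx`` from the left edge.

    Insensitive to front shape and noise; expects ``f ~ 1`` on the left
    and ``f ~ 0`` on the right.  Warns if the profile contains more than
    one front (multiple 0.75/0.25 hysteresis crossings); pass
    ``warn=False`` for strongly speckled stochastic profiles where the
    mass integral is still the right summary.
    """
    f, d = _as_frequency_profile(obj)
    if dx is not None:
        d = dx
    if not warn:
        return float(f.sum() * d)
    # hysteresis-binarised crossing count: enter mutant domain above 0.75,
    # leave below 0.25 - robust to noise right at the front
    state = f[0] > 0.5
    crossings = 0
    for v in f:
        if state and v < 0.25:
            state = False
            crossings += 1
        elif not state and v > 0.75:
            state = True
            crossings += 1
    if crossings > 1:
        warnings.warn(
            f"profile has {crossings} front crossings; mass-integral position "
            "is the sum over all of them",
            stacklevel=2,
        )
    return float(f.sum() * d)


def front_position_threshold(obj, level: float = 0.5, dx: float | None = None) -> float:
    """Interpolated position of the first downward crossing of ``level``."""
    f, d = _as_frequency_profile(obj)
    if dx is not None:
        d = dx
    below = np.nonzero(f < level)[0]
    if len(below) == 0:
        return float(len(f) * d)
    i = below[0]
    if i == 0:
        return 0.0
    frac = (f[i - 1] - level) / (f[i - 1] - f[i])
    return float((i - 1 + frac + 0.5) * d)


def front_width(obj, lo: float = 0.25, hi: float = 0.75, dx: float | None = None) -> float:
    """Distance between the ``hi`` and ``lo`` threshold crossings."""
    return max(
        front_position_threshold(obj, level=lo, dx=dx)
        - front_position_threshold(obj, level=hi, dx=dx),
        0.0,
    )


def estimate_speed(traj: FrontTrajectory, burn_in: float = 0.25) -> SpeedEstimate:
    """Least-squares front speed after discarding a burn-in fraction.

    With replicate seeds the quoted stderr is the between-seed standard
    error of the per-seed OLS slopes; for a single trajectory it is an
    autocorrelation-robust (HAC) OLS standard error.
    """
    t = traj.times
    keep = t >= t[0] + burn_in * (t[-1] - t[0])
    t = t[keep]
    X = traj.positions[:, keep]
    if len(t) < 20:
        raise ValueError(f"only {len(t)} post-burn-in samples; need >= 20")
    window = (float(t[0]), float(t[-1]))
    tc = t - t.mean()
    denom = (tc**2).sum()
    slopes = (X - X.mean(axis=1, keepdims=True)) @ tc / denom
    if traj.n_seeds > 1:
        v = float(slopes.mean())
        se = float(slopes.std(ddof=1) / np.sqrt(len(slopes)))
    else:
        import statsmodels.api as sm

        model = sm.OLS(X[0], sm.add_constant(t))
        res = model.fit(cov_type="HAC", cov_kwds={"maxlags": max(1, int(len(t) ** (1 / 3)))})
        v = float(res.params[1])
        se = float(res.bse[1])
    return SpeedEstimate(v=v, stderr=se, window=window, n_seeds=traj.n_seeds)


# --------------------------------------------------------------------------
# theory
# --------------------------------------------------------------------------


def _ito_factor(eps: float) -> float:
    """Exact finite-eps coefficient of the spurious Ito drift, ``-> 1`` as eps -> 0.

    The Cole-Hopf field has h'' = 2 eps C (1 + eps f) with
    C = 3 eps / ((1+eps)^3 - 1); the quasi-static noise variance carries a
    matching 1/(1+eps f), so the drift coefficient is eps lam C / K.
    """
    if eps == 0.0:
        return 1.0
    return 3.0 * eps / ((1.0 + eps) ** 3 - 1.0)


def compute_theory(params: ModelParams, c: float | None = None) -> TheoryBundle:
    """Fill every derived quantity for one parameter set.

    ``c`` is the rate-yield trade-off coefficient (``eps = c s``); when
    given, the evolutionarily stable capacity ``K* = c lam`` is reported.
    """
    D = params.D
    itof = _ito_factor(params.eps)
    s_eff = params.eps * params.lam / params.K * itof
    Gamma = D * params.K * params.eps / params.lam
    v_small = params.m * params.eps * params.a
    s_net = s_eff - params.s
    v_large = 2.0 * np.sqrt(D * s_net) if s_net > 0 else 0.0
    K_star = c * params.lam if c is not None else None
    return TheoryBundle(
        D=D,
        Gamma=Gamma,
        s_eff=s_eff,
        v_small=v_small,
        v_large=float(v_large),
        s_net=s_net,
        ito_factor=itof,
        c=c,
        K_star=K_star,
    )


def invasion_condition(s: float, bundle: TheoryBundle) -> bool:
    """Theory-side predicate: mutants invade iff their cost is below s_eff."""
    return s < bundle.s_eff


# --------------------------------------------------------------------------
# fixation-probability oracles (absorbing Markov chains)
# --------------------------------------------------------------------------


def wf_fixation_probability(N: int, i: int = 1, s: float = 0.0) -> float:
    """Fixation probability of ``i`` mutants in a fixed-size Wright-Fisher deme.

    Exact absorbing-chain solve of the binomial chain with success
    probability ``f - s f (1-f)``; the neutral case reduces to ``i/N``.
    """
    if not 0 <= i <= N:
        raise ValueError("need 0 <= i <= N")
    j = np.arange(N + 1)
    f = j / N
    p = np.clip(f - s * f * (1.0 - f), 0.0, 1.0)
    P = stats.binom.pmf(j[None, :], N, p[:, None])  # P[row i, col i']
    Q = P[1:N, 1:N]
    r = P[1:N, N]
    u = np.linalg.solve(np.eye(N - 1) - Q, r)
    full = np.concatenate([[0.0], u, [1.0]])
    return float(full[i])


def _pair_chain_transitions(n0: int, n1: int, params: ModelParams, tol: float = 1e-12):
    """Transition distribution of the within-deme pair chain (n0, n1).

    Expected composition from :func:`growth_expectation`; the realised
    total is the rounded expectation (deterministic - keeps the state
    space one-dimensional per total) and the mutant count a binomial draw.
    """
    e0, e1 = growth_expectation((float(n0), float(n1)), params)
    etot = e0 + e1
    M = int(round(etot))
    if M <= 0 or e0 <= 0:
        return [((0, M), 1.0)] if M > 0 else [((0, 0), 1.0)]
    if e1 <= 0:
        return [((M, 0), 1.0)]
    p = e0 / etot
    mean = M * p
    sd = np.sqrt(M * p * (1 - p))
    lo = max(0, int(np.floor(mean - 8 * sd - 2)))
    hi = min(M, int(np.ceil(mean + 8 * sd + 2)))
    ii = np.arange(lo, hi + 1)
    pmf = stats.binom.pmf(ii, M, p)
    keep = pmf > tol
    ii, pmf = ii[keep], pmf[keep]
    pmf = pmf / pmf.sum()
    return [((int(i), M - int(i)), float(w)) for i, w in zip(ii, pmf)]


def deme_fixation_probability(
    params: ModelParams, n0: int, n1: int, max_states: int = 400_000
) -> float:
    """Probability that mutants fix in an isolated deme started at (n0, n1).

    Exact sparse solve of the absorbing pair chain.  For ``s = 0`` the
    mutant frequency is a bounded martingale, so the result equals the
    initial frequency ``n0 / (n0 + n1)`` - a closed form the tests use to
    validate this solver.
    """
    start = (int(n0), int(n1))
    index: dict[tuple[int, int], int] = {}
    transitions: list[list[tuple[tuple[int, int], float]]] = []
    frontier = [start]
    index[start] = 0
    transitions.append([])
    order = [start]
    while frontier:
        state = frontier.pop()
        if state[0] == 0 or state[1] == 0:
            continue
        trans = _pair_chain_transitions(state[0], state[1], params)
        transitions[index[state]] = trans
        for nxt, _w in trans:
            if nxt not in index:
                index[nxt] = len(order)
                order.append(nxt)
                transitions.append([])
                frontier.append(nxt)
                if len(order) > max_states:
                    raise RuntimeError("pair-chain state space exceeded max_states")
    transient = [st for st in order if st[0] > 0 and st[1] > 0]
    tidx = {st: k for k, st in enumerate(transient)}
    rows, cols, vals = [], [], []
    r = np.zeros(len(transient))
    for st in transient:
        k = tidx[st]
        for nxt, w in transitions[index[st]]:
            if nxt[1] == 0 and nxt[0] > 0:  # mutant fixation
                r[k] += w
            elif nxt[0] > 0 and nxt[1] > 0:
                rows.append(k)
                cols.append(tidx[nxt])
                vals.append(w)
    if start[0] == 0:
        return 0.0
    if start[1] == 0:
        return 1.0
    n = len(transient)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    u = spla.spsolve(sp.eye(n, format="csr") - Q, r)
    return float(u[tidx[start]])


def renewal_speed_oracle(params: ModelParams, equalize_fixation: bool = False) -> float:
    """Net front drift in the low-migration renewal regime, in demes/generation.

    The front is a step between a mutant deme (capacity ``K(1+eps)``) and
    a wild-type deme (capacity ``K``).  It hops forward when a mutant
    migrant fixes in the wild-type deme (rate = migrant flux x fixation
    probability) and backward for the mirror event:

        v = (m/2) [ K(1+eps) * P_fix(mutant in WT deme)
                    - K * P_fix(wild in mutant deme) ]

    Fixation probabilities come from the exact pair-chain solve.
    ``equalize_fixation=True`` replaces both with the common neutral value
    ``1/(K+1)``, isolating the migrant-flux bias (half of ``v = m eps``).
    """
    if params.m * params.K > 0.1:
        warnings.warn(
            f"m*K = {params.m * params.K:.3g} is not << 1; the renewal "
            "(single-fixation) picture may not apply",
            stacklevel=2,
        )
    K, Km = params.K, params.K_mut
    if equalize_fixation:
        p_fwd = p_bwd = 1.0 / (K + 1)
    else:
        p_fwd = deme_fixation_probability(params, n0=1, n1=K)
        p_bwd = 1.0 - deme_fixation_probability(params, n0=Km, n1=1)
    return float(params.a * 0.5 * params.m * (Km * p_fwd - K * p_bwd))


# --------------------------------------------------------------------------
# simulation-side measurements
# --------------------------------------------------------------------------


def measure_front_speed(
    params: ModelParams,
    n_seeds: int = 16,
    generations: int | None = None,
    record_every: int | None = None,
    burn_in: float = 0.25,
    init_width: float | None = None,
    x0: float | None = None,
    seed: int | None = None,
) -> tuple[FrontTrajectory, SpeedEstimate]:
    """Ensemble wave-speed measurement on the individual-based model.

    Runs ``n_seeds`` replicate lattices through the batched kernel, tracks
    the mass-integral front position, and fits per-seed OLS slopes.  The
    initial profile defaults to a logistic front of the predicted
    steady-state width ``~ sqrt(D / s_eff)`` (capped at L/10) to shorten
    the relaxation transient; pass ``init_width=0`` for a hard step.
    """
    from ._kernels import run_front_ensemble

    T = params.generations if generations is None else generations
    if record_every is None:
        record_every = max(1, T // 200)
    if init_width is None:
        th = compute_theory(params)
        if th.s_eff > 0 and params.D > 0:
            init_width = min(0.5 * np.sqrt(params.D / th.s_eff), params.L / 10.0)
        else:
            init_width = 0.0
    times, pos = run_front_ensemble(
        params,
        n_seeds=n_seeds,
        generations=T,
        record_every=record_every,
        init_width=init_width,
        x0=x0,
        seed=seed,
    )
    traj = FrontTrajectory(
        times=times,
        positions=pos,
        source={"engine": "deme", "params": params, "seed": seed if seed is not None else params.seed},
    )
    return traj, estimate_speed(traj, burn_in=burn_in)


# --------------------------------------------------------------------------
# scaling collapse
# --------------------------------------------------------------------------


@dataclass
class CollapseReport:
    gammas: np.ndarray
    v_rescaled: np.ndarray
    se_rescaled: np.ndarray
    pair_max_dev_sigma: float
    monotone_decreasing: bool
    slope: float
    slope_stderr: float
    slope_points: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"Gamma": self.gammas, "v_over_v_small": self.v_rescaled, "stderr": self.se_rescaled}
        )


def scaling_collapse(runs: list[tuple[ModelParams, SpeedEstimate]]) -> CollapseReport:
    """Collapse measured speeds onto the master curve ``v/v_small`` vs Gamma.

    Requires >= 3 parameter sets spanning at least one decade of Gamma.
    Reports the worst matched-Gamma pair deviation (in units of joint
    stderr), whether the Gamma-group means are monotone decreasing, and
    the log-log slope fitted over the largest-Gamma decade (the theory
    asymptote is -1/2).
    """
    if len(runs) < 3:
        raise ValueError("need >= 3 parameter sets")
    gam, y, se = [], [], []
    for p, est in runs:
        th = compute_theory(p)
        if th.v_small <= 0 or th.Gamma <= 0:
            raise ValueError("collapse requires eps > 0 and m > 0")
        gam.append(th.Gamma)
        y.append(est.v / th.v_small)
        se.append(est.stderr / th.v_small)
    gam, y, se = map(np.asarray, (gam, y, se))
    if gam.max() / gam.min() < 10.0 * (1 - 1e-9):
        raise ValueError("Gamma range spans less than one decade")
    order = np.argsort(gam)
    gam, y, se = gam[order], y[order], se[order]

    # matched-Gamma pairs: same Gamma to within 5% in log
    pair_dev = 0.0
    for i in range(len(gam)):
        for j in range(i + 1, len(gam)):
            if abs(np.log(gam[j] / gam[i])) < 0.05:
                dev = abs(y[i] - y[j]) / np.hypot(se[i], se[j])
                pair_dev = max(pair_dev, dev)

    # group means per Gamma level, then monotonicity of the master curve
    levels = np.unique(np.round(np.log10(gam), 2))
    means = np.array(
        [y[np.abs(np.log10(gam) - lv) < 0.025].mean() for lv in levels]
    )
    monotone = bool(np.all(np.diff(means) <= 0))

    top = gam >= gam.max() / 10.0 * (1 - 1e-9)
    lx, ly = np.log10(gam[top]), np.log10(y[top])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res_, *_ = np.linalg.lstsq(A, ly, rcond=None)
    n = top.sum()
    if n > 2:
        resid = ly - A @ coef
        s2 = (resid**2).sum() / (n - 2)
        slope_se = float(np.sqrt(s2 / ((lx - lx.mean()) ** 2).sum()))
    else:
        slope_se = float("nan")
    return CollapseReport(
        gammas=gam,
        v_rescaled=y,
        se_rescaled=se,
        pair_max_dev_sigma=float(pair_dev),
        monotone_decreasing=monotone,
        slope=float(coef[0]),
        slope_stderr=slope_se,
        slope_points=int(n),
    )


# --------------------------------------------------------------------------
# evolutionarily stable strategy
# --------------------------------------------------------------------------


@dataclass
class ESSResult:
    s_star: float
    bracket: tuple[float, float]
    verdict: str
    K_star_empirical: float | None
    evaluations: list = field(default_factory=list)


def _resolve_speed_sign(
    params: ModelParams,
    n_seeds: int,
    generations: int,
    cap: int,
    seed: int,
    x0: float | None = None,
) -> tuple[float, float, int]:
    """Add replicate batches until the speed sign is resolved at 2 sigma or
    the replicate cap is hit; returns (v, stderr, total seeds)."""
    slopes: list[np.ndarray] = []
    total = 0
    batch = 0
    while total < cap:
        traj, est = measure_front_speed(
            params,
            n_seeds=min(n_seeds, cap - total),
            generations=generations,
            seed=seed + 7919 * batch,
            x0=x0,
        )
        t = traj.times
        keep = t >= t[0] + 0.25 * (t[-1] - t[0])
        tc = t[keep] - t[keep].mean()
        X = traj.positions[:, keep]
        slopes.append((X - X.mean(axis=1, keepdims=True)) @ tc / (tc**2).sum())
        total += traj.n_seeds
        batch += 1
        all_s = np.concatenate(slopes)
        v = all_s.mean()
        se = all_s.std(ddof=1) / np.sqrt(len(all_s))
        if abs(v) > 2.0 * se:
            return float(v), float(se), total
    return float(v), float(se), total


def find_ess(
    params_base: ModelParams,
    c: float | None = None,
    s_max: float | None = None,
    n_seeds: int = 16,
    generations: int | None = None,
    seed_cap: int = 64,
    tol: float | None = None,
    x0: float | None = None,
) -> ESSResult:
    """Locate the selection cost ``s*`` at which the wave speed changes sign.

    Bisects ``v(s)`` on ``[0, s_max]`` (default ``2.5 x s_eff``),
    resolving the sign at each point at 2 sigma with up to ``seed_cap``
    replicate seeds; a point whose sign cannot be resolved within the cap
    is taken as the root (the speed there is statistically zero).  Reports
    ``s*``, the final bracket, and - given a trade-off coefficient ``c`` -
    the implied evolutionarily stable capacity
    ``K*_emp = c K s* / eps`` (equal to ``c lam`` when ``s*`` matches the
    theory).  If ``v`` never changes sign on the interval, the verdict is
    monotone and ``s*`` is NaN.
    """
    th = compute_theory(params_base)
    if th.s_eff <= 0:
        raise ValueError("find_ess needs eps > 0")
    s_max = 2.5 * th.s_eff if s_max is None else s_max
    tol = th.s_eff / 8.0 if tol is None else tol
    T = params_base.generations if generations is None else generations
    evals: list[tuple[float, float, float, int]] = []

    def measure(s_val: float, k: int):
        p = params_base.with_(s=s_val)
        v, se, n = _resolve_speed_sign(
            p, n_seeds, T, seed_cap, params_base.seed + 100_003 * k, x0=x0
        )
        evals.append((s_val, v, se, n))
        return v, se, n

    v_lo, se_lo, _ = measure(0.0, 0)
    v_hi, se_hi, _ = measure(s_max, 1)
    K_emp = None

    def result(s_star: float, lo: float, hi: float, verdict: str) -> ESSResult:
        K_e = None
        if c is not None and np.isfinite(s_star):
            K_e = c * params_base.K * s_star / params_base.eps
        return ESSResult(
            s_star=s_star, bracket=(lo, hi), verdict=verdict, K_star_empirical=K_e, evaluations=evals
        )

    if v_lo <= 0 and abs(v_lo) > 2 * se_lo:
        return result(float("nan"), 0.0, s_max, "monotone_negative")
    if v_hi >= 0 and abs(v_hi) > 2 * se_hi:
        return result(float("nan"), 0.0, s_max, "monotone_positive")
    lo, hi = 0.0, s_max
    k = 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        v, se, n = measure(mid, k)
        k += 1
        if abs(v) <= 2 * se:  # sign indeterminate at the cap: statistically zero
            return result(mid, lo, hi, "indeterminate_at_cap")
        if v > 0:
            lo = mid
        else:
            hi = mid
    return result(0.5 * (lo + hi), lo, hi, "bracketed")
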