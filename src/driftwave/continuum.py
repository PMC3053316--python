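"""Continuum limit of the stepping-stone model.

Migration between demes is approximated by diffusion with diffusivity
``D = m a^2 / 2``.  The coupled density/frequency system is

    dn/dt = D n_xx + r0 (1 - n / K_c(f)) n
    df/dt = D f_xx + 2 D (d/dx ln n) f_x - s f (1 - f)

For small migration rates the density tracks the carrying capacity
(quasi-static closure ``n = K_c(f)``), which closes the frequency
equation:

    df/dt = D f_xx + 2 D eps f_x^2 / (1 + eps f) - s f (1 - f)

The gradient-squared nonlinearity is removed by the Cole-Hopf field

    h(f) = [(1 + eps f)^3 - 1] / [(1 + eps)^3 - 1],

a monotone bijection of [0,1] with ``h ~ f`` to leading order in eps,
under which the deterministic quasi-static equation becomes pure
diffusion: no traveling wave, only a front broadening like sqrt(D t).

With genetic drift the frequency obeys the Ito SPDE

    df = [D f_xx + 2 D eps f_x^2/(1+eps f) - s f(1-f)] dt
         + sqrt(lam f(1-f) / (n dx)) dW,   n = K_c(f) dx per deme,

and the same transformation picks up a spurious Ito drift that is a
logistic growth term ``s_eff h (1 - h)`` favouring the mutants - the
mathematical heart of noise-driven waves.  After rescaling space and time
the transformed equation is a stochastic Fisher-Kolmogorov equation whose
noise strength is controlled by the single parameter ``Gamma = D K eps / lam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import ModelParams

__all__ = [
    "ContinuumField",
    "NoiseSpec",
    "make_field",
    "cole_hopf",
    "inverse_cole_hopf",
    "step_deterministic",
    "step_quasistatic",
    "step_spde",
    "step_mapped_sfkpp",
    "run_continuum",
    "measure_ito_drift",
]


@dataclass
class ContinuumField:
    """Discretised density/frequency fields for the PDE/SPDE solvers.

    ``n`` is carried only by the full deterministic system; the
    quasi-static, SPDE and mapped solvers evolve ``f`` (or the transformed
    field) alone.
    """

    x: np.ndarray
    f: np.ndarray
    n: np.ndarray | None = None
    t: float = 0.0
    D: float = 0.05
    dx: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if (self.f < 0).any() or (self.f > 1).any():
            raise ValueError("f must lie in [0, 1]")
        if self.n is not None and (np.asarray(self.n) < 0).any():
            raise ValueError("n must be non-negative")

    def copy(self) -> "ContinuumField":
        return ContinuumField(
            self.x.copy(),
            self.f.copy(),
            None if self.n is None else self.n.copy(),
            self.t,
            self.D,
            self.dx,
            self.dt,
        )


@dataclass
class NoiseSpec:
    """Wright-Fisher noise discretisation (Ito interpretation).

    Per step, each grid cell receives an independent Gaussian increment of
    standard deviation ``sqrt(lam f(1-f) dt / (n dx))`` where ``n dx`` is
    the local population per cell; the amplitude vanishes exactly at f = 0
    and f = 1.  ``quasistatic_n=True`` evaluates ``n = K_c(f)`` (the
    closure used throughout the analytics); ``False`` would use a
    dynamically evolved density, which this package does not integrate in
    the SPDE (the difference is O(m)).
    """

    lam: float = 1.0
    interpretation: Literal["ito"] = "ito"
    quasistatic_n: bool = True

    def amplitude(self, f: np.ndarray, params: ModelParams, dx: float, dt: float) -> np.ndarray:
        n = params.K * (1.0 + params.eps * f) * dx
        var = self.lam * np.clip(f * (1.0 - f), 0.0, None) * dt / n
        return np.sqrt(var)


def make_field(
    params: ModelParams,
    L: int | None = None,
    dx: float = 1.0,
    dt: float | None = None,
    x0: float | None = None,
    width: float = 0.0,
    with_density: bool = False,
) -> ContinuumField:
    """Step (or logistic-smoothed) tug-of-war initial condition on a grid."""
    L = params.L if L is None else L
    n_cells = int(round(L / dx))
    x = (np.arange(n_cells) + 0.5) * dx
    if x0 is None:
        x0 = L / 2.0
    if width > 0:
        f = 1.0 / (1.0 + np.exp(np.clip((x - x0) / width, -50, 50)))
    else:
        f = np.where(x < x0, 1.0, 0.0)
    D = params.D
    if dt is None:
        # honour both the diffusive CFL limit and the logistic reaction rate
        dt_diff = 0.2 * dx**2 / (2.0 * D) if D > 0 else np.inf
        dt = min(dt_diff, 0.5 / params.r0)
    n = params.K * (1.0 + params.eps * f) if with_density else None
    return ContinuumField(x=x, f=f, n=n, t=0.0, D=D, dx=dx, dt=dt)


def cole_hopf(f, eps: float):
    """Cole-Hopf field ``h(f) = [(1+eps f)^3 - 1] / [(1+eps)^3 - 1]``.

    Monotone bijection [0,1] -> [0,1] with h(0)=0, h(1)=1 and ``h = f +
    O(eps)``; turns the quasi-static frequency equation into pure
    diffusion.  ``eps = 0`` is the identity.
    """
    f = np.asarray(f, dtype=float)
    if (f < -1e-12).any() or (f > 1 + 1e-12).any():
        raise ValueError("f must lie in [0, 1]")
    # ((1+eps f)^3 - 1)/((1+eps)^3 - 1) written with the common factor eps
    # cancelled, which stays well conditioned as eps -> 0
    u = eps * f
    out = f * (3.0 + 3.0 * u + u * u) / (3.0 + 3.0 * eps + eps * eps)
    return float(out) if out.ndim == 0 else out


def inverse_cole_hopf(h, eps: float):
    """Inverse of :func:`cole_hopf`, exact to machine precision."""
    h = np.asarray(h, dtype=float)
    if eps == 0.0:
        out = h.copy()
    else:
        # f = ((1 + h ((1+eps)^3 - 1))^{1/3} - 1)/eps via log1p/expm1 so the
        # small-eps cancellation is exact
        d = eps * (3.0 + 3.0 * eps + eps * eps)
        out = np.expm1(np.log1p(h * d) / 3.0) / eps
    return float(out) if out.ndim == 0 else out


def _cole_hopf_d1(f, eps: float):
    """dh/df = 3 (1+eps f)^2 / (3 + 3 eps + eps^2)."""
    f = np.asarray(f, dtype=float)
    return 3.0 * (1.0 + eps * f) ** 2 / (3.0 + 3.0 * eps + eps * eps)


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    """Second difference with zero-flux (Neumann) boundaries."""
    out = np.empty_like(u)
    out[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
    out[0] = u[1] - u[0]
    out[-1] = u[-2] - u[-1]
    return out / dx**2


def _gradient(u: np.ndarray, dx: float) -> np.ndarray:
    return np.gradient(u, dx)


def _check_stability(fieldD: float, dx: float, dt: float) -> None:
    if fieldD > 0 and dt > dx**2 / (2.0 * fieldD) * (1.0 + 1e-12):
        raise ValueError(
            f"explicit scheme unstable: dt={dt} exceeds dx^2/(2D)={dx**2/(2*fieldD):.4g}"
        )


def step_deterministic(fld: ContinuumField, params: ModelParams) -> ContinuumField:
    """One explicit step of the coupled (n, f) system."""
    _check_stability(fld.D, fld.dx, fld.dt)
    if fld.dt * params.r0 > 2.0:
        raise ValueError(
            f"explicit logistic step unstable: dt={fld.dt} exceeds 2/r0={2.0/params.r0:.4g}"
        )
    if fld.n is None:
        raise ValueError("deterministic stepper needs a density field; build with with_density=True")
    n, f, D, dx, dt = fld.n, fld.f, fld.D, fld.dx, fld.dt
    Kc = params.K * (1.0 + params.eps * f)
    growth = params.r0 * (1.0 - n / Kc)
    n_new = n + dt * (D * _laplacian(n, dx) + growth * n)
    grad_ln_n = _gradient(np.log(np.clip(n, 1e-300, None)), dx)
    f_new = f + dt * (
        D * _laplacian(f, dx)
        + 2.0 * D * grad_ln_n * _gradient(f, dx)
        - params.s * f * (1.0 - f)
    )
    out = fld.copy()
    out.n = np.clip(n_new, 0.0, None)
    out.f = np.clip(f_new, 0.0, 1.0)
    out.t = fld.t + dt
    return out


def step_quasistatic(fld: ContinuumField, params: ModelParams) -> ContinuumField:
    """One explicit step of the closed frequency equation (n = K_c(f))."""
    _check_stability(fld.D, fld.dx, fld.dt)
    f, D, dx, dt = fld.f, fld.D, fld.dx, fld.dt
    grad = _gradient(f, dx)
    f_new = f + dt * (
        D * _laplacian(f, dx)
        + 2.0 * D * params.eps * grad**2 / (1.0 + params.eps * f)
        - params.s * f * (1.0 - f)
    )
    out = fld.copy()
    out.f = np.clip(f_new, 0.0, 1.0)
    out.t = fld.t + dt
    return out


def step_spde(
    fld: ContinuumField,
    params: ModelParams,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> ContinuumField:
    """Euler-Maruyama step: quasi-static drift plus Wright-Fisher noise.

    Ito interpretation; f is clipped to [0,1] and the uniform states f=0
    and f=1 are absorbing (noise amplitude vanishes there).
    """
    _check_stability(fld.D, fld.dx, fld.dt)
    det = step_quasistatic(fld, params)
    amp = noise.amplitude(fld.f, params, fld.dx, fld.dt)
    if amp.max() > 0.25:
        import warnings

        warnings.warn(
            f"noise amplitude per step reaches {amp.max():.2f}; reduce dt", stacklevel=2
        )
    det.f = np.clip(det.f + amp * rng.standard_normal(fld.f.shape), 0.0, 1.0)
    return det


def step_mapped_sfkpp(
    h_fld: ContinuumField,
    effective,
    rng: np.random.Generator | None = None,
) -> ContinuumField:
    """One step of the mapped stochastic Fisher-Kolmogorov equation.

    Works in rescaled units (unit diffusivity and unit logistic rate, so
    the deterministic pulled-front speed is 2):

        du = [u_xx + u(1-u)] dt + Gamma^(-1/4) sqrt(u(1-u) dt / dx) xi

    ``effective`` is a :class:`driftwave.fronts.TheoryBundle`; its
    ``Gamma`` sets the noise strength and its ``D``/``s_eff`` convert
    speeds back to lattice units via ``v = v_rescaled * sqrt(D s_eff)``.
    ``rng=None`` runs the noiseless FKPP limit.

    The noise is generated by binomial resampling of each cell with an
    effective per-cell population ``N = dx / (Gamma^(-1/2) dt)``, which
    has exactly the Wright-Fisher variance above.  A Gaussian increment
    clipped to [0,1] would bias pulled fronts badly: at the absorbing tip
    negative kicks are clipped while positive ones survive and are
    amplified, a ratchet that inflates the front speed many-fold.
    Sampling keeps u = 0 absorbing and reproduces the finite-population
    cutoff that sets the true stochastic front speed.
    """
    _check_stability(1.0, h_fld.dx, h_fld.dt)
    u, dx, dt = h_fld.f, h_fld.dx, h_fld.dt
    u_new = u + dt * (_laplacian(u, dx) + u * (1.0 - u))
    u_new = np.clip(u_new, 0.0, 1.0)
    if rng is not None and effective.Gamma > 0:
        n_cell = max(1, int(round(dx * effective.Gamma**0.5 / dt)))
        u_new = rng.binomial(n_cell, u_new) / n_cell
    out = h_fld.copy()
    out.f = u_new.astype(float)
    out.t = h_fld.t + dt
    return out


def run_continuum(
    params: ModelParams,
    engine: Literal["deterministic", "quasistatic", "spde"] = "deterministic",
    T: float | None = None,
    dx: float = 1.0,
    dt: float | None = None,
    L: int | None = None,
    record_every: float = 10.0,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    x0: float | None = None,
    width: float = 0.0,
):
    """Evolve a tug-of-war profile; return (times, f_records, final field)."""
    T = float(params.generations) if T is None else T
    fld = make_field(
        params, L=L, dx=dx, dt=dt, x0=x0, width=width, with_density=engine == "deterministic"
    )
    if engine == "spde":
        noise = noise or NoiseSpec(lam=params.lam)
        rng = rng or np.random.default_rng(params.seed)
    times = [0.0]
    records = [fld.f.copy()]
    next_record = record_every
    while fld.t < T - 1e-9:
        if engine == "deterministic":
            fld = step_deterministic(fld, params)
        elif engine == "quasistatic":
            fld = step_quasistatic(fld, params)
        elif engine == "spde":
            fld = step_spde(fld, params, noise, rng)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        if fld.t >= next_record - 1e-9:
            times.append(fld.t)
            records.append(fld.f.copy())
            next_record += record_every
    return np.asarray(times), records, fld


def measure_ito_drift(
    params: ModelParams,
    rng: np.random.Generator | None = None,
    f_values: np.ndarray | None = None,
    reps: int = 400,
    n_steps: int = 250,
    dt: float = 0.01,
) -> float:
    """Measured logistic drift rate of the Cole-Hopf field in a well-mixed deme.

    Runs zero-dimensional (no diffusion) sampling-noise trajectories
    ``df = sqrt(lam f(1-f)/K_c(f)) dW`` from a range of starting
    frequencies, transforms pathwise to ``h`` and estimates the spurious
    Ito drift coefficient by regressing the per-step increment

        q = h(f') - h(f) - h'(f) (f' - f)

    against ``h(1-h) dt``.  Subtracting the martingale part ``h'(f) df``
    is a zero-mean control variate: it leaves exactly the Ito correction
    (h is cubic in f, so no higher-order terms survive in expectation) and
    shrinks the estimator variance by a factor of order dt.  The result
    should match ``compute_theory(params).s_eff``; it is the noise-induced
    effective growth-rate advantage of the mutants.
    """
    rng = rng or np.random.default_rng(params.seed)
    if f_values is None:
        f_values = np.linspace(0.15, 0.85, 8)
    f = np.repeat(np.asarray(f_values, dtype=float), reps)
    num = 0.0
    den = 0.0
    eps, lam, K = params.eps, params.lam, params.K
    for _ in range(n_steps):
        amp = np.sqrt(lam * np.clip(f * (1.0 - f), 0.0, None) * dt / (K * (1.0 + eps * f)))
        f_next = np.clip(f + amp * rng.standard_normal(f.shape), 0.0, 1.0)
        h = cole_hopf(f, eps)
        q = cole_hopf(f_next, eps) - h - _cole_hopf_d1(f, eps) * (f_next - f)
        num += q.sum()
        den += (h * (1.0 - h) * dt).sum()
        f = f_next
    return float(num / den)
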