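"""Core model definitions shared by every simulator.

The model is a linear stepping-stone habitat: ``L`` demes (well-mixed
subpopulations) coupled by nearest-neighbour migration.  Two types compete
for one limited resource: wild type (counts ``N1``) and a mutant (counts
``N0``) whose only intrinsic difference is that it uses the resource more
economically.  A deme containing a mutant fraction ``f`` can therefore
sustain a larger equilibrium population,

    K_c(f) = K * (1 + eps * f),

interpolating between ``K`` (all wild type) and ``K*(1+eps)`` (all mutant).
The mutant may additionally pay a growth-rate cost ``s`` per generation
(rate-yield trade-off).  Genetic drift enters through the sampling step of
the stochastic simulator; this module holds only the deterministic
per-generation expectation that all simulators share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "LatticeState",
    "carrying_capacity",
    "growth_expectation",
    "tug_of_war",
]

Boundary = Literal["reservoir", "reflecting"]


@dataclass
class ModelParams:
    """Scalar parameters of the deme model and run control.

    Parameters
    ----------
    m : migration probability per individual per generation (split evenly
        between the two neighbouring demes).
    K : wild-type carrying capacity per deme, in individuals.
    eps : relative carrying-capacity increase of mutants (the "yield
        effect" of the mutation).
    s : selective disadvantage of mutants per generation.
    lam : variance in offspring number; scales the strength of genetic
        drift (plain Wright-Fisher sampling has ``lam = 1``).
    r0 : low-density per-capita birth rate per generation.
    L : number of demes.
    a : deme spacing, in length units.  ``D = m * a**2 / 2``.
    generations : default run length.
    seed : RNG seed.
    boundary : ``"reservoir"`` pins the left edge all-mutant at capacity
        and the right edge all-wild-type at capacity (keeps a single front
        in frame); ``"reflecting"`` conserves both types exactly.
    """

    m: float = 0.1
    K: int = 100
    eps: float = 0.1
    s: float = 0.0
    lam: float = 1.0
    r0: float = 1.0
    L: int = 200
    a: float = 1.0
    generations: int = 1000
    seed: int = 0
    boundary: Boundary = "reservoir"

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m={self.m} outside [0, 1]")
        if self.K < 2:
            raise ValueError(f"K={self.K} must be >= 2")
        if not abs(self.eps) < 1.0:
            raise ValueError(f"eps={self.eps} must satisfy |eps| < 1")
        if self.s < 0.0:
            raise ValueError(f"s={self.s} must be >= 0")
        if self.lam <= 0.0:
            raise ValueError(f"lam={self.lam} must be > 0")
        if self.r0 <= 0.0:
            raise ValueError(f"r0={self.r0} must be > 0")
        if self.L < 2:
            raise ValueError(f"L={self.L} must be >= 2")
        if self.a <= 0.0:
            raise ValueError(f"a={self.a} must be > 0")
        if self.boundary not in ("reservoir", "reflecting"):
            raise ValueError(f"boundary={self.boundary!r} not in {{reservoir, reflecting}}")

    # diffusivity of the continuum limit of nearest-neighbour hopping
    @property
    def D(self) -> float:
        return 0.5 * self.m * self.a**2

    @property
    def K_mut(self) -> int:
        """Integer carrying capacity of an all-mutant deme."""
        return int(round(self.K * (1.0 + self.eps)))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class LatticeState:
    """Per-deme mutant (``N0``) and wild-type (``N1``) counts at one generation."""

    N0: np.ndarray
    N1: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.N0 = np.asarray(self.N0, dtype=np.int64)
        self.N1 = np.asarray(self.N1, dtype=np.int64)
        if self.N0.shape != self.N1.shape:
            raise ValueError("N0 and N1 must have the same shape")
        if (self.N0 < 0).any() or (self.N1 < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> np.ndarray:
        return self.N0 + self.N1

    def frequency(self, empty: float = 0.0) -> np.ndarray:
        """Mutant frequency per deme; ``empty`` is substituted where N = 0."""
        N = self.N
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(N > 0, self.N0 / np.maximum(N, 1), empty)
        return f

    def copy(self) -> "LatticeState":
        return LatticeState(self.N0.copy(), self.N1.copy(), self.t)


def carrying_capacity(f, params: ModelParams):
    """Frequency-dependent carrying capacity ``K_c(f) = K * (1 + eps * f)``.

    ``f`` may be a scalar or array of mutant frequencies in [0, 1].
    """
    f = np.asarray(f, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("mutant frequency must lie in [0, 1]")
    out = params.K * (1.0 + params.eps * f)
    return float(out) if out.ndim == 0 else out


def growth_expectation(counts, params: ModelParams):
    """Expected next-generation counts of one deme before sampling.

    Both types share the logistic factor ``g = r0 * (1 - N / K_c(f))``; an
    antisymmetric selection term of magnitude ``s * N0 * N1 / N`` shifts
    expected numbers from mutant to wild type.  The two selection terms sum
    to zero, so the expected total is unaffected by ``s``, and the expected
    frequency change from selection alone is ``-s f (1-f)`` to leading
    order.  Negative expectations (possible only for large ``r0`` overshoot
    or large ``s``) are clipped at zero.  Empty demes return (0, 0):
    colonisation happens only via migration.

    Accepts scalars or per-deme arrays; returns a float pair / float arrays.
    """
    N0 = np.asarray(counts[0], dtype=float)
    N1 = np.asarray(counts[1], dtype=float)
    N = N0 + N1
    occupied = N > 0
    Nsafe = np.where(occupied, N, 1.0)
    f = N0 / Nsafe
    Kc = params.K * (1.0 + params.eps * f)
    g = params.r0 * (1.0 - N / Kc)
    sel = params.s * N0 * N1 / Nsafe
    e0 = np.where(occupied, np.maximum(N0 * (1.0 + g) - sel, 0.0), 0.0)
    e1 = np.where(occupied, np.maximum(N1 * (1.0 + g) + sel, 0.0), 0.0)
    if e0.ndim == 0:
        return float(e0), float(e1)
    return e0, e1


def tug_of_war(params: ModelParams, x0: float | None = None, width: float = 0.0) -> LatticeState:
    """Initial condition staging a tug of war between the two types.

    All demes left of ``x0`` (default: mid-lattice) are mutant at the
    mutant capacity ``K*(1+eps)``, all demes to the right are wild type at
    capacity ``K``.  With ``width > 0`` the step is smoothed into a
    logistic profile ``f = 1 / (1 + exp((x - x0)/width))``, which shortens
    the initial front-relaxation transient for broad-front runs.  The
    logistic tails are truncated at f < 0.02 (and f > 0.98): for large K
    the rounded far tail would otherwise seed isolated pioneer individuals
    many demes ahead of the front, which a step-like founding population
    does not contain; the genuine stochastic tail builds up dynamically.
    """
    L = params.L
    if x0 is None:
        x0 = L / 2.0
    x = np.arange(L, dtype=float)
    if width > 0:
        f = 1.0 / (1.0 + np.exp(np.clip((x - x0) / width, -50, 50)))
        f[f < 0.02] = 0.0
        f[f > 0.98] = 1.0
    else:
        f = np.where(x < x0, 1.0, 0.0)
    Kc = params.K * (1.0 + params.eps * f)
    N0 = np.rint(Kc * f).astype(np.int64)
    N1 = np.rint(Kc * (1.0 - f)).astype(np.int64)
    return LatticeState(N0, N1, t=0)
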