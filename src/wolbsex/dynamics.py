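"""Deterministic dynamics of a feminizing cytoplasmic sex-ratio distorter in an
XY/XX population.

The model tracks six genotype classes across non-overlapping generations:
uninfected XY males (``g1``), uninfected YY males (``g3``), uninfected XX
females (``g2``), and infected females of the three sex-chromosome genotypes
(``g4`` = XX, ``g6`` = XY, ``g8`` = YY).  Infection feminizes: every carrier
develops as a female, so genetic males (XY, YY) carrying the symbiont appear
in the female classes.  An infected mother transmits the symbiont to each
offspring independently with a probability that depends on her own
sex-chromosome genotype (``t_x`` for XX, ``t_xy`` for XY, ``t_y`` for YY
mothers).  Mating is random; gamete pools are formed from the current
genotype frequencies and offspring classes are products of the normalized
sperm and egg pools.

Class indices follow the 1,2,3,4,6,8 numbering convention of the underlying
genetic model; indices 5 and 7 are intentionally absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeState",
    "GametePools",
    "TransmissionRates",
    "EquilibriumResult",
    "DoseSummary",
    "STANDARD_XY_XX",
    "perturbed_start",
    "male_gametes",
    "female_gametes",
    "next_generation",
    "iterate_to_equilibrium",
    "summarize_state",
    "sweep_alpha",
    "trajectory",
    "invasion_threshold",
    "persistence_threshold",
    "invaded_jacobian",
]

_SUM_TOL = 1e-9

#: distorter is declared extinct below this frequency and clamped to zero
EXTINCTION_THRESHOLD = 1e-9


class NoMalesError(ValueError):
    """Raised when a reproducing population contains no males."""


class NoFemalesError(ValueError):
    """Raised when a reproducing population contains no females."""


@dataclass(frozen=True)
class GenotypeState:
    """Frequencies of the six genotype classes at one generation.

    Attributes
    ----------
    g1, g3
        Uninfected XY and YY males.
    g2
        Uninfected XX females.
    g4, g6, g8
        Infected XX, XY and YY females (all feminized carriers).
    """

    g1: float = 0.0
    g2: float = 0.0
    g3: float = 0.0
    g4: float = 0.0
    g6: float = 0.0
    g8: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g1", "g2", "g3", "g4", "g6", "g8"):
            v = getattr(self, name)
            if v < -_SUM_TOL:
                raise ValueError(f"negative class frequency {name}={v}")
        total = self.g1 + self.g2 + self.g3 + self.g4 + self.g6 + self.g8
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class frequencies sum to {total}, expected 1")

    @property
    def male_freq(self) -> float:
        return self.g1 + self.g3

    @property
    def female_freq(self) -> float:
        return self.g2 + self.g4 + self.g6 + self.g8

    @property
    def distorter_freq(self) -> float:
        return self.g4 + self.g6 + self.g8

    def as_array(self) -> np.ndarray:
        return np.array([self.g1, self.g2, self.g3, self.g4, self.g6, self.g8])

    @staticmethod
    def from_array(a: Sequence[float]) -> "GenotypeState":
        g1, g2, g3, g4, g6, g8 = a
        return GenotypeState(g1=g1, g2=g2, g3=g3, g4=g4, g6=g6, g8=g8)


@dataclass(frozen=True)
class GametePools:
    """Normalized sperm (p1=Y, p3=X) and egg (p2=X, p4=Y, p6=X.Wo+, p8=Y.Wo+)
    pools."""

    p1: float = 0.0
    p3: float = 0.0
    p2: float = 0.0
    p4: float = 0.0
    p6: float = 0.0
    p8: float = 0.0


@dataclass(frozen=True)
class TransmissionRates:
    """Maternal symbiont transmission rates by mother genotype.

    ``t_x`` applies to infected XX mothers, ``t_xy`` to infected XY mothers
    and ``t_y`` to infected YY mothers.  All are per-offspring probabilities
    in [0, 1].
    """

    t_x: float
    t_xy: float
    t_y: float

    def __post_init__(self) -> None:
        for name in ("t_x", "t_xy", "t_y"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @staticmethod
    def from_alpha(alpha: float, mode: Literal["blocked", "uniform"]) -> "TransmissionRates":
        """Scalar parameterization: ``blocked`` sets t_y=0 (YY mothers do not
        transmit), ``uniform`` sets all three rates to ``alpha``."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha={alpha} outside [0, 1]")
        if mode == "blocked":
            return TransmissionRates(alpha, alpha, 0.0)
        if mode == "uniform":
            return TransmissionRates(alpha, alpha, alpha)
        raise ValueError(f"unknown mode {mode!r}; expected 'blocked' or 'uniform'")


@dataclass(frozen=True)
class DoseSummary:
    """Expected sex-chromosome copy counts, by default per mating pair
    (one male + one female drawn from the current genotype distributions)."""

    y_dose: float
    x_dose: float
    autosome_dose: float
    per_individual: bool = False

    @property
    def y_to_x(self) -> float:
        return self.y_dose / self.x_dose if self.x_dose else math.inf

    @property
    def x_to_y(self) -> float:
        return self.x_dose / self.y_dose if self.y_dose else math.inf

    @property
    def y_to_a(self) -> float:
        return self.y_dose / self.autosome_dose

    @property
    def x_to_a(self) -> float:
        return self.x_dose / self.autosome_dose


@dataclass(frozen=True)
class EquilibriumResult:
    state: GenotypeState
    x_freq: float
    y_freq: float
    distorter_freq: float
    female_freq: float
    generations: int
    converged: bool
    distorter_lost: bool


#: the distorter-free XY/XX population: half XY males, half XX females
STANDARD_XY_XX = GenotypeState(g1=0.5, g2=0.5)


def perturbed_start(eps: float = 0.01) -> GenotypeState:
    """Distorter-free XY/XX equilibrium with a fraction ``eps`` of the females
    converted to infected XX females — the canonical introduction scenario."""
    if not 0.0 < eps < 1.0:
        raise ValueError("eps must be in (0, 1)")
    return GenotypeState(g1=0.5, g2=0.5 * (1.0 - eps), g4=0.5 * eps)


def male_gametes(state: GenotypeState) -> GametePools:
    """Sperm pool: p1 = (g1/2 + g3)/F_M (Y sperm), p3 = (g1/2)/F_M (X sperm)."""
    fm = state.male_freq
    if fm <= 0.0:
        raise NoMalesError("no males: population not viable")
    return GametePools(p1=(state.g1 / 2.0 + state.g3) / fm, p3=(state.g1 / 2.0) / fm)


def female_gametes(state: GenotypeState, rates: TransmissionRates) -> GametePools:
    """Egg pool with genotype-dependent maternal transmission.

    Infected XY mothers pass X and Y eggs in equal numbers; each egg carries
    the symbiont with probability ``t_xy``, hence the symmetric tXY/2 splits.
    """
    ff = state.female_freq
    if ff <= 0.0:
        raise NoFemalesError("no females: population not viable")
    tx, txy, ty = rates.t_x, rates.t_xy, rates.t_y
    p2 = (state.g2 + state.g4 * (1 - tx) + state.g6 * (1 - txy) / 2.0) / ff
    p4 = (state.g6 * (1 - txy) / 2.0 + state.g8 * (1 - ty)) / ff
    p6 = (state.g4 * tx + state.g6 * txy / 2.0) / ff
    p8 = (state.g8 * ty + state.g6 * txy / 2.0) / ff
    return GametePools(p2=p2, p4=p4, p6=p6, p8=p8)


def next_generation(state: GenotypeState, rates: TransmissionRates) -> GenotypeState:
    """One generation of random mating.

    Offspring classes are products of the sperm and egg pools: an uninfected
    egg fertilized by Y sperm gives an XY male if the egg carried X (p1*p2)
    or a YY male if it carried Y (p1*p4), and so on.  Infected eggs (p6, p8)
    produce the infected — hence female — classes regardless of genotype.
    """
    sperm = male_gametes(state)
    eggs = female_gametes(state, rates)
    p1, p3 = sperm.p1, sperm.p3
    p2, p4, p6, p8 = eggs.p2, eggs.p4, eggs.p6, eggs.p8
    return GenotypeState(
        g1=p1 * p2 + p3 * p4,
        g3=p1 * p4,
        g2=p3 * p2,
        g4=p3 * p6,
        g6=p1 * p6 + p3 * p8,
        g8=p1 * p8,
    )


def _step(g: tuple, tx: float, txy: float, ty: float) -> tuple:
    # unboxed hot loop used by iterate_to_equilibrium / trajectory
    g1, g2, g3, g4, g6, g8 = g
    fm = g1 + g3
    ff = g2 + g4 + g6 + g8
    if fm <= 0.0:
        raise NoMalesError("no males: population not viable")
    if ff <= 0.0:
        raise NoFemalesError("no females: population not viable")
    p1 = (g1 / 2.0 + g3) / fm
    p3 = (g1 / 2.0) / fm
    p2 = (g2 + g4 * (1 - tx) + g6 * (1 - txy) / 2.0) / ff
    p4 = (g6 * (1 - txy) / 2.0 + g8 * (1 - ty)) / ff
    p6 = (g4 * tx + g6 * txy / 2.0) / ff
    p8 = (g8 * ty + g6 * txy / 2.0) / ff
    return (
        p1 * p2 + p3 * p4,
        p3 * p2,
        p1 * p4,
        p3 * p6,
        p1 * p6 + p3 * p8,
        p1 * p8,
    )


def summarize_state(state: GenotypeState) -> tuple[float, float, float, float, DoseSummary]:
    """Chromosome-copy frequencies, distorter frequency, female frequency and
    the chromosome dose summary.

    X and Y frequencies are counted among the sex-chromosome copies carried by
    individuals (each diploid individual carries two), not among gametes.
    """
    g1, g2, g3, g4, g6, g8 = state.g1, state.g2, state.g3, state.g4, state.g6, state.g8
    x_freq = (g1 + 2 * g2 + 2 * g4 + g6) / 2.0
    y_freq = (g1 + 2 * g3 + g6 + 2 * g8) / 2.0
    fm, ff = state.male_freq, state.female_freq
    if fm > 0 and ff > 0:
        # expected copies contributed by one male plus one female
        male_x = (g1 * 1) / fm
        male_y = (g1 * 1 + g3 * 2) / fm
        female_x = (g2 * 2 + g4 * 2 + g6 * 1) / ff
        female_y = (g6 * 1 + g8 * 2) / ff
        dose = DoseSummary(y_dose=male_y + female_y, x_dose=male_x + female_x, autosome_dose=4.0)
    else:
        dose = DoseSummary(y_dose=math.nan, x_dose=math.nan, autosome_dose=4.0)
    return x_freq, y_freq, state.distorter_freq, state.female_freq, dose


def iterate_to_equilibrium(
    state0: GenotypeState,
    rates: TransmissionRates,
    tol: float = 1e-12,
    max_gen: int = 1_000_000,
) -> EquilibriumResult:
    """Iterate the recursion until the maximum per-class change drops below
    ``tol`` or ``max_gen`` generations elapse.

    The distorter is declared lost when its frequency falls below the
    extinction threshold (1e-9); the infected classes are then clamped to
    exactly zero so a numerically dying infection is not reported as
    persistence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    tx, txy, ty = rates.t_x, rates.t_xy, rates.t_y
    g = tuple(state0.as_array())
    converged = False
    n = 0
    for n in range(1, max_gen + 1):
        g_new = _step(g, tx, txy, ty)
        delta = max(abs(a - b) for a, b in zip(g_new, g))
        g = g_new
        if g[3] + g[4] + g[5] < EXTINCTION_THRESHOLD:
            g = (g[0], g[1], g[2], 0.0, 0.0, 0.0)
            s = sum(g)
            g = tuple(v / s for v in g)
        if delta < tol:
            converged = True
            break
    state = GenotypeState.from_array(g)
    x_freq, y_freq, distorter_freq, female_freq, _ = summarize_state(state)
    return EquilibriumResult(
        state=state,
        x_freq=x_freq,
        y_freq=y_freq,
        distorter_freq=distorter_freq,
        female_freq=female_freq,
        generations=n,
        converged=converged,
        distorter_lost=distorter_freq < EXTINCTION_THRESHOLD,
    )


def trajectory(
    state0: GenotypeState, rates: TransmissionRates, n_gen: int
) -> pd.DataFrame:
    """Time series of (female_freq, distorter_freq, x_freq, y_freq) for
    generations 0..n_gen inclusive."""
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    tx, txy, ty = rates.t_x, rates.t_xy, rates.t_y
    g = tuple(state0.as_array())
    rows = []
    for gen in range(n_gen + 1):
        state = GenotypeState.from_array(g)
        x, y, d, f, _ = summarize_state(state)
        rows.append((gen, f, d, x, y))
        if gen < n_gen:
            g = _step(g, tx, txy, ty)
    return pd.DataFrame(
        rows, columns=["generation", "female_freq", "distorter_freq", "x_freq", "y_freq"]
    )


def sweep_alpha(
    mode: Literal["blocked", "uniform"],
    alphas: Sequence[float],
    start: GenotypeState | None = None,
    tol: float = 1e-12,
    max_gen: int = 1_000_000,
) -> pd.DataFrame:
    """Equilibrium summary for each transmission rate ``alpha`` on a grid.

    Returns one row per alpha with equilibrium chromosome, distorter and
    female frequencies, the final class frequencies and convergence flags.
    """
    if start is None:
        start = perturbed_start()
    rows = []
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"alpha={a} outside [0, 1]")
        rates = TransmissionRates.from_alpha(a, mode)
        res = iterate_to_equilibrium(start, rates, tol=tol, max_gen=max_gen)
        s = res.state
        rows.append(
            dict(
                alpha=a,
                converged=res.converged,
                generations=res.generations,
                x_freq=res.x_freq,
                y_freq=res.y_freq,
                distorter_freq=res.distorter_freq,
                female_freq=res.female_freq,
                distorter_lost=res.distorter_lost,
                g1=s.g1,
                g2=s.g2,
                g3=s.g3,
                g4=s.g4,
                g6=s.g6,
                g8=s.g8,
            )
        )
    return pd.DataFrame(rows)


def invaded_jacobian(alpha: float, mode: Literal["blocked", "uniform"]) -> np.ndarray:
    """Jacobian of the infected-class subsystem (g4, g6, g8) linearized at the
    distorter-free XY/XX equilibrium (sperm pools 1/2 each, eggs all
    uninfected X).

    At that equilibrium, to first order in the infected classes::

        g4' = t_x*g4 + t_xy/2*g6
        g6' = t_x*g4 + t_xy*g6 + t_y*g8
        g8' =          t_xy/2*g6 + t_y*g8
    """
    r = TransmissionRates.from_alpha(alpha, mode)
    return np.array(
        [
            [r.t_x, r.t_xy / 2.0, 0.0],
            [r.t_x, r.t_xy, r.t_y],
            [0.0, r.t_xy / 2.0, r.t_y],
        ]
    )


def leading_eigenvalue(alpha: float, mode: Literal["blocked", "uniform"]) -> float:
    """Spectral radius of the infected-subsystem Jacobian; the distorter
    invades from rarity iff this exceeds 1."""
    return float(np.max(np.abs(np.linalg.eigvals(invaded_jacobian(alpha, mode)))))


def invasion_threshold(
    mode: Literal["blocked", "uniform"], tol: float = 1e-9
) -> tuple[float, Callable[[float], float]]:
    """Critical alpha at which the leading eigenvalue of the linearized
    infected subsystem crosses 1, found by bisection on [0, 1].

    Returns the threshold and the eigenvalue function for inspection.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")

    def eig(a: float) -> float:
        return leading_eigenvalue(a, mode)

    lo, hi = 0.0, 1.0
    if eig(hi) <= 1.0:
        return 1.0, eig
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if eig(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), eig


def persistence_threshold(
    mode: Literal["blocked", "uniform"],
    eps: float = 0.01,
    grid_tol: float = 1e-3,
    tol: float = 1e-12,
    max_gen: int = 200_000,
) -> float:
    """Smallest alpha (to ``grid_tol``) at which the distorter persists at
    equilibrium when introduced at frequency ``eps``, found by bisection on
    the lost/persists boundary.  Complements the linear invasion threshold
    for detecting possible bistability."""
    start = perturbed_start(eps)

    def lost(a: float) -> bool:
        rates = TransmissionRates.from_alpha(a, mode)
        return iterate_to_equilibrium(start, rates, tol=tol, max_gen=max_gen).distorter_lost

    lo, hi = 0.0, 1.0
    if lost(hi):
        return math.inf
    while hi - lo > grid_tol:
        mid = 0.5 * (lo + hi)
        if lost(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
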