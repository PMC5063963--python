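"""Deterministic steady-state model of GAL-network activity.

The GAL network is reduced to an activator/repressor pair at steady state:
galactose-activated inducers (Gal3, and Gal1 at ~40-fold lower potency)
sequester the repressor Gal80 with 1-to-1 stoichiometry, and network
activity is a decreasing Hill function of the *free* Gal80 concentration.
All regulated genes share Gal4-binding promoters, so their synthesis rates
are proportional to the common activity ``A``; the fixed points of the
resulting one-dimensional self-consistency map are the network's steady
states (the map is bistable over a window of galactose concentrations).

A global dosage multiplier ``lambda_dosage`` scales every synthesis rate in
the network, modelling network-copy-number changes or global extrinsic
perturbations (ribosomes, polymerase, volume).  In the natural topology the
ON-branch activity depends on repressor and inducer totals only through the
ratio ``I/(X - I)`` in the strong-binding, inducer-excess regime, so the
multiplier cancels: the network is dosage compensated.  Rewiring Gal80
production through an rtTA-driven TET promoter (the synthetic topology)
makes repressor output a nonlinear function of the dosage-scaled rtTA
level, the cancellation fails, and invariance is abolished — unless the
TET response is independent of rtTA, which restores compensation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "SteadyStateParams",
    "Topology",
    "ActivitySolution",
    "free_inhibitor",
    "activity_map",
    "solve_steady_states",
    "invariance_deviation",
]


class Topology(Enum):
    """Which gene's synthesis law produces the Gal80 repressor.

    ``NATURAL``: Gal80 is expressed from its own Gal4-regulated promoter.
    ``SYNTHETIC``: Gal80 is expressed from a TET promoter driven by rtTA,
    with rtTA expressed from the Gal80 promoter (the negative-feedback path
    from activity to repressor production is preserved, but now passes
    through the doxycycline-dependent rtTA/P_TET link).
    """

    NATURAL = "natural"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class SteadyStateParams:
    """Parameters of the deterministic activity model.

    Rates are in arbitrary concentration per minute; ``delta`` is the
    shared first-order dilution/degradation rate (per minute), so totals
    like ``a3/delta`` are steady-state concentrations.  Defaults give a
    bistable dose response over the experimental galactose range
    (0–0.5% w/v) and a strongly sequestered ON branch.
    """

    lambda_dosage: float = 1.0
    # maximal synthesis rates (Gal3, Gal80, Gal4, Gal1, Gal2)
    a3: float = 3.0
    a80: float = 0.5
    a4: float = 0.4
    a1: float = 3.0
    a2: float = 0.8
    # basal expression fractions of the Gal4-regulated genes; Gal80's basal
    # exceeds the inducers' so the uninduced state has repressor in excess
    b3: float = 0.05
    b80: float = 0.5
    b1: float = 0.05
    b2: float = 0.05
    # galactose input
    s_gal: float = 0.0
    K_s: float = 0.08
    m: float = 1.5
    # Gal1 is a ~40-fold weaker inducer than Gal3
    w1: float = 1.0 / 40.0
    # 1-to-1 inducer*–Gal80 sequestration
    Kd_seq: float = 0.1
    # free-Gal80 -> activity repression Hill
    K_act: float = 1.0
    p: float = 2.0
    # synthetic rtTA / P_TET link (two rtTA operators -> Hill coefficient 2)
    a_r: float = 0.5
    dox: float = 1.0
    t_basal: float = 0.02
    t_max: float = 0.6
    K_T: float = 50.0
    q: float = 2.0
    # shared dilution/degradation
    delta: float = 0.007

    def __post_init__(self) -> None:
        positive = {
            "a3": self.a3, "a80": self.a80, "a4": self.a4, "a1": self.a1,
            "a2": self.a2, "K_s": self.K_s, "m": self.m, "Kd_seq": self.Kd_seq,
            "K_act": self.K_act, "p": self.p, "a_r": self.a_r, "K_T": self.K_T,
            "q": self.q, "delta": self.delta, "lambda_dosage": self.lambda_dosage,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ValueError(f"{name} must be strictly positive, got {val!r}")
        for name, val in (("b3", self.b3), ("b80", self.b80),
                          ("b1", self.b1), ("b2", self.b2)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val!r}")
        if self.s_gal < 0 or self.dox < 0:
            raise ValueError("s_gal and dox must be nonnegative")
        if self.t_basal < 0 or self.t_max < 0:
            raise ValueError("TET outputs must be nonnegative")
        if not self.w1 <= 1.0:
            raise ValueError("w1 must not exceed 1 (Gal1 is the weaker inducer)")
        if self.w1 < 0:
            raise ValueError("w1 must be nonnegative")


def free_inhibitor(I_total: float, X_total: float, Kd: float) -> float:
    """Free repressor concentration under 1-to-1 sequestration.

    Solves the mass-action equilibrium ``I_f * X_f = Kd * C`` with
    ``I_f + C = I_total`` and ``X_f + C = X_total``.  The complex is the
    smaller root of the quadratic, evaluated in the cancellation-safe form
    ``C = 2 I X / (b + sqrt(b^2 - 4 I X))`` with ``b = I + X + Kd``.

    Parameters are concentrations (same arbitrary units); ``Kd > 0``.
    Returns ``I_total - C``, guaranteed in ``[0, I_total]``.
    """
    if I_total < 0 or X_total < 0:
        raise ValueError("totals must be nonnegative")
    if not Kd > 0:
        raise ValueError("Kd must be strictly positive")
    if I_total == 0.0:
        return 0.0
    b = I_total + X_total + Kd
    disc = b * b - 4.0 * I_total * X_total
    # disc >= Kd^2 > 0 analytically; guard against rounding
    root = math.sqrt(max(disc, 0.0))
    C = 2.0 * I_total * X_total / (b + root)
    C = min(C, I_total, X_total)
    return I_total - C


def _hill(x: float, K: float, n: float) -> float:
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (xn + K ** n)


def _totals(A: float, params: SteadyStateParams, topology: Topology):
    """Steady-state inducer* and Gal80 totals implied by activity ``A``."""
    p = params
    lam = p.lambda_dosage
    h = _hill(p.s_gal, p.K_s, p.m)
    X = lam * (p.a3 * (p.b3 + (1.0 - p.b3) * A)
               + p.w1 * p.a1 * (p.b1 + (1.0 - p.b1) * A)) * h / p.delta
    if topology is Topology.NATURAL:
        I = lam * p.a80 * (p.b80 + (1.0 - p.b80) * A) / p.delta
    else:
        r = lam * p.a_r * (p.b80 + (1.0 - p.b80) * A) / p.delta
        T = p.t_basal + (p.t_max - p.t_basal) * _hill(r * p.dox, p.K_T, p.q)
        I = lam * T / p.delta
    return X, I


def activity_map(A: float, params: SteadyStateParams,
                 topology: Topology = Topology.NATURAL) -> float:
    """Self-consistency map: activity implied by assuming activity ``A``.

    Assuming every Gal4-regulated promoter operates at activity ``A``, the
    steady-state totals of active inducer (``X``, galactose-gated via
    ``h(s) = s^m/(s^m + K_s^m)``) and of Gal80 (``I``) follow from
    synthesis/dilution balance; the free repressor after 1-to-1
    sequestration then sets the returned activity
    ``1 / (1 + (I_f/K_act)^p)``.  Fixed points of this map are the
    network's steady states.
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"activity must be in [0, 1], got {A!r}")
    X, I = _totals(A, params, topology)
    I_f = free_inhibitor(I, X, params.Kd_seq)
    return 1.0 / (1.0 + (I_f / params.K_act) ** params.p)


@dataclass(frozen=True)
class ActivitySolution:
    """Fixed points of the activity map, classified by local stability."""

    stable_activities: tuple[float, ...]
    unstable_activities: tuple[float, ...]

    @property
    def bistable(self) -> bool:
        return len(self.stable_activities) >= 2

    @property
    def on_activity(self) -> float:
        """Largest stable fixed point (the ON branch when bistable)."""
        return max(self.stable_activities)

    @property
    def off_activity(self) -> float:
        return min(self.stable_activities)


def solve_steady_states(params: SteadyStateParams,
                        topology: Topology = Topology.NATURAL,
                        n_grid: int = 10_001,
                        tol: float = 1e-10) -> ActivitySolution:
    """All fixed points of :func:`activity_map` on [0, 1].

    Sign changes of ``g(A) = activity_map(A) - A`` are located on a dense
    grid (default 10,001 points) and refined by bisection to ``|dA| < tol``.
    Stability is classified from the finite-difference slope of the map at
    the fixed point (slope < 1 stable, > 1 unstable).  The map is a
    continuous self-map of [0, 1], so at least one fixed point exists.
    """

    def g(A: float) -> float:
        return activity_map(A, params, topology) - A

    grid = np.linspace(0.0, 1.0, n_grid)
    gv = np.array([g(a) for a in grid])

    roots: list[float] = []
    # exact zeros on grid points
    for a, val in zip(grid, gv):
        if val == 0.0:
            roots.append(float(a))
    for i in range(n_grid - 1):
        lo, hi = grid[i], grid[i + 1]
        flo, fhi = gv[i], gv[i + 1]
        if flo == 0.0 or fhi == 0.0:
            continue
        if flo * fhi < 0.0:
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                fm = g(mid)
                if fm == 0.0:
                    lo = hi = mid
                    break
                if flo * fm < 0.0:
                    hi, fhi = mid, fm
                else:
                    lo, flo = mid, fm
            roots.append(0.5 * (lo + hi))

    # deduplicate near-coincident roots
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 10 * tol:
            merged.append(r)

    stable: list[float] = []
    unstable: list[float] = []
    eps = 1e-7
    for r in merged:
        lo = max(0.0, r - eps)
        hi = min(1.0, r + eps)
        slope = (activity_map(hi, params, topology)
                 - activity_map(lo, params, topology)) / (hi - lo)
        (stable if slope < 1.0 else unstable).append(r)
    return ActivitySolution(tuple(stable), tuple(unstable))


def invariance_deviation(params: SteadyStateParams,
                         topology: Topology,
                         lambda_values: Sequence[float],
                         s_values: Sequence[float]) -> np.ndarray:
    """ON-branch activity deviation under global synthesis-rate scaling.

    For each dosage multiplier ``lam`` and galactose level ``s``, returns
    ``|A_on(lam, s) - A_on(1, s)|`` where ``A_on`` is the largest stable
    fixed point.  A dosage-compensated topology yields a matrix of zeros
    (to numerical tolerance) in the strong-binding, inducer-excess regime.

    Shape: ``(len(lambda_values), len(s_values))``.
    """
    lambda_values = list(lambda_values)
    if any(l <= 0 for l in lambda_values):
        raise ValueError("lambda values must be strictly positive")
    ref = []
    for s in s_values:
        p1 = replace(params, lambda_dosage=1.0, s_gal=float(s))
        ref.append(solve_steady_states(p1, topology).on_activity)
    out = np.empty((len(lambda_values), len(ref)))
    for i, lam in enumerate(lambda_values):
        for j, s in enumerate(s_values):
            pl = replace(params, lambda_dosage=float(lam), s_gal=float(s))
            a_on = solve_steady_states(pl, topology).on_activity
            out[i, j] = abs(a_on - ref[j])
    return out
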