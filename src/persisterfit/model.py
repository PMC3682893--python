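"""Closed-form two-state kill-curve model.

During antibiotic treatment a population is modelled as a mixture of two
phenotypes: *normal* cells, which die at rate ``m`` (per hour) and switch into
a protected *persister* state at rate ``a``, and persister cells, which neither
die nor grow and switch back to the normal state at rate ``b``::

    n'(t) = -(m + a) n(t) + b p(t)
    p'(t) =        a n(t) - b p(t)

The total viable count ``N(t) = n(t) + p(t)`` is a biexponential,

    N(t) = c1 exp(lam1 t) + c2 exp(lam2 t),        lam1 < lam2 <= 0,

which is what a biphasic time-kill curve looks like on a log scale: a fast
initial kill of the normal subpopulation followed by a slowly decaying
persister tail.  Only the four observational parameters (c1, c2, lam1, lam2)
are identifiable from CFU data; the five mechanistic quantities (m, a, b, and
the initial condition N0, fp) are constrained to a one-parameter family.  This
module provides the trajectory evaluation, the maps between the two
parameterizations, and the identifiability interval of the persister fraction
``fp`` (the fraction of cells in the persister state at drug addition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MechanisticParams",
    "InitialState",
    "ObservationalParams",
    "FractionInterval",
    "DegenerateModelError",
    "InfeasibleParametersError",
    "eigenvalues",
    "mech_to_obs",
    "total_cfu",
    "state_trajectory",
    "feasible_fp_interval",
    "obs_to_mech",
]

#: relative discriminant below which the two eigenvalues are treated as equal
_DEGENERATE_REL_DISC = 1e-12


class DegenerateModelError(ValueError):
    """Raised when the two decay eigenvalues coincide (repeated root)."""


class InfeasibleParametersError(ValueError):
    """Raised when no nonnegative mechanistic parameters reproduce the input."""


@dataclass(frozen=True)
class MechanisticParams:
    """Biological rates of the two-state model, all per hour.

    m : death rate of normal cells (>= 0; > 0 under any antibiotic)
    a : switching rate normal -> persister (>= 0)
    b : switching rate persister -> normal (>= 0)
    """

    m: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("m", "a", "b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class InitialState:
    """Population state at the moment of drug addition.

    N0 : total viable cells (CFU/ml, > 0)
    fp : persister fraction p0 / (n0 + p0), in [0, 1]
    """

    N0: float
    fp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.N0) or self.N0 <= 0:
            raise ValueError(f"N0 must be finite and > 0, got {self.N0}")
        if not 0.0 <= self.fp <= 1.0:
            raise ValueError(f"fp must lie in [0, 1], got {self.fp}")

    @property
    def n0(self) -> float:
        return (1.0 - self.fp) * self.N0

    @property
    def p0(self) -> float:
        return self.fp * self.N0


@dataclass(frozen=True)
class ObservationalParams:
    """Identifiable biexponential parameters of a kill curve.

    c1, c2 : fast/slow phase amplitudes (CFU/ml); c2 >= 0 and c1 + c2 > 0.
        c1 may be negative: when back-switching is fast relative to killing
        the slow amplitude exceeds N0, yet N(t) remains positive and
        nonincreasing (the total initial decay rate D = -N'(0)/N0 stays
        >= 0).  The *fitted* parameter space restricts to c1 > 0, matching
        the visibly biphasic curves the likelihood is applied to.
    lam1, lam2 : decay eigenvalues (per hour), lam1 < lam2 <= 0
    """

    c1: float
    c2: float
    lam1: float
    lam2: float

    def __post_init__(self) -> None:
        if self.c2 < 0 or self.c1 + self.c2 <= 0:
            raise ValueError(
                f"require c2 >= 0 and c1 + c2 > 0, got c1={self.c1}, c2={self.c2}"
            )
        if not (self.lam1 < self.lam2 <= 0.0):
            raise ValueError(
                f"eigenvalues must satisfy lam1 < lam2 <= 0, got ({self.lam1}, {self.lam2})"
            )
        if self.c1 * self.lam1 + self.c2 * self.lam2 > 0:
            raise ValueError("N(t) must be nonincreasing at t = 0 (needs N'(0) <= 0)")

    @property
    def N0(self) -> float:
        """Total viable count at t = 0."""
        return self.c1 + self.c2

    @property
    def slow_fraction(self) -> float:
        """Model-free persister-fraction proxy c2 / (c1 + c2)."""
        return self.c2 / (self.c1 + self.c2)


@dataclass(frozen=True)
class FractionInterval:
    """Feasible persister-fraction interval with its midpoint point estimate."""

    fp_min: float
    fp_mid: float
    fp_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_min <= self.fp_mid <= self.fp_max < 1.0):
            raise ValueError(
                f"require 0 <= fp_min <= fp_mid <= fp_max < 1, got "
                f"({self.fp_min}, {self.fp_mid}, {self.fp_max})"
            )

    @property
    def width(self) -> float:
        return self.fp_max - self.fp_min

    def contains(self, fp: float, atol: float = 1e-12) -> bool:
        return self.fp_min - atol <= fp <= self.fp_max + atol


def eigenvalues(mech: MechanisticParams) -> tuple[float, float]:
    """Decay eigenvalues (lam1, lam2), lam1 <= lam2 <= 0.

    Roots of ``lam^2 + (m + a + b) lam + m b = 0``.  The discriminant
    ``(m + a + b)^2 - 4 m b`` equals ``(lam1 - lam2)^2`` and is nonnegative
    for all nonnegative rates.
    """
    s = mech.m + mech.a + mech.b
    prod = mech.m * mech.b
    if prod == 0.0:  # one eigenvalue is exactly 0 (no death or inert persisters)
        return (-s, 0.0)
    disc = s * s - 4.0 * prod
    r = math.sqrt(max(disc, 0.0))
    lam1 = -(s + r) / 2.0
    # product form avoids cancellation in the slow eigenvalue
    return (lam1, prod / lam1)


def _check_nondegenerate(mech: MechanisticParams) -> tuple[float, float]:
    lam1, lam2 = eigenvalues(mech)
    s = mech.m + mech.a + mech.b
    if s == 0.0:
        raise DegenerateModelError("all rates zero: repeated eigenvalue at 0")
    if (lam1 - lam2) ** 2 < _DEGENERATE_REL_DISC * s * s:
        raise DegenerateModelError(
            f"repeated eigenvalue (lam1={lam1}, lam2={lam2}); the biexponential "
            "parameterization is undefined on this measure-zero boundary"
        )
    return lam1, lam2


def mech_to_obs(mech: MechanisticParams, init: InitialState) -> ObservationalParams:
    """Map mechanistic rates + initial condition to biexponential parameters.

    Uses N(0) = N0 and N'(0) = -m (1 - fp) N0 (only normal cells die):
    c2 = (N'(0) - lam1 N0) / (lam2 - lam1), c1 = N0 - c2.
    """
    lam1, lam2 = _check_nondegenerate(mech)
    N0 = init.N0
    dN0 = -mech.m * (1.0 - init.fp) * N0
    c2 = (dN0 - lam1 * N0) / (lam2 - lam1)
    c1 = N0 - c2
    # clamp FP dust at the b=0 boundary (c2 >= 0 holds exactly in real arithmetic)
    if c2 < 0 and c2 > -1e-12 * N0:
        c2 = 0.0
    return ObservationalParams(c1=c1, c2=c2, lam1=lam1, lam2=lam2)


def total_cfu(obs: ObservationalParams, t) -> np.ndarray | float:
    """Total viable count N(t) = c1 exp(lam1 t) + c2 exp(lam2 t), t >= 0 (h)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = obs.c1 * np.exp(obs.lam1 * t_arr) + obs.c2 * np.exp(obs.lam2 * t_arr)
    return out if t_arr.ndim else float(out)


def state_trajectory(
    mech: MechanisticParams, init: InitialState, t
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (n(t), p(t)) of the linear two-state system.

    Evaluated via the Lagrange form of the matrix exponential,
    ``exp(A t) = e^{lam1 t}(A - lam2 I)/(lam1 - lam2) + e^{lam2 t}(A - lam1 I)/(lam2 - lam1)``,
    which is valid for every nonnegative rate combination including a = 0 or
    b = 0; the repeated-eigenvalue boundary uses the limiting form
    ``e^{lam t}(I + t (A - lam I))``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    A = np.array(
        [[-(mech.m + mech.a), mech.b], [mech.a, -mech.b]], dtype=float
    )
    v0 = np.array([init.n0, init.p0])
    lam1, lam2 = eigenvalues(mech)
    s = mech.m + mech.a + mech.b
    eye = np.eye(2)
    if s == 0.0 or (lam1 - lam2) ** 2 < _DEGENERATE_REL_DISC * max(s * s, 1e-300):
        lam = 0.5 * (lam1 + lam2)
        w0 = v0
        w1 = (A - lam * eye) @ v0
        traj = np.exp(lam * t_arr)[:, None] * (w0[None, :] + t_arr[:, None] * w1[None, :])
    else:
        u1 = ((A - lam2 * eye) @ v0) / (lam1 - lam2)
        u2 = ((A - lam1 * eye) @ v0) / (lam2 - lam1)
        traj = (
            np.exp(lam1 * t_arr)[:, None] * u1[None, :]
            + np.exp(lam2 * t_arr)[:, None] * u2[None, :]
        )
    n = np.clip(traj[:, 0], 0.0, None)
    p = np.clip(traj[:, 1], 0.0, None)
    if np.ndim(t) == 0:
        return float(n[0]), float(p[0])
    return n, p


def _initial_decay_rate(obs: ObservationalParams) -> float:
    """D = -N'(0)/N(0) = -(c1 lam1 + c2 lam2)/(c1 + c2) >= 0."""
    return -(obs.c1 * obs.lam1 + obs.c2 * obs.lam2) / (obs.c1 + obs.c2)


def feasible_fp_interval(obs: ObservationalParams) -> FractionInterval:
    """Identifiability interval of the persister fraction.

    A biexponential constrains five mechanistic quantities (m, a, b, N0, fp)
    through four observables, leaving fp free on an interval.  Writing
    u = 1 - fp and D = -N'(0)/N(0), the inverse map gives m = D/u and
    b = lam1 lam2 / m, so m, b >= 0 automatically; nonnegativity of
    a = -(lam1 + lam2) - m - b reduces to

        (lam1 lam2 / D) u^2 + (lam1 + lam2) u + D <= 0,

    an upward parabola in u with roots u = D/|lam1| and u = D/|lam2|.
    Intersected with u <= 1, the feasible set is
    u in [D/|lam1|, min(1, D/|lam2|)].  For a fitted curve (c1, c2 >= 0) D
    is a convex combination of |lam1| and |lam2|, so the set is nonempty
    with upper u-endpoint 1: fp_min = 0 and fp_max = 1 - D/|lam1|.  (The
    equivalent normal-fraction interval [D/|lam1|, 1] is what near-one
    published F0 ranges correspond to.)  In the negative-c1 regime D falls
    below |lam2| and fp_min becomes positive.
    """
    D = _initial_decay_rate(obs)
    if not np.isfinite(D) or D <= 0:
        raise InfeasibleParametersError(
            f"initial decay rate D = {D} is not positive; no valid kill-curve "
            "mechanism reproduces these observational parameters"
        )
    u_lo = D / (-obs.lam1)
    u_hi = 1.0 if obs.lam2 == 0.0 else min(1.0, D / (-obs.lam2))
    if u_lo > u_hi * (1.0 + 1e-12):
        raise InfeasibleParametersError(
            f"empty feasible set: u in [{u_lo}, {u_hi}] from D={D}, "
            f"lam1={obs.lam1}, lam2={obs.lam2}"
        )
    u_lo = min(u_lo, u_hi)
    fp_min = max(0.0, 1.0 - u_hi)
    fp_max = max(fp_min, 1.0 - u_lo)
    return FractionInterval(fp_min=fp_min, fp_mid=0.5 * (fp_min + fp_max), fp_max=fp_max)


def obs_to_mech(obs: ObservationalParams, fp: float) -> MechanisticParams:
    """Mechanistic rates consistent with ``obs`` at a given persister fraction.

    With u = 1 - fp and D = -N'(0)/N(0):  m = D/u (matching the initial kill
    rate of the normal subpopulation), b = lam1 lam2 / m (from the
    characteristic-polynomial product), and a = -(lam1 + lam2) - m - b (from
    its sum).  Raises if ``fp`` lies outside the identifiability interval.
    """
    interval = feasible_fp_interval(obs)
    if not interval.contains(fp):
        raise InfeasibleParametersError(
            f"fp={fp} outside the feasible interval "
            f"[{interval.fp_min}, {interval.fp_max}]"
        )
    fp = min(max(fp, interval.fp_min), interval.fp_max)
    D = _initial_decay_rate(obs)
    u = 1.0 - fp
    m = D / u
    b = (obs.lam1 * obs.lam2) / m
    a = -(obs.lam1 + obs.lam2) - m - b
    # a is >= 0 on the feasible interval up to rounding at its endpoints
    scale = abs(obs.lam1) + abs(obs.lam2)
    if a < 0:
        if a > -1e-9 * scale:
            a = 0.0
        else:  # pragma: no cover - guarded by the interval check
            raise InfeasibleParametersError(f"derived a = {a} < 0 at fp = {fp}")
    if b < 0 and b > -1e-15 * scale:
        b = 0.0
    return MechanisticParams(m=m, a=a, b=b)
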