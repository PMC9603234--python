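"""Steady-state solution of the cross-bridge master equation and FV curves.

For a huge ensemble sliding at constant shortening velocity v, the state
probabilities p_j(x) at head-site offset x obey

    v dp/dx = Q(x)^T p      (shortening advects heads toward decreasing x)

over one 36-nm actin target-zone repeat with periodic boundary conditions
(a head leaving the window at the low-x end reappears, in the same
biochemical state, 36 nm up at the next site).  At v = 0 each offset is an
independent continuous-time Markov chain and p(x) is the stationary vector
of the local generator.

The sliding solver steps the probability vector across the period with
interval-wise matrix exponentials of the generator evaluated at interval
midpoints (second-order accurate, unconditionally stable and positivity
preserving even where the capped rates make the problem extremely stiff).
The periodic steady state is the eigenvector of the resulting one-period
propagator at eigenvalue one, so no shooting iteration is needed.

Ensemble observables (mean force per available head, ATP turnover per
head) are integrals of p_j(x) over the repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space
from scipy.optimize import brentq

from .parameters import ModelParameters, SITE_SPACING_NM
from .rates import rate_detach, rate_matrix, state_minimum_position, clamp_rate
from .states import ATTACHED_STATES, State

__all__ = [
    "StateDistribution",
    "FVPoint",
    "FVCurve",
    "SolverError",
    "solve_isometric",
    "solve_sliding",
    "mean_force",
    "atpase_rate",
    "fv_curve",
    "find_v0",
    "default_velocities",
]

#: Offset window relative to the rigor minimum x3: one full 36-nm repeat.
WINDOW_LO_NM = -22.0
WINDOW_HI_NM = 14.0

#: Force-integral window (relative to x3) for the numerator of the mean
#: force; attached probability outside it is negligible by construction.
FORCE_WINDOW_LO_NM = -9.0


class SolverError(RuntimeError):
    """Numerical degeneracy or non-convergence in a steady-state solve."""


@dataclass(frozen=True)
class StateDistribution:
    """Per-offset conditional state probabilities over one 36-nm repeat."""

    x: np.ndarray          # offsets, nm; spans [x3 - 22, x3 + 14]
    p: np.ndarray          # shape (len(x), 7); p[:, j-1] is state j
    velocity: float        # nm/s the distribution was solved for (0 = isometric)

    def __post_init__(self) -> None:
        if self.p.shape != (len(self.x), 7):
            raise ValueError("probability array must be (n_grid, 7)")
        sums = self.p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("state probabilities must sum to 1 at every offset")
        if self.x[-1] - self.x[0] != 0 and not math.isclose(
            self.x[-1] - self.x[0], SITE_SPACING_NM, rel_tol=1e-9
        ):
            raise ValueError("offset grid must span exactly one 36-nm period")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"p{j}": self.p[:, j - 1] for j in range(1, 8)}
        return pd.DataFrame({"x_nm": self.x, **cols})


@dataclass(frozen=True)
class FVPoint:
    velocity: float                      # nm/s
    force: float                         # pN per available head
    atpase: Optional[float] = None       # ATP turnovers per head per s
    ci_halfwidth: Optional[float] = None  # 95% CI half-width, pN (MC points)


@dataclass(frozen=True)
class FVCurve:
    """Force-velocity curve, sorted by velocity, with provenance metadata."""

    points: tuple[FVPoint, ...]
    parameter_set: str = ""
    backend: str = "ode"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "points", tuple(sorted(self.points, key=lambda q: q.velocity))
        )
        if any(q.velocity < 0 for q in self.points):
            raise ValueError("velocities must be non-negative")

    @property
    def velocities(self) -> np.ndarray:
        return np.array([q.velocity for q in self.points])

    @property
    def forces(self) -> np.ndarray:
        return np.array([q.force for q in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "velocity_nm_s": self.velocities,
                "force_pN_per_head": self.forces,
                "atpase_per_head_s": [q.atpase for q in self.points],
                "ci_halfwidth_pN": [q.ci_halfwidth for q in self.points],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **meta) -> "FVCurve":
        pts = [
            FVPoint(
                float(r["velocity_nm_s"]),
                float(r["force_pN_per_head"]),
                None if pd.isna(r.get("atpase_per_head_s")) else float(r["atpase_per_head_s"]),
                None if pd.isna(r.get("ci_halfwidth_pN")) else float(r["ci_halfwidth_pN"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(tuple(pts), **meta)


# ---------------------------------------------------------------------------
# grids and solvers
# ---------------------------------------------------------------------------

def _grid(p: ModelParameters, grid_step: float) -> np.ndarray:
    if not 0 < grid_step <= 1.0:
        raise ValueError("grid_step must be in (0, 1] nm")
    n = int(round(SITE_SPACING_NM / grid_step))
    return p.x3 + np.linspace(WINDOW_LO_NM, WINDOW_HI_NM, n + 1)


def solve_isometric(p: ModelParameters, grid_step: float = 0.1) -> StateDistribution:
    """Stationary state probabilities at every offset for v = 0.

    Each offset is solved independently as the null space of the local
    generator (isometric rate caps).
    """
    xs = _grid(p, grid_step)
    P = np.empty((len(xs), 7))
    for i, x in enumerate(xs):
        Q = rate_matrix(x, p, mode="iso")
        ns = null_space(Q.T, rcond=1e-12)
        if ns.shape[1] != 1:
            raise SolverError(
                f"generator at x = {x:.3f} nm has a {ns.shape[1]}-dimensional "
                "null space; cannot identify a unique stationary distribution"
            )
        v = np.abs(ns[:, 0])
        P[i] = v / v.sum()
    return StateDistribution(xs, P, velocity=0.0)


def _period_propagators(p: ModelParameters, v: float,
                        xs: np.ndarray) -> list[np.ndarray]:
    """Interval propagators M_i with p(x_{i+1}) = M_i p(x_i), stepping down.

    The grid ``xs`` is ascending; stepping proceeds from the top of the
    window toward decreasing x, the direction in which shortening carries
    the heads.
    """
    h = xs[1] - xs[0]
    mats = []
    for i in range(len(xs) - 1, 0, -1):
        x_mid = 0.5 * (xs[i] + xs[i - 1])
        Q = rate_matrix(x_mid, p, mode="shortening")
        mats.append(expm(Q.T * (h / v)))
    return mats


def solve_sliding(p: ModelParameters, v: float,
                  grid_step: float = 0.1) -> StateDistribution:
    """Periodic steady-state distribution at shortening velocity v > 0.

    The one-period propagator (product of the interval propagators) is a
    column-stochastic matrix; the periodic solution is its eigenvector at
    eigenvalue 1, transported back across the period to fill the grid.
    """
    if v <= 0:
        raise ValueError("v must be > 0; use solve_isometric for v = 0")
    xs = _grid(p, grid_step)
    mats = _period_propagators(p, v, xs)
    M = np.eye(7)
    for m in mats:
        M = m @ M
    w, vecs = np.linalg.eig(M)
    k = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[k] - 1.0) > 1e-8:
        raise SolverError(
            f"one-period propagator has no eigenvalue 1 (closest: {w[k]:.6g})"
        )
    q = np.real(vecs[:, k])
    q = np.abs(q)
    q /= q.sum()
    # sweep down from the top of the window, recording each grid point
    P = np.empty((len(xs), 7))
    P[-1] = q
    for step, m in enumerate(mats):
        q = m @ q
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        P[len(xs) - 2 - step] = q
    return StateDistribution(xs, P, velocity=float(v))


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def mean_force(d: StateDistribution, p: ModelParameters,
               window: str = "standard") -> float:
    """Mean elastic force per available head, pN.

    The numerator integrates k_s p_j(x) (x - x_j) for the attached states;
    the denominator is the full 36-nm period of the uniform offset
    distribution.  With the ``"standard"`` window the numerator runs over
    [x3 - 9, x3 + 14], the published averaging convention; ``"full"``
    integrates the whole period, which matters only during rapid sliding
    when attached heads are dragged below x3 - 9 (and is the definition
    the stochastic backend's total force corresponds to).
    """
    if window == "standard":
        lo = FORCE_WINDOW_LO_NM
    elif window == "full":
        lo = WINDOW_LO_NM
    else:
        raise ValueError(f"unknown force window {window!r}")
    mask = d.x >= p.x3 + lo - 1e-12
    xs = d.x[mask]
    total = 0.0
    for s in ATTACHED_STATES:
        xj = state_minimum_position(s, p)
        integrand = p.k_s * d.p[mask, s.value - 1] * (xs - xj)
        total += np.trapezoid(integrand, xs)
    return total / SITE_SPACING_NM


def atpase_rate(d: StateDistribution, p: ModelParameters) -> float:
    """ATP turnover per available head per second (flux through detachment)."""
    mode = "iso" if d.velocity == 0 else "shortening"
    koff = clamp_rate(rate_detach(d.x, p), mode, p)
    flux = koff * d.p[:, State.AM_AMD.value - 1]
    return float(np.trapezoid(flux, d.x) / SITE_SPACING_NM)


def default_velocities(v_max: float = 20000.0, n: int = 25) -> list[float]:
    """Default FV velocity grid: 0 plus n log-spaced points up to v_max."""
    return [0.0] + list(np.geomspace(v_max / 300.0, v_max, n))


def fv_curve(p: ModelParameters, velocities: Sequence[float],
             grid_step: float = 0.1, parameter_set: str = "",
             with_atpase: bool = True) -> FVCurve:
    """Steady-state FV curve, one point per requested velocity."""
    vs = list(velocities)
    if len(set(vs)) != len(vs):
        raise ValueError("velocities must be distinct")
    pts = []
    for v in vs:
        try:
            d = solve_isometric(p, grid_step) if v == 0 else solve_sliding(p, v, grid_step)
        except Exception as exc:
            raise SolverError(f"FV point at v = {v} nm/s failed: {exc}") from exc
        pts.append(
            FVPoint(
                velocity=float(v),
                force=mean_force(d, p),
                atpase=atpase_rate(d, p) if with_atpase else None,
            )
        )
    return FVCurve(tuple(pts), parameter_set=parameter_set, backend="ode")


def _bracketed_force_root(f, f_at_zero: float, tol: float,
                          v_hi: float) -> float:
    """Root of a decreasing force-velocity function by bracket expansion.

    ``f_at_zero`` must be positive; the upper bracket edge is doubled until
    the force turns negative.
    """
    if f_at_zero <= 0:
        raise SolverError(f"isometric force {f_at_zero:.4g} pN is not positive")
    lo = 0.0
    hi = v_hi
    for _ in range(12):
        f_hi = f(hi)
        if f_hi < 0:
            break
        lo = hi
        hi *= 2.0
    else:
        raise SolverError(f"no zero crossing of mean force below v = {hi} nm/s")
    if lo == 0.0:
        lo = 1e-3 * hi
        if f(lo) < 0:
            raise SolverError("mean force negative at the lower bracket edge")
    return float(brentq(f, lo, hi, xtol=tol))


def find_v0(p: ModelParameters, tol: float = 1.0, grid_step: float = 0.1,
            v_hi: float = 4000.0, window: str = "standard") -> float:
    """Unloaded shortening velocity: root of mean_force(v) = 0 by bracketing.

    Raises
    ------
    SolverError
        If the isometric force is not positive or no sign change is found
        below an upper search limit.
    """
    f0 = mean_force(solve_isometric(p, grid_step), p, window)

    def f(v: float) -> float:
        return mean_force(solve_sliding(p, v, grid_step), p, window)

    return _bracketed_force_root(f, f0, tol, v_hi)
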