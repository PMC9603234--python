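"""Hill (1938) hyperbola fitting of force-velocity data.

The rectangular hyperbola ``(F + a)(V + b) = b (F0* + a)`` is fitted to
(force, velocity) points by non-linear least squares with residuals in
velocity (velocity expressed as a function of force), since that is how FV
points are usually generated: force is the controlled or better-determined
coordinate.  Derived quantities: the extrapolated unloaded velocity
``V0 = b F0* / a``, the curvature ratio ``a/F0*`` (smaller = more curved)
and the deviation ratio ``F0*/F0_measured`` quantifying how far the
measured isometric point sits above the fitted hyperbola.

``HillModel`` holds the data and windowing; ``fit()`` returns a
``HillFitResult`` with estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .steady_state import FVCurve

__all__ = ["HillModel", "HillFitResult", "HillFitError", "fit_hill", "power_curve"]

#: Curvature ratio beyond which a fit is declared degenerate (non-hyperbolic
#: data, e.g. very small ensembles).
DEGENERACY_CURVATURE = 5.0


class HillFitError(RuntimeError):
    """Non-convergence or invalid input in a Hill-equation fit."""


@dataclass(frozen=True)
class HillFitResult:
    """Estimates and diagnostics of a Hill-hyperbola fit."""

    a: float                 # pN
    b: float                 # nm/s
    F0_star: float           # pN, fitted isometric intercept
    rss: float               # residual sum of squares, (nm/s)^2
    n_points: int
    window: str
    F0_measured: Optional[float] = None
    jacobian_rank: int = 3
    converged: bool = True

    # -- derived -------------------------------------------------------
    @property
    def V0_hill(self) -> float:
        """Extrapolated unloaded velocity b F0*/a, nm/s."""
        return self.b * self.F0_star / self.a

    @property
    def curvature_ratio(self) -> float:
        """a/F0*: smaller means a more curved FV relationship."""
        return self.a / self.F0_star

    @property
    def deviation_ratio(self) -> Optional[float]:
        """F0*/F0_measured, < 1 when the isometric point sits above the
        hyperbola extrapolation; None if no measured F0 was supplied."""
        if self.F0_measured is None:
            return None
        return self.F0_star / self.F0_measured

    @property
    def degenerate(self) -> bool:
        """True for non-hyperbolic data (near-linear FV relationships)."""
        return (self.curvature_ratio > DEGENERACY_CURVATURE
                or self.jacobian_rank < 3 or not self.converged)

    def predict_velocity(self, force) -> np.ndarray:
        """Hill-equation velocity at the given force(s), nm/s."""
        f = np.asarray(force, dtype=float)
        return self.b * (self.F0_star + self.a) / (f + self.a) - self.b

    def predict_force(self, velocity) -> np.ndarray:
        """Hill-equation force at the given velocity(ies), pN."""
        v = np.asarray(velocity, dtype=float)
        return self.b * (self.F0_star + self.a) / (v + self.b) - self.a

    def summary(self) -> str:
        dev = ("-" if self.deviation_ratio is None
               else f"{self.deviation_ratio:10.4f}")
        lines = [
            "Hill hyperbola fit  (F + a)(V + b) = b (F0* + a)",
            "=" * 50,
            f"  points used          {self.n_points:10d}",
            f"  window               {self.window:>10s}",
            f"  a        [pN]        {self.a:10.4f}",
            f"  b        [nm/s]      {self.b:10.2f}",
            f"  F0*      [pN]        {self.F0_star:10.4f}",
            f"  V0=bF0*/a [nm/s]     {self.V0_hill:10.2f}",
            f"  a/F0*    [-]         {self.curvature_ratio:10.4f}",
            f"  F0*/F0   [-]         {dev}",
            f"  RSS      [(nm/s)^2]  {self.rss:10.4g}",
            f"  degenerate           {str(self.degenerate):>10s}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a_pN": self.a,
            "b_nm_s": self.b,
            "F0_star_pN": self.F0_star,
            "V0_hill_nm_s": self.V0_hill,
            "curvature_ratio": self.curvature_ratio,
            "deviation_ratio": self.deviation_ratio,
            "rss": self.rss,
            "n_points": self.n_points,
            "window": self.window,
            "degenerate": self.degenerate,
        }


class HillModel:
    """Hill-hyperbola model of a force-velocity data set.

    Parameters
    ----------
    forces, velocities:
        FV points, pN and nm/s; forces must be non-negative.
    window:
        ``"all"`` uses every point; ``"below_0.8F0"`` keeps forces below
        80% of the measured isometric force; ``"exclude_isometric"`` drops
        the isometric (v = 0) point.
    F0_measured:
        Measured isometric force; defaults to the force at the smallest
        velocity in the data.
    """

    def __init__(self, forces: Sequence[float], velocities: Sequence[float],
                 window: str = "all",
                 F0_measured: Optional[float] = None) -> None:
        f = np.asarray(forces, dtype=float)
        v = np.asarray(velocities, dtype=float)
        if f.shape != v.shape or f.ndim != 1:
            raise ValueError("forces and velocities must be 1-d and equal length")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")
        self.F0_measured = (float(f[np.argmin(v)]) if F0_measured is None
                            else float(F0_measured))
        if window == "all":
            keep = np.ones_like(f, dtype=bool)
        elif window == "below_0.8F0":
            keep = f < 0.8 * self.F0_measured
        elif window == "exclude_isometric":
            keep = v > 0
        else:
            raise ValueError(f"unknown window {window!r}")
        self.window = window
        self.forces = f[keep]
        self.velocities = v[keep]
        if len(self.forces) < 4:
            raise HillFitError(
                f"need at least 4 points after windowing, have {len(self.forces)}"
            )

    @classmethod
    def from_curve(cls, curve: FVCurve, window: str = "all",
                   F0_measured: Optional[float] = None) -> "HillModel":
        return cls(curve.forces, curve.velocities, window=window,
                   F0_measured=F0_measured)

    def fit(self, residuals: str = "velocity") -> HillFitResult:
        """Least-squares fit; positivity enforced by log-parameterization.

        ``residuals`` selects the minimized coordinate, ``"velocity"``
        (default) or ``"force"``.
        """
        f, v = self.forces, self.velocities
        fmax = max(f.max(), 1e-12)
        vmax = max(v.max(), 1e-12)
        theta0 = np.log([0.25 * fmax, 0.25 * vmax, max(self.F0_measured, 0.5 * fmax)])

        def resid(theta: np.ndarray) -> np.ndarray:
            a, b, f0 = np.exp(theta)
            if residuals == "velocity":
                return b * (f0 + a) / (f + a) - b - v
            return b * (f0 + a) / (v + b) - a - f

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14,
                            ftol=1e-14, gtol=1e-14, max_nfev=20000)
        a, b, f0 = np.exp(sol.x)
        rank = int(np.linalg.matrix_rank(sol.jac, tol=1e-8 * max(1.0,
                   float(np.abs(sol.jac).max()))))
        if not sol.success:
            raise HillFitError(f"fit did not converge: {sol.message}")
        return HillFitResult(
            a=float(a), b=float(b), F0_star=float(f0),
            rss=float(2.0 * sol.cost), n_points=len(f), window=self.window,
            F0_measured=self.F0_measured, jacobian_rank=rank,
            converged=bool(sol.success),
        )


def fit_hill(curve: FVCurve | tuple, window: str = "all",
             F0_measured: Optional[float] = None,
             residuals: str = "velocity") -> HillFitResult:
    """Convenience wrapper: fit the Hill hyperbola to an FV curve.

    ``curve`` may be an :class:`FVCurve` or a ``(forces, velocities)`` pair.
    """
    if isinstance(curve, FVCurve):
        model = HillModel.from_curve(curve, window=window, F0_measured=F0_measured)
    else:
        forces, velocities = curve
        model = HillModel(forces, velocities, window=window,
                          F0_measured=F0_measured)
    return model.fit(residuals=residuals)


def power_curve(curve: FVCurve, refine: bool = True
                ) -> tuple[np.ndarray, float, float]:
    """Mechanical power P = F V along an FV curve, pN nm/s per head.

    Returns (per-point power, max power, velocity at max).  With
    ``refine`` a local quadratic through the discrete maximum and its
    neighbours sharpens the peak estimate.
    """
    v = curve.velocities
    f = curve.forces
    if len(v) == 0:
        raise ValueError("empty FV curve")
    power = f * v
    k = int(np.argmax(power))
    p_max, v_max = float(power[k]), float(v[k])
    if refine and 0 < k < len(v) - 1:
        coeffs = np.polyfit(v[k - 1:k + 2], power[k - 1:k + 2], 2)
        if coeffs[0] < 0:
            v_star = -coeffs[1] / (2.0 * coeffs[0])
            if v[k - 1] <= v_star <= v[k + 1]:
                v_max = float(v_star)
                p_max = float(np.polyval(coeffs, v_star))
    return power, p_max, v_max
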