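"""Canned simulation protocols for ensemble force and FV assays.

These functions bundle the run recipes used throughout the package's
validation work so that a result can be regenerated from a parameter set
and a single seed:

* :func:`isometric_force_ensemble` - repeated isometric Gillespie runs
  with the ensemble size drawn per run from a small range, reported as the
  grand mean of run means with a 95% t-interval (the standard presentation
  for small-ensemble isometric force).
* :func:`small_ensemble_fv` - a full Monte Carlo FV assay for a
  ~100-head ensemble: unloaded runs to locate V0, isometric runs for the
  v = 0 point, iso-velocity ramps at fixed fractions of V0, and a Hill fit
  excluding the isometric point.

Ramp forces average *all* samples recorded during a ramp of at least one
36-nm actin repeat and at least 0.1 s, mirroring how iso-velocity runs are
usually reduced to a single force estimate; this includes the brief
isometric-to-shortening transient, which is part of the assay definition
rather than an artefact (see the methods note).  Both protocols simulate
the main power stroke as a rapid-equilibrium node, the treatment used in
published small-ensemble simulations of this model; the exact-kinetics
engine remains available through :class:`~xbridge.EnsembleConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hill import HillFitResult, fit_hill
from .montecarlo import EnsembleConfig, _grand_mean_ci, run_isometric, run_ramp, run_unloaded
from .parameters import ModelParameters, SITE_SPACING_NM
from .steady_state import FVCurve, FVPoint

__all__ = [
    "IsometricEnsembleResult",
    "SmallEnsembleFVResult",
    "isometric_force_ensemble",
    "small_ensemble_fv",
    "DEFAULT_VELOCITY_FRACTIONS",
]

#: Ramp speeds for the FV assay, as fractions of the measured V0.
DEFAULT_VELOCITY_FRACTIONS = (0.05, 0.12, 0.22, 0.35, 0.5, 0.65, 0.8)


@dataclass(frozen=True)
class IsometricEnsembleResult:
    grand_mean: float        # pN
    ci_halfwidth: float      # pN, 95% t-interval across runs
    run_means: tuple[float, ...]
    run_N: tuple[int, ...]

    @property
    def n_runs(self) -> int:
        return len(self.run_means)


def isometric_force_ensemble(p: ModelParameters,
                             N_range: tuple[int, int],
                             n_runs: int,
                             seed: int,
                             equilibration_time: float = 0.5,
                             total_time: float = 1.5,
                             record_interval: float = 0.025,
                             ) -> IsometricEnsembleResult:
    """Grand-mean steady isometric force of small stochastic ensembles.

    Each run draws N uniformly from ``N_range`` (inclusive) and fresh
    uniform head offsets, equilibrates, then averages the recorded force
    samples; the grand mean is taken across run means.
    """
    root = np.random.default_rng(seed)
    means, ns = [], []
    for _ in range(n_runs):
        s = int(root.integers(0, 2**31 - 1))
        cfg = EnsembleConfig(
            N_range=N_range, mode="isometric", seed=s,
            equilibration_time=equilibration_time, total_time=total_time,
            record_interval=record_interval, lump_powerstroke=True,
        )
        tr = run_isometric(p, cfg, seed=s)
        means.append(tr.steady_force(equilibration_time))
        ns.append(tr.N)
    gm, half = _grand_mean_ci(means)
    return IsometricEnsembleResult(gm, half, tuple(means), tuple(ns))


@dataclass(frozen=True)
class SmallEnsembleFVResult:
    curve: FVCurve           # per-head forces, incl. v = 0 and unloaded points
    v0_unloaded: float       # nm/s, measured from unloaded runs
    fit: HillFitResult       # Hill fit excluding the isometric point

    @property
    def curvature_ratio(self) -> float:
        return self.fit.curvature_ratio


def small_ensemble_fv(p: ModelParameters, seed: int,
                      N_range: tuple[int, int] = (100, 110),
                      fractions: Sequence[float] = DEFAULT_VELOCITY_FRACTIONS,
                      n_runs_loaded: int = 2,
                      n_runs_isometric: int = 10,
                      n_runs_unloaded: int = 3,
                      ) -> SmallEnsembleFVResult:
    """Monte Carlo FV assay with a Hill fit, for ~100-head ensembles.

    The unloaded velocity is measured first (mean over unloaded runs);
    loaded points are iso-velocity ramps at the given fractions of that
    V0.  The Hill hyperbola is fitted to the loaded points plus the
    unloaded (F = 0) point, excluding the isometric point.
    """
    root = np.random.default_rng(seed)

    v0s = []
    for _ in range(n_runs_unloaded):
        s = int(root.integers(0, 2**31 - 1))
        cfg = EnsembleConfig(N_range=N_range, mode="unloaded", seed=s,
                             equilibration_time=0.1, total_time=0.4,
                             record_interval=0.002, lump_powerstroke=True)
        v0s.append(run_unloaded(p, cfg, seed=s).velocity(0.1))
    v0 = float(np.mean(v0s))

    pts: list[FVPoint] = []
    iso_means = []
    for _ in range(n_runs_isometric):
        s = int(root.integers(0, 2**31 - 1))
        cfg = EnsembleConfig(N_range=N_range, mode="isometric", seed=s,
                             equilibration_time=0.4, total_time=1.0,
                             record_interval=0.02, lump_powerstroke=True)
        tr = run_isometric(p, cfg, seed=s)
        iso_means.append(tr.steady_force(0.4) / tr.N)
    gm, half = _grand_mean_ci(iso_means)
    pts.append(FVPoint(velocity=0.0, force=gm, ci_halfwidth=half))

    for frac in fractions:
        v = frac * v0
        dur = max(SITE_SPACING_NM / v, 0.1)
        means = []
        for _ in range(n_runs_loaded):
            s = int(root.integers(0, 2**31 - 1))
            cfg = EnsembleConfig(N_range=N_range, mode="ramp", seed=s,
                                 ramp_velocity=v, equilibration_time=0.4,
                                 total_time=0.4 + dur,
                                 record_interval=dur / 30,
                                 lump_powerstroke=True)
            tr = run_ramp(p, cfg, seed=s)
            means.append(tr.steady_force(0.4) / tr.N)
        gm, half = _grand_mean_ci(means)
        pts.append(FVPoint(velocity=v, force=max(gm, 0.0),
                           ci_halfwidth=None if np.isnan(half) else half))

    pts.append(FVPoint(velocity=v0, force=0.0))
    curve = FVCurve(tuple(pts), backend="mc")
    fit = fit_hill(curve, window="exclude_isometric")
    return SmallEnsembleFVResult(curve=curve, v0_unloaded=v0, fit=fit)
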