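"""Gillespie stochastic simulation of finite myosin ensembles.

A rigid actin filament is propelled by N independent-headed myosin motors,
each seeing a single binding site per 36-nm target-zone repeat at a random
(uniform) offset.  Three run modes mirror the standard experimental
protocols:

* ``isometric`` - the filament is held fixed; force builds to a stochastic
  steady state.
* ``unloaded``  - after every transition the filament is repositioned so
  the total elastic force is exactly zero; the drift of the filament
  position gives the unloaded shortening velocity.
* ``ramp``      - isometric equilibration followed by an imposed
  iso-velocity shortening ramp; the mean of all force samples recorded
  during the ramp estimates the steady-state force at that velocity.

By default the full 7-state kinetics is simulated with the same capped
rates the master-equation backend integrates, so the two backends agree
for large N (the module's principal cross-check).  Setting
``lump_powerstroke=True`` instead treats the very fast main power stroke
as a rapid equilibrium (AMD_L/AMD_H collapsed into one Boltzmann-weighted
node), which removes the fastest events at the cost of a small force bias
during rapid sliding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .parameters import ModelParameters, SITE_SPACING_NM
from .steady_state import FVCurve, FVPoint, WINDOW_LO_NM

__all__ = [
    "EnsembleConfig",
    "Trajectory",
    "AttachmentStats",
    "build_ensemble",
    "gillespie_step",
    "run_isometric",
    "run_unloaded",
    "run_ramp",
    "fv_from_mc",
    "binomial_attachment_stats",
]

#: Default single-site accessibility: ~5 nm of favourable offsets per 36 nm.
DEFAULT_SITE_P = 5.0 / 36.0


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of a Monte Carlo run set."""

    N: Optional[int] = None            # number of available heads
    rho: Optional[float] = None        # surface motor density, um^-2
    L: Optional[float] = None          # filament length, um
    d: Optional[float] = None          # reach band width, um
    N_range: Optional[tuple[int, int]] = None  # inclusive; N drawn per run
    mode: str = "isometric"            # isometric | unloaded | ramp
    ramp_velocity: float = 0.0         # nm/s, ramp mode only
    equilibration_time: float = 0.5    # s
    total_time: float = 1.5            # s
    record_interval: float = 0.025     # s
    n_runs: int = 1
    seed: int = 0
    site_spacing: float = SITE_SPACING_NM
    lump_powerstroke: bool = False     # rapid-equilibrium power-stroke node

    def __post_init__(self) -> None:
        if self.mode not in ("isometric", "unloaded", "ramp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ramp" and self.ramp_velocity <= 0:
            raise ValueError("ramp mode requires ramp_velocity > 0")
        if self.total_time <= 0 or self.record_interval <= 0:
            raise ValueError("times must be positive")
        if (self.N is None and self.N_range is None
                and (self.rho is None or self.L is None or self.d is None)):
            raise ValueError(
                "specify N, N_range, or the full surface geometry (rho, L, d)"
            )

    def draw_N(self, rng: np.random.Generator) -> int:
        if self.N_range is not None:
            lo, hi = self.N_range
            return int(rng.integers(lo, hi + 1))
        if self.N is not None:
            return int(self.N)
        return int(round(self.rho * self.d * self.L))


@dataclass(frozen=True)
class Trajectory:
    """Sampled time series of one Monte Carlo run.

    ``counts`` carries per-state head counts for the full 7 states; the
    lumped power-stroke node is split between AMD_L and AMD_H by its
    Boltzmann weight, so those two columns are fractional but every row
    still sums exactly to N.
    """

    time: np.ndarray          # s
    X: np.ndarray             # filament position, nm
    force: np.ndarray         # total ensemble force, pN
    counts: np.ndarray        # (R, 7)
    atp_events: np.ndarray    # cumulative ATP turnovers
    N: int
    mode: str
    ramp_start: Optional[float] = None   # s, ramp mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N > 0 and not np.allclose(self.counts.sum(axis=1), self.N,
                                          atol=1e-9):
            raise ValueError("per-record head counts must sum to N")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.time, "X_nm": self.X, "force_pN": self.force}
        )
        for j in range(7):
            df[f"n_state_{j + 1}"] = self.counts[:, j]
        df["atp_events"] = self.atp_events
        return df

    # -- summaries -----------------------------------------------------
    def steady_force(self, t_from: float) -> float:
        """Mean force over samples recorded at or after ``t_from``, pN."""
        m = self.time >= t_from - 1e-12
        return float(self.force[m].mean())

    def velocity(self, t_from: float = 0.0) -> float:
        """Mean sliding speed (positive for shortening), nm/s."""
        m = self.time >= t_from - 1e-12
        if m.sum() < 2:
            raise ValueError("not enough samples to estimate a velocity")
        slope = np.polyfit(self.time[m], self.X[m], 1)[0]
        return float(-slope)

    def attached_count(self) -> np.ndarray:
        return self.counts[:, :5].sum(axis=1)


@dataclass(frozen=True)
class AttachmentStats:
    """Binomial between-run statistics of the attached-head count."""

    N: int
    p: float
    mean: float
    sd: float
    snr: float


def binomial_attachment_stats(N: int, p: float = DEFAULT_SITE_P) -> AttachmentStats:
    """Exact Bin(N, p) mean, SD and signal-to-noise ratio sqrt(Np/(1-p))."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if N < 0:
        raise ValueError("N must be non-negative")
    mean = N * p
    sd = math.sqrt(N * p * (1.0 - p))
    snr = math.sqrt(N * p / (1.0 - p)) if p < 1.0 else math.inf
    return AttachmentStats(N=N, p=p, mean=mean, sd=sd, snr=snr)


# ---------------------------------------------------------------------------
# setup helpers
# ---------------------------------------------------------------------------

def _pack_params(p: ModelParameters) -> np.ndarray:
    pv = np.zeros(K.NPAR)
    pv[K.KS], pv[K.X1], pv[K.X11], pv[K.X2], pv[K.X3] = (
        p.k_s, p.x1, p.x11, p.x2, p.x3,
    )
    pv[K.XCRIT] = p.x_crit
    pv[K.DG_ON], pv[K.DG_PIR], pv[K.DG_LH], pv[K.DG_HD] = (
        p.dG_on, p.dG_PiR, p.dG_LH, p.dG_HD,
    )
    pv[K.KON], pv[K.KPR], pv[K.KPPLUS] = p.kon_prime, p.kPr_prime, p.kP_plus
    pv[K.K5MINUS], pv[K.K2ZERO], pv[K.K6] = p.k5_minus, p.k2_zero, p.k6
    pv[K.K3F], pv[K.K3R] = p.k3_plus, p.k3_minus
    pv[K.K1C], pv[K.KC], pv[K.MGATP], pv[K.PI_C] = p.K1, p.KC, p.mgatp, p.pi
    pv[K.KBT], pv[K.RMIN] = p.kBT, p.r_min
    pv[K.KLHMINUS] = p.kLH_minus
    return pv


def build_ensemble(cfg: EnsembleConfig, p: ModelParameters,
                   rng: np.random.Generator | int | None = None,
                   N: Optional[int] = None) -> np.ndarray:
    """Initial head-site offsets: N draws uniform over one 36-nm repeat."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = cfg.draw_N(rng) if N is None else int(N)
    lo = p.x3 + WINDOW_LO_NM
    return lo + rng.random(n) * SITE_SPACING_NM


def _initial_states(n: int, p: ModelParameters,
                    rng: np.random.Generator) -> np.ndarray:
    """Detached start, equilibrated between MT and MDP (odds 1 : K3)."""
    mdp = rng.random(n) < p.K3 / (1.0 + p.K3)
    return np.where(mdp, 6, 5).astype(np.int64)


def gillespie_step(states: np.ndarray, xs: np.ndarray, p: ModelParameters,
                   rng: np.random.Generator, mode: str = "iso",
                   lump: bool = False) -> tuple[int, int, float]:
    """One exact Gillespie step for an ensemble of heads.

    ``states`` uses the cycle codes (0 PP, 1 PiR, 2 AMD_L, 3 AMD_H,
    4 AM/AMD, 5 MT, 6 MDP; with ``lump`` state 2 is the combined
    power-stroke node and 3 is unused).  The waiting time is exponential
    in the total propensity and the event is chosen with probability
    proportional to its propensity.  Returns (head index, new state,
    waiting time).

    Raises
    ------
    RuntimeError
        If every propensity is zero (absorbing configuration).
    """
    pv = _pack_params(p)
    rmax = p.r_max(mode)
    n = len(states)
    rates = np.zeros((n, 2))
    targets = np.zeros((n, 2), dtype=int)
    for i in range(n):
        r0, t0, r1, t1 = K.head_rates(int(states[i]), float(xs[i]), pv,
                                      rmax, lump)
        rates[i] = (r0, r1)
        targets[i] = (t0, t1)
    total = rates.sum()
    if total <= 0:
        raise RuntimeError("all propensities are zero: absorbing state")
    dt = rng.exponential(1.0 / total)
    flat = rates.ravel().cumsum()
    k = int(np.searchsorted(flat, rng.random() * total, side="right"))
    head, which = divmod(k, 2)
    return head, int(targets[head, which]), float(dt)


# ---------------------------------------------------------------------------
# run modes
# ---------------------------------------------------------------------------

def _rec_times(cfg: EnsembleConfig) -> np.ndarray:
    return np.arange(cfg.record_interval, cfg.total_time + 1e-12,
                     cfg.record_interval)


def _run_prescribed(p: ModelParameters, cfg: EnsembleConfig, ramp_v: float,
                    seed: Optional[int]) -> Trajectory:
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x0 = build_ensemble(cfg, p, rng)
    s0 = _initial_states(len(x0), p, rng)
    rec = _rec_times(cfg)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    if len(x0) == 0:
        force = np.zeros(len(rec))
        counts = np.zeros((len(rec), 7))
        atp = np.zeros(len(rec))
    else:
        force, counts, atp = K.simulate_prescribed(
            _pack_params(p), x0, s0, float(ramp_v), cfg.equilibration_time,
            cfg.total_time, rec, p.x3 + WINDOW_LO_NM, p.r_max_iso,
            p.r_max_shortening, 0.1, cfg.lump_powerstroke, kernel_seed,
        )
    if ramp_v > 0:
        X = -np.clip(rec - cfg.equilibration_time, 0.0, None) * ramp_v
        ramp_start: Optional[float] = cfg.equilibration_time
    else:
        X = np.zeros_like(rec)
        ramp_start = None
    return Trajectory(rec, X, force, counts, np.cumsum(atp), N=len(x0),
                      mode=cfg.mode, ramp_start=ramp_start, seed=seed)


def run_isometric(p: ModelParameters, cfg: EnsembleConfig,
                  seed: Optional[int] = None) -> Trajectory:
    """Isometric run: filament held fixed, isometric rate caps."""
    if cfg.mode != "isometric":
        raise ValueError("config mode must be 'isometric'")
    return _run_prescribed(p, cfg, 0.0, seed)


def run_ramp(p: ModelParameters, cfg: EnsembleConfig,
             seed: Optional[int] = None) -> Trajectory:
    """Isometric equilibration followed by an iso-velocity shortening ramp."""
    if cfg.mode != "ramp":
        raise ValueError("config mode must be 'ramp'")
    ramp_dist = cfg.ramp_velocity * (cfg.total_time - cfg.equilibration_time)
    if ramp_dist < SITE_SPACING_NM:
        import warnings

        warnings.warn(
            f"ramp distance {ramp_dist:.1f} nm is below one 36-nm repeat; "
            "between-run variability will not average out", stacklevel=2,
        )
    return _run_prescribed(p, cfg, cfg.ramp_velocity, seed)


def run_unloaded(p: ModelParameters, cfg: EnsembleConfig,
                 seed: Optional[int] = None) -> Trajectory:
    """Unloaded run: filament repositioned to zero net force after each event."""
    if cfg.mode != "unloaded":
        raise ValueError("config mode must be 'unloaded'")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x0 = build_ensemble(cfg, p, rng)
    s0 = _initial_states(len(x0), p, rng)
    rec = _rec_times(cfg)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    X, force, counts, atp = K.simulate_unloaded(
        _pack_params(p), x0, s0, cfg.total_time, rec,
        p.x3 + WINDOW_LO_NM, p.r_max_shortening, 0.05,
        cfg.lump_powerstroke, kernel_seed,
    )
    return Trajectory(rec, X, force, counts, np.cumsum(atp), N=len(x0),
                      mode="unloaded", seed=seed)


# ---------------------------------------------------------------------------
# FV construction
# ---------------------------------------------------------------------------

def _grand_mean_ci(run_means: Sequence[float]) -> tuple[float, float]:
    """Grand mean and 95% CI half-width across run means (t distribution)."""
    m = np.asarray(run_means, dtype=float)
    gm = float(m.mean())
    if len(m) < 2:
        return gm, math.nan
    half = float(stats.t.ppf(0.975, len(m) - 1) * m.std(ddof=1)
                 / math.sqrt(len(m)))
    return gm, half


def fv_from_mc(p: ModelParameters, cfg: EnsembleConfig,
               velocities: Sequence[float], n_runs: Optional[int] = None,
               n_runs_isometric: Optional[int] = None,
               include_unloaded: bool = False,
               parameter_set: str = "") -> FVCurve:
    """Monte Carlo FV curve: isometric runs at v = 0, ramp runs at v > 0.

    Forces are per available head (grand mean of run means); the CI
    half-width is the 95% t-interval across runs.  With
    ``include_unloaded`` an unloaded point (F = 0 at the measured V0) is
    appended.
    """
    n_runs = cfg.n_runs if n_runs is None else n_runs
    n_iso = n_runs if n_runs_isometric is None else n_runs_isometric
    root = np.random.default_rng(cfg.seed)
    pts: list[FVPoint] = []
    for v in velocities:
        runs = n_iso if v == 0 else n_runs
        means = []
        for _ in range(runs):
            seed = int(root.integers(0, 2**31 - 1))
            if v == 0:
                c = replace(cfg, mode="isometric", ramp_velocity=0.0)
                tr = run_isometric(p, c, seed=seed)
            else:
                c = replace(cfg, mode="ramp", ramp_velocity=float(v))
                tr = run_ramp(p, c, seed=seed)
            means.append(tr.steady_force(cfg.equilibration_time) / tr.N)
        gm, half = _grand_mean_ci(means)
        pts.append(FVPoint(velocity=float(v), force=gm,
                           ci_halfwidth=None if math.isnan(half) else half))
    if include_unloaded:
        v0s = []
        for _ in range(max(2, n_runs)):
            seed = int(root.integers(0, 2**31 - 1))
            c = replace(cfg, mode="unloaded", ramp_velocity=0.0)
            tr = run_unloaded(p, c, seed=seed)
            v0s.append(tr.velocity(cfg.equilibration_time))
        pts.append(FVPoint(velocity=float(np.mean(v0s)), force=0.0))
    return FVCurve(tuple(pts), parameter_set=parameter_set, backend="mc")
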