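"""Gillespie ensemble simulation: step statistics, run modes, invariants."""

import numpy as np
import pytest
from scipy import stats

import xbridge._kernels as K
from xbridge import (
    EnsembleConfig,
    binomial_attachment_stats,
    build_ensemble,
    run_isometric,
    run_ramp,
    run_unloaded,
    solve_sliding,
)
from xbridge.montecarlo import _initial_states, _pack_params, gillespie_step


# ---------------------------------------------------------------------------
# configuration and setup
# ---------------------------------------------------------------------------

def test_config_requires_some_ensemble_size():
    with pytest.raises(ValueError):
        EnsembleConfig()
    cfg = EnsembleConfig(rho=250.0, L=400.0, d=0.05)
    n = cfg.draw_N(np.random.default_rng(0))
    assert n == round(250.0 * 400.0 * 0.05)


def test_surface_geometry_reaches_large_ensembles():
    # the convergence geometry: L > 400 um, rho < 250 um^-2 gives N > 1000
    cfg = EnsembleConfig(rho=249.0, L=410.0, d=0.02)
    assert cfg.draw_N(np.random.default_rng(0)) > 1000


def test_config_mode_validation():
    with pytest.raises(ValueError):
        EnsembleConfig(N=10, mode="ramp", ramp_velocity=0.0)
    with pytest.raises(ValueError):
        EnsembleConfig(N=10, mode="flying")


def test_build_ensemble_offsets_uniform(optimized, rng):
    cfg = EnsembleConfig(N=10_000, seed=7)
    x = build_ensemble(cfg, optimized, rng)
    lo = optimized.x3 - 22.0
    assert x.min() >= lo
    assert x.max() < lo + 36.0
    ks = stats.kstest((x - lo) / 36.0, "uniform")
    assert ks.pvalue > 0.01


def test_empty_ensemble_zero_force(optimized):
    cfg = EnsembleConfig(N=0, mode="isometric", total_time=0.2,
                         record_interval=0.05, seed=1)
    tr = run_isometric(optimized, cfg)
    assert np.all(tr.force == 0.0)
    assert np.all(tr.counts == 0.0)


def test_initial_states_equilibrated_between_detached(optimized, rng):
    s = _initial_states(200_000, optimized, rng)
    assert set(np.unique(s)) <= {5, 6}
    frac_mdp = np.mean(s == 6)
    expected = optimized.K3 / (1 + optimized.K3)
    assert frac_mdp == pytest.approx(expected, abs=0.005)


# ---------------------------------------------------------------------------
# single-step statistics
# ---------------------------------------------------------------------------

def test_waiting_time_exponential(optimized, rng):
    """Single head in MT: only hydrolysis possible at rate k3_plus."""
    p = optimized
    states = np.array([5])
    xs = np.array([p.x3])
    dts = np.array([gillespie_step(states, xs, p, rng)[2]
                    for _ in range(10_000)])
    rate = p.k3_plus
    se = 1.0 / (rate * np.sqrt(len(dts)))
    assert abs(dts.mean() - 1.0 / rate) < 3 * se
    # all events are MT -> MDP
    head, new_state, _ = gillespie_step(states, xs, p, rng)
    assert (head, new_state) == (0, 6)


def test_event_selection_proportional_to_propensity(optimized, rng):
    """MDP head at an offset where attachment runs at twice the reverse
    hydrolysis rate: selection frequencies 2:1."""
    p = optimized
    target = 2.0 * p.k3_minus
    # solve kon(x) = target for x > x1
    dx = np.sqrt(4 * p.kBT * (p.dG_on - np.log(target / p.kon_prime)) / p.k_s)
    states = np.array([6])
    xs = np.array([p.x1 + dx])
    n = 5000
    to_attached = sum(
        gillespie_step(states, xs, p, rng)[1] == 0 for _ in range(n)
    )
    ci = stats.binomtest(to_attached, n, 2.0 / 3.0).pvalue
    assert ci > 0.001


def test_lumped_powerstroke_boltzmann_weight(optimized):
    """Where the power-stroke rates are uncapped the lumped-node split is
    the plain Boltzmann factor; where the forward rate saturates at the
    cap the split saturates with it (matching the capped 7-state kinetics)."""
    p = optimized
    pv = _pack_params(p)
    rmax = p.r_max_shortening
    for x in (-3.5, -2.0, 0.0, 2.0):
        gap = p.dG_LH + p.k_s * ((x - p.x11) ** 2 - (x - p.x2) ** 2) / (2 * p.kBT)
        if p.kLH_minus * np.exp(gap) < rmax:
            expected = 1.0 / (1.0 + np.exp(-gap))
            assert K.lh_weight_h(x, pv, rmax) == pytest.approx(expected,
                                                               rel=1e-12)
    # strongly downhill: forward clamped, ratio = rmax / kLH_minus
    r = rmax / p.kLH_minus
    assert K.lh_weight_h(-8.0, pv, rmax) == pytest.approx(r / (1 + r),
                                                          rel=1e-12)


def test_absorbing_state_raises(optimized, rng):
    p = optimized.replace(mgatp=1e-12, r_min=1e-300)
    # AM/AMD head with no ATP: detachment ~ 0 but reverse stroke remains
    states, xs = np.array([4]), np.array([p.x3])
    head, new_state, dt = gillespie_step(states, xs, p, rng)
    assert new_state == 3  # reverse second sub-stroke still available


# ---------------------------------------------------------------------------
# run modes
# ---------------------------------------------------------------------------

def test_isometric_run_invariants(optimized):
    cfg = EnsembleConfig(N=25, mode="isometric", total_time=0.5,
                         equilibration_time=0.2, record_interval=0.01, seed=3)
    tr = run_isometric(optimized, cfg)
    assert np.all(tr.X == 0.0)
    assert np.allclose(tr.counts.sum(axis=1), 25)
    assert tr.steady_force(0.2) > 0


def test_isometric_reproducible_with_seed(optimized):
    cfg = EnsembleConfig(N=15, mode="isometric", total_time=0.3,
                         record_interval=0.01, seed=42)
    a = run_isometric(optimized, cfg)
    b = run_isometric(optimized, cfg)
    assert np.array_equal(a.force, b.force)
    assert np.array_equal(a.counts, b.counts)


def test_unloaded_force_is_zero_at_every_sample(optimized):
    cfg = EnsembleConfig(N=60, mode="unloaded", total_time=0.05,
                         record_interval=0.001, seed=9)
    tr = run_unloaded(optimized, cfg)
    assert np.abs(tr.force).max() < 1e-9
    assert tr.velocity(0.01) > 0  # net shortening


def test_zero_force_shift_single_attached_head(optimized):
    """One rigor head at strain s: the filament must shift by exactly -s."""
    p = optimized
    pv = _pack_params(p)
    s = 2.7
    x = np.array([p.x3 + s])
    st_ = np.array([4], dtype=np.int64)
    delta, ok = K._zero_force_shift(x, st_, pv, p.r_max_shortening, False)
    assert ok
    assert delta == pytest.approx(-s, abs=1e-9)


def test_ramp_force_below_isometric_and_above_zero(optimized):
    iso = EnsembleConfig(N=200, mode="isometric", total_time=0.7,
                         equilibration_time=0.3, record_interval=0.01, seed=21)
    f_iso = run_isometric(optimized, iso).steady_force(0.3) / 200
    cfg = EnsembleConfig(N=200, mode="ramp", ramp_velocity=2000.0,
                         total_time=0.5, equilibration_time=0.3,
                         record_interval=0.005, seed=21)
    tr = run_ramp(optimized, cfg)
    # steady portion: skip the first repeat of post-onset relaxation
    f_ramp = tr.steady_force(0.3 + 36.0 / 2000.0) / 200
    assert 0 < f_ramp < f_iso
    assert tr.ramp_start == 0.3
    # filament position follows the prescribed ramp
    m = tr.time >= 0.3
    assert np.allclose(tr.X[m], -(tr.time[m] - 0.3) * 2000.0)


def test_ramp_warns_below_one_repeat(optimized):
    cfg = EnsembleConfig(N=5, mode="ramp", ramp_velocity=100.0,
                         total_time=0.35, equilibration_time=0.3,
                         record_interval=0.01, seed=2)
    with pytest.warns(UserWarning, match="36"):
        run_ramp(optimized, cfg)


def test_slow_ramp_approaches_isometric_force(optimized):
    """Continuity: a very slow ramp's mean force is close to isometric."""
    iso = EnsembleConfig(N=300, mode="isometric", total_time=1.0,
                         equilibration_time=0.4, record_interval=0.01, seed=33)
    f_iso = run_isometric(optimized, iso).steady_force(0.4) / 300
    slow = EnsembleConfig(N=300, mode="ramp", ramp_velocity=40.0,
                          total_time=1.4, equilibration_time=0.4,
                          record_interval=0.01, seed=33)
    f_slow = run_ramp(optimized, slow).steady_force(0.4) / 300
    assert f_slow == pytest.approx(f_iso, rel=0.12)


def test_unloaded_velocity_increases_with_ensemble_size(optimized):
    def v0(N, seed):
        cfg = EnsembleConfig(N=N, mode="unloaded", total_time=0.15,
                             equilibration_time=0.05, record_interval=0.002,
                             seed=seed)
        return run_unloaded(optimized, cfg).velocity(0.05)

    small = np.mean([v0(15, s) for s in (1, 2, 3)])
    large = np.mean([v0(150, s) for s in (1, 2, 3)])
    assert small < large


def test_between_run_ramp_spread_smaller_than_isometric(optimized):
    """Slow shortening over >36 nm averages out the head-placement noise
    that dominates isometric force variability in tiny ensembles."""
    iso_means, ramp_means = [], []
    for s in range(10):
        iso = EnsembleConfig(N=18, mode="isometric", total_time=0.8,
                             equilibration_time=0.3, record_interval=0.02,
                             seed=100 + s)
        iso_means.append(run_isometric(optimized, iso).steady_force(0.3))
        ramp = EnsembleConfig(N=18, mode="ramp", ramp_velocity=450.0,
                              total_time=0.5, equilibration_time=0.3,
                              record_interval=0.005, seed=100 + s)
        ramp_means.append(run_ramp(optimized, ramp).steady_force(0.3))
    assert np.var(ramp_means) < np.var(iso_means)


# ---------------------------------------------------------------------------
# occupancy cross-check against the master-equation backend
# ---------------------------------------------------------------------------

def test_sliding_occupancy_matches_master_equation(optimized):
    """Heads swept through the repeat at constant speed sample the
    periodic steady state: time-averaged state fractions match the
    period-averaged solution of the master equation."""
    p = optimized
    v = 2000.0
    d = solve_sliding(p, v)
    marg = d.p.mean(axis=0)  # uniform offsets -> plain grid average
    cfg = EnsembleConfig(N=400, mode="ramp", ramp_velocity=v,
                         total_time=0.9, equilibration_time=0.3,
                         record_interval=0.005, seed=77)
    tr = run_ramp(p, cfg)
    m = tr.time >= 0.5  # well into the ramp
    frac = tr.counts[m].mean(axis=0) / 400
    # compare attached fraction and the dominant states coarsely (the MC
    # lumps the power-stroke pair, so tolerances are statistical)
    assert frac[:5].sum() == pytest.approx(marg[:5].sum(), abs=0.03)
    assert frac[5] == pytest.approx(marg[5], abs=0.03)
    assert frac[6] == pytest.approx(marg[6], abs=0.03)


# ---------------------------------------------------------------------------
# binomial attachment statistics
# ---------------------------------------------------------------------------

def test_binomial_attachment_moments():
    st_ = binomial_attachment_stats(36, 5.0 / 36.0)
    assert st_.mean == pytest.approx(5.0)
    assert st_.sd == pytest.approx(np.sqrt(36 * (5 / 36) * (31 / 36)))
    assert st_.sd == pytest.approx(2.075, abs=0.001)
    assert st_.snr == pytest.approx(np.sqrt(5.0 / (31 / 36)))


def test_binomial_attachment_edge_cases():
    z = binomial_attachment_stats(10, 0.0)
    assert z.mean == 0 and z.sd == 0 and z.snr == 0
    with pytest.raises(ValueError):
        binomial_attachment_stats(10, 1.5)
    with pytest.raises(ValueError):
        binomial_attachment_stats(-1, 0.5)


# ---------------------------------------------------------------------------
# FV assembly and ATP accounting
# ---------------------------------------------------------------------------

def test_fv_from_mc_assembles_curve_with_intervals(optimized):
    from xbridge import fv_from_mc

    cfg = EnsembleConfig(N=40, mode="isometric", total_time=0.6,
                         equilibration_time=0.3, record_interval=0.01,
                         seed=13, n_runs=3)
    curve = fv_from_mc(optimized, cfg, [0.0, 3000.0], include_unloaded=True)
    assert curve.backend == "mc"
    assert len(curve.points) == 3
    iso = curve.points[0]
    assert iso.velocity == 0.0 and iso.ci_halfwidth is not None
    unloaded = curve.points[-1]
    assert unloaded.force == 0.0 and unloaded.velocity > 3000.0


def test_atp_turnover_matches_steady_state_flux(optimized):
    """ATP-consuming detachments per head per second in a long isometric
    run agree with the cycle flux of the master-equation solution."""
    from xbridge import atpase_rate, solve_isometric

    p = optimized
    rate_ode = atpase_rate(solve_isometric(p), p)
    cfg = EnsembleConfig(N=800, mode="isometric", total_time=1.5,
                         equilibration_time=0.5, record_interval=0.05,
                         seed=19)
    tr = run_isometric(p, cfg)
    m = tr.time >= 0.5
    events = tr.atp_events[m][-1] - tr.atp_events[m][0]
    duration = tr.time[m][-1] - tr.time[m][0]
    rate_mc = events / (800 * duration)
    # Poisson-ish counting error over ~3000 events plus placement noise
    assert rate_mc == pytest.approx(rate_ode, rel=0.10)
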