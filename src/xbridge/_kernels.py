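"""Numba kernels for the Gillespie ensemble simulations.

Head states use the cycle's own indices::

    0 AMDP_PP   1 AMDP_PiR   2 AMD_L   3 AMD_H   4 AM/AMD   5 MT   6 MDP

Two kinetic treatments of the fast main power stroke are supported.  With
``lump = False`` (the default of the public API) AMD_L and AMD_H are
simulated explicitly with their capped forward/backward rates — exactly
the kinetics the master-equation backend integrates.  With ``lump = True``
state 2 represents a rapid-equilibrium node combining AMD_L and AMD_H
(state 3 is then unused): its internal split is the fast-equilibrium
ratio of the *capped* power-stroke rates and its exit propensities are the
split-weighted exit rates of the two sub-states.  Lumping removes the
fastest transitions but slightly biases the force during rapid sliding,
where the true power-stroke population lags its local equilibrium.

Parameter vectors are packed by :func:`xbridge.montecarlo._pack_params`;
index constants below must stay in sync with it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter-vector layout
KS, X1, X11, X2, X3, XCRIT = 0, 1, 2, 3, 4, 5
DG_ON, DG_PIR, DG_LH, DG_HD = 6, 7, 8, 9
KON, KPR, KPPLUS, K5MINUS, K2ZERO, K6 = 10, 11, 12, 13, 14, 15
K3F, K3R, K1C, KC, MGATP, PI_C, KBT, RMIN = 16, 17, 18, 19, 20, 21, 22, 23
KLHMINUS = 24
NPAR = 25

SPAN = 36.0


@njit(cache=True)
def _clamp(r, rmin, rmax):
    if r < rmin:
        return rmin
    if r > rmax:
        return rmax
    return r


@njit(cache=True)
def lh_weight_h(x, pv, rmax):
    """Occupancy weight of AMD_H within the rapid-equilibrium node.

    The split is the fast-equilibrium ratio of the forward and reverse
    power-stroke rates *after* rate capping, so the node reproduces the
    capped-kinetics occupancies of the explicit description (uncapped, the
    ratio reduces to the Boltzmann factor of the two wells).
    """
    gap = pv[DG_LH] + pv[KS] * (
        (x - pv[X11]) ** 2 - (x - pv[X2]) ** 2
    ) / (2.0 * pv[KBT])
    k_rev = _clamp(pv[KLHMINUS], pv[RMIN], rmax)
    if gap > 100.0:
        k_fwd = rmax
    else:
        k_fwd = _clamp(pv[KLHMINUS] * np.exp(gap), pv[RMIN], rmax)
    r = k_fwd / k_rev
    return r / (1.0 + r)


@njit(cache=True)
def head_rates(s, x, pv, rmax, lump):
    """Exit propensities of a head in state s at strain x.

    Returns (r0, target0, r1, target1); r1 may be 0 (single-exit states).
    """
    rmin = pv[RMIN]
    ks = pv[KS]
    kbt = pv[KBT]
    if s == 0:  # AMDP_PP -> PiR | -> MDP
        strain = (ks / 2.0) * ((x - pv[X11]) ** 2 - (x - pv[X1]) ** 2) / (2.0 * kbt)
        r0 = pv[KPR] * np.exp(pv[DG_PIR] / 2.0 - strain)
        r1 = pv[KON] * np.exp(ks * (x - pv[X1]) ** 2 / (4.0 * kbt))
        return _clamp(r0, rmin, rmax), 1, _clamp(r1, rmin, rmax), 6
    if s == 1:  # AMDP_PiR -> AMD_L (Pi release) | -> PP
        strain = (ks / 2.0) * ((x - pv[X11]) ** 2 - (x - pv[X1]) ** 2) / (2.0 * kbt)
        r0 = pv[KPPLUS]
        r1 = pv[KPR] * np.exp(-pv[DG_PIR] / 2.0 + strain)
        return _clamp(r0, rmin, rmax), 2, _clamp(r1, rmin, rmax), 0
    if s == 2:
        k_pi_rev = pv[KPPLUS] * pv[PI_C] / pv[KC]
        if lump:  # rapid-equilibrium node: weighted exits from L and H
            wh = lh_weight_h(x, pv, rmax)
            gap5 = pv[DG_HD] + ks * (
                (x - pv[X2]) ** 2 - (x - pv[X3]) ** 2) / (2.0 * kbt)
            k5f = pv[K5MINUS] * np.exp(gap5)
            r0 = (1.0 - wh) * _clamp(k_pi_rev, rmin, rmax)
            r1 = wh * _clamp(k5f, rmin, rmax)
            return r0, 1, r1, 4
        # explicit AMD_L -> PiR | -> AMD_H (main power stroke)
        gap = pv[DG_LH] + ks * (
            (x - pv[X11]) ** 2 - (x - pv[X2]) ** 2) / (2.0 * kbt)
        if gap > 100.0:
            k_lh = rmax
        else:
            k_lh = _clamp(pv[KLHMINUS] * np.exp(gap), rmin, rmax)
        return _clamp(k_pi_rev, rmin, rmax), 1, k_lh, 3
    if s == 3:  # AMD_H -> AMD_L (stroke reversal) | -> AM/AMD
        gap5 = pv[DG_HD] + ks * (
            (x - pv[X2]) ** 2 - (x - pv[X3]) ** 2) / (2.0 * kbt)
        if gap5 > 100.0:
            k5f = rmax
        else:
            k5f = _clamp(pv[K5MINUS] * np.exp(gap5), rmin, rmax)
        return _clamp(pv[KLHMINUS], rmin, rmax), 2, k5f, 4
    if s == 4:  # AM/AMD -> MT (ATP-induced, irreversible) | -> AMD_H
        k2 = pv[K2ZERO] * np.exp(ks * np.abs(x - pv[X3]) * pv[XCRIT] / kbt)
        T = pv[MGATP]
        koff = k2 * T / (1.0 / pv[K1C] + (1.0 + k2 / pv[K6]) * T)
        back = 2 if lump else 3
        return _clamp(koff, rmin, rmax), 5, _clamp(pv[K5MINUS], rmin, rmax), back
    if s == 5:  # MT -> MDP (recovery stroke + hydrolysis)
        return _clamp(pv[K3F], rmin, rmax), 6, 0.0, 5
    # s == 6, MDP -> PP (attachment) | -> MT
    r0 = pv[KON] * np.exp(pv[DG_ON] - pv[KS] * (x - pv[X1]) ** 2 / (4.0 * kbt))
    return _clamp(r0, rmin, rmax), 0, _clamp(pv[K3R], rmin, rmax), 5


@njit(cache=True)
def _state_xmin(s, x, pv, rmax, lump):
    if s == 0:
        return pv[X1]
    if s == 1:
        return pv[X11]
    if s == 2:
        if lump:
            wh = lh_weight_h(x, pv, rmax)
            return (1.0 - wh) * pv[X11] + wh * pv[X2]
        return pv[X11]
    if s == 3:
        return pv[X2]
    return pv[X3]


@njit(cache=True)
def head_force(s, x, pv, rmax, lump):
    """Elastic force of a head, pN (detached states exert none)."""
    if s >= 5:
        return 0.0
    return pv[KS] * (x - _state_xmin(s, x, pv, rmax, lump))


@njit(cache=True)
def _wrap(x, lo):
    while x < lo:
        x += SPAN
    while x >= lo + SPAN:
        x -= SPAN
    return x


@njit(cache=True)
def _add_counts(counts, rec, s, x, pv, rmax, lump):
    if s == 2 and lump:
        wh = lh_weight_h(x, pv, rmax)
        counts[rec, 2] += 1.0 - wh
        counts[rec, 3] += wh
    else:
        counts[rec, s] += 1.0


@njit(cache=True)
def simulate_prescribed(pv, x0, s0, ramp_v, t_equil, t_end, rec_times,
                        wrap_lo, rmax_iso, rmax_short, max_step_nm, lump,
                        seed):
    """Isometric (ramp_v = 0) or isometric + iso-velocity-ramp run.

    The filament position X(t) is prescribed (0 during equilibration, then
    decreasing at ramp_v), so the heads are statistically independent and
    are simulated one at a time.  During the ramp, propensities are frozen
    over displacements of at most ``max_step_nm`` (null events are inserted
    when the exponential waiting time overshoots).

    Returns (force[R], counts[R, 7], atp_events[R]) where atp_events bins
    ATP-consuming detachment events by the following record time.
    """
    np.random.seed(seed)
    N = x0.shape[0]
    R = rec_times.shape[0]
    force = np.zeros(R)
    counts = np.zeros((R, 7))
    atp = np.zeros(R)
    for i in range(N):
        t = 0.0
        x = x0[i]
        s = s0[i]
        rec = 0
        while t < t_end:
            in_ramp = ramp_v > 0.0 and t >= t_equil
            rmax = rmax_short if in_ramp else rmax_iso
            r0, tg0, r1, tg1 = head_rates(s, x, pv, rmax, lump)
            a = r0 + r1
            dt = -np.log(np.random.random()) / a
            if ramp_v > 0.0:
                cap = (t_equil - t) if t < t_equil else (max_step_nm / ramp_v)
            else:
                cap = 1.0e18
            is_event = dt <= cap
            if not is_event:
                dt = cap
            t_new = t + dt
            if t_new > t_end:
                t_new = t_end
                is_event = False
            # record samples falling in (t, t_new]
            while rec < R and rec_times[rec] <= t_new + 1e-15:
                tr = rec_times[rec]
                dx = ramp_v * (tr - t_equil if t < t_equil else tr - t) \
                    if (ramp_v > 0.0 and tr > t_equil) else 0.0
                xr = x - dx
                force[rec] += head_force(s, xr, pv, rmax, lump)
                _add_counts(counts, rec, s, xr, pv, rmax, lump)
                rec += 1
            # advance the strain for motion over (t, t_new]
            if ramp_v > 0.0 and t_new > t_equil:
                x -= ramp_v * (t_new - (t_equil if t < t_equil else t))
                if s >= 5:
                    x = _wrap(x, wrap_lo)
            t = t_new
            if t >= t_end:
                break
            if is_event:
                if np.random.random() * a < r0:
                    s_new = tg0
                else:
                    s_new = tg1
                if s == 4 and s_new == 5 and rec < R:
                    atp[rec] += 1.0
                s = s_new
    return force, counts, atp


@njit(cache=True)
def _total_force_shifted(x, s, pv, delta, rmax, lump):
    f = 0.0
    for i in range(x.shape[0]):
        if s[i] <= 4:
            xi = x[i] + delta
            f += pv[KS] * (xi - _state_xmin(s[i], xi, pv, rmax, lump))
    return f


@njit(cache=True)
def _zero_force_shift(x, s, pv, rmax, lump):
    """Displacement delta nulling the total elastic force (root bracketing).

    With the lumped node the effective minimum moves with strain, so the
    force is solved by bisection after expanding a bracket around the
    linear guess (which is exact for explicit kinetics).
    """
    n_att = 0
    strain = 0.0
    for i in range(x.shape[0]):
        if s[i] <= 4:
            n_att += 1
            strain += x[i] - _state_xmin(s[i], x[i], pv, rmax, lump)
    if n_att == 0:
        return 0.0, False
    d0 = -strain / n_att
    f0 = _total_force_shifted(x, s, pv, d0, rmax, lump)
    if f0 == 0.0:
        return d0, True
    # expand a bracket [lo, hi] with F(lo) <= 0 <= F(hi); the total force
    # increases with delta apart from local wiggles of the lumped node
    step = 0.5
    if f0 > 0.0:
        hi = d0
        lo = d0
        while step < 1.0e4:
            lo -= step
            step *= 2.0
            if _total_force_shifted(x, s, pv, lo, rmax, lump) <= 0.0:
                break
    else:
        lo = d0
        hi = d0
        while step < 1.0e4:
            hi += step
            step *= 2.0
            if _total_force_shifted(x, s, pv, hi, rmax, lump) >= 0.0:
                break
    mid = d0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = _total_force_shifted(x, s, pv, mid, rmax, lump)
        if fm < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1.0e-12 or np.abs(fm) < 1.0e-11:
            break
    return mid, True


@njit(cache=True)
def simulate_unloaded(pv, x0, s0, t_end, rec_times, wrap_lo, rmax,
                      refresh_dx, lump, seed):
    """Unloaded-shortening run: after every event the filament is
    repositioned so the total cross-bridge force is exactly zero.

    Head propensities are refreshed for all heads whenever the filament has
    moved more than ``refresh_dx`` nm since the last full refresh (between
    refreshes only the head that fired is updated); with the default
    0.05 nm this approximation changes individual rates by well under a
    percent.

    Returns (X[R], force[R], counts[R, 7], atp_events[R]).
    """
    np.random.seed(seed)
    N = x0.shape[0]
    R = rec_times.shape[0]
    x = x0.copy()
    s = s0.copy()
    rates = np.zeros((N, 2))
    targets = np.zeros((N, 2), dtype=np.int64)
    for i in range(N):
        r0, tg0, r1, tg1 = head_rates(s[i], x[i], pv, rmax, lump)
        rates[i, 0] = r0
        rates[i, 1] = r1
        targets[i, 0] = tg0
        targets[i, 1] = tg1
    A = rates.sum()
    X = 0.0
    X_ref = 0.0
    t = 0.0
    rec = 0
    Xrec = np.zeros(R)
    force = np.zeros(R)
    counts = np.zeros((R, 7))
    atp = np.zeros(R)
    while t < t_end:
        dt = -np.log(np.random.random()) / A
        t_new = t + dt
        while rec < R and rec_times[rec] <= t_new + 1e-15:
            Xrec[rec] = X
            force[rec] = _total_force_shifted(x, s, pv, 0.0, rmax, lump)
            for i in range(N):
                _add_counts(counts, rec, s[i], x[i], pv, rmax, lump)
            rec += 1
        t = t_new
        if t >= t_end:
            break
        # select head and transition by propensity
        u = np.random.random() * A
        cum = 0.0
        i_sel = N - 1
        k_sel = 0
        for i in range(N):
            cum += rates[i, 0]
            if u < cum:
                i_sel = i
                k_sel = 0
                break
            cum += rates[i, 1]
            if u < cum:
                i_sel = i
                k_sel = 1
                break
        s_old = s[i_sel]
        s_new = targets[i_sel, k_sel]
        if s_old == 4 and s_new == 5 and rec < R:
            atp[rec] += 1.0
        s[i_sel] = s_new
        # reposition the filament to zero total force
        delta, ok = _zero_force_shift(x, s, pv, rmax, lump)
        if ok:
            for i in range(N):
                x[i] += delta
                if s[i] >= 5:
                    x[i] = _wrap(x[i], wrap_lo)
            X += delta
        # refresh propensities
        if np.abs(X - X_ref) > refresh_dx or not ok:
            for i in range(N):
                r0, tg0, r1, tg1 = head_rates(s[i], x[i], pv, rmax, lump)
                rates[i, 0] = r0
                rates[i, 1] = r1
                targets[i, 0] = tg0
                targets[i, 1] = tg1
            A = rates.sum()
            X_ref = X
        else:
            r0, tg0, r1, tg1 = head_rates(s[i_sel], x[i_sel], pv, rmax, lump)
            A += r0 + r1 - rates[i_sel, 0] - rates[i_sel, 1]
            rates[i_sel, 0] = r0
            rates[i_sel, 1] = r1
            targets[i_sel, 0] = tg0
            targets[i_sel, 1] = tg1
    return Xrec, force, counts, atp
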