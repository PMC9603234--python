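"""Strain-dependent transition rates and free-energy diagrams.

Each attached state j sits in a harmonic free-energy well
``G_j(x) = G_j^min + k_s (x - x_j)^2 / (2 kBT)`` centred on its minimum
position x_j; the detached states are strain-independent.  Forward and
reverse rates of every reversible step obey detailed balance against these
diagrams: ``log(k_fwd / k_rev) = G_from(x) - G_to(x)``.

Two literal-form toggles are provided (``pir_as_printed`` and
``powerstroke_x1``) that reproduce published variants of the Pi-release-entry
reverse rate and of the power-stroke forward rate in which detailed balance
does not hold exactly; they exist to demonstrate the discrepancy and are
never used by the solvers.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ModelParameters
from .states import State

__all__ = [
    "free_energy",
    "state_minimum_position",
    "rate_on",
    "rate_on_rev",
    "rate_pir",
    "rate_pi_release",
    "rate_powerstroke",
    "rate_second_stroke",
    "rate_detach",
    "rate_hydrolysis",
    "clamp_rate",
    "rate_matrix",
]


def state_minimum_position(state: State, p: ModelParameters) -> float:
    """Strain-axis position of the free-energy minimum of an attached state."""
    positions = {
        State.AMDP_PP: p.x1,
        State.AMDP_PIR: p.x11,
        State.AMD_L: p.x11,
        State.AMD_H: p.x2,
        State.AM_AMD: p.x3,
    }
    try:
        return positions[state]
    except KeyError:
        raise ValueError(f"{state!r} is detached and has no minimum position")


def _minimum_levels(p: ModelParameters) -> dict[State, float]:
    """Free-energy minimum level of each state, kBT, with MDP as reference 0.

    Successive attached minima drop by dG_on, dG_PiR, ln(KC/[Pi]), dG_LH and
    dG_HD along the cycle.  MT lies ln(K3) above MDP so that the hydrolysis
    equilibrium K3 = k+3/k-3 is honoured.
    """
    g_pp = -p.dG_on
    g_pir = g_pp - p.dG_PiR
    # Pi release: forward kP+, reverse kP+ [Pi]/KC -> drop ln(KC/[Pi]).
    if p.pi > 0:
        g_l = g_pir - math.log(p.KC / p.pi)
    else:
        g_l = -math.inf
    g_h = g_l - p.dG_LH
    g_am = g_h - p.dG_HD
    return {
        State.MDP: 0.0,
        State.MT: math.log(p.K3),
        State.AMDP_PP: g_pp,
        State.AMDP_PIR: g_pir,
        State.AMD_L: g_l,
        State.AMD_H: g_h,
        State.AM_AMD: g_am,
    }


def free_energy(state: State, x: float, p: ModelParameters) -> float:
    """Free energy of a state at strain-axis position x, in kBT.

    Detached states are flat; attached states add the harmonic strain term
    to their cumulative minimum level.  For the rigor-like AM/AMD state the
    parabola is the integral of the (linear) elastic force from x3 to x.
    """
    g = _minimum_levels(p)[State(state)]
    if State(state).attached:
        xj = state_minimum_position(State(state), p)
        g += p.k_s * (x - xj) ** 2 / (2.0 * p.kBT)
    return g


# ---------------------------------------------------------------------------
# individual rate functions (uncapped; capping is applied separately)
# ---------------------------------------------------------------------------

def rate_on(x, p: ModelParameters):
    """MDP -> AMDP_PP attachment rate, s^-1."""
    x = np.asarray(x, dtype=float)
    return p.kon_prime * np.exp(p.dG_on - p.k_s * (x - p.x1) ** 2 / (4.0 * p.kBT))


def rate_on_rev(x, p: ModelParameters):
    """AMDP_PP -> MDP detachment (reversal of attachment), s^-1."""
    x = np.asarray(x, dtype=float)
    return p.kon_prime * np.exp(p.k_s * (x - p.x1) ** 2 / (4.0 * p.kBT))


def rate_pir(x, p: ModelParameters, direction: str = "forward",
             as_printed: bool = False):
    """AMDP_PP <-> AMDP_PiR transition rates, s^-1.

    The strain terms use half the cross-bridge stiffness (transition state
    midway along the reaction coordinate).  The reverse rate carries
    -dG_PiR/2 so that forward/reverse satisfies detailed balance; with
    ``as_printed=True`` the reverse keeps +dG_PiR/2, a documented pathology
    in which the equilibrium constant of the step loses its dG_PiR
    dependence.
    """
    x = np.asarray(x, dtype=float)
    strain = (p.k_s / 2.0) * ((x - p.x11) ** 2 - (x - p.x1) ** 2) / (2.0 * p.kBT)
    if direction == "forward":
        return p.kPr_prime * np.exp(p.dG_PiR / 2.0 - strain)
    if direction == "reverse":
        sign = +1.0 if as_printed else -1.0
        return p.kPr_prime * np.exp(sign * p.dG_PiR / 2.0 + strain)
    raise ValueError(f"unknown direction {direction!r}")


def rate_pi_release(p: ModelParameters, direction: str = "forward") -> float:
    """AMDP_PiR <-> AMD_L (Pi release), strain-insensitive, s^-1."""
    if p.pi < 0:
        raise ValueError("[Pi] must be non-negative")
    if direction == "forward":
        return p.kP_plus
    if direction == "reverse":
        return p.kP_plus * p.pi / p.KC
    raise ValueError(f"unknown direction {direction!r}")


def rate_powerstroke(x, p: ModelParameters, direction: str = "forward",
                     use_x1: bool = False):
    """AMD_L <-> AMD_H (main power stroke), s^-1.

    The reverse rate is the constant kLH_minus; the forward rate follows
    from detailed balance between the AMD_L well (centred on x11) and the
    AMD_H well (centred on x2).  ``use_x1=True`` centres the AMD_L well on
    x1 instead, the literal published variant (identical whenever x1 = x11).
    """
    x = np.asarray(x, dtype=float)
    if direction == "reverse":
        return p.kLH_minus * np.ones_like(x) if x.ndim else p.kLH_minus
    if direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    x_l = p.x1 if use_x1 else p.x11
    gap = p.dG_LH + p.k_s * ((x - x_l) ** 2 - (x - p.x2) ** 2) / (2.0 * p.kBT)
    return p.kLH_minus * np.exp(gap)


def rate_second_stroke(x, p: ModelParameters, direction: str = "forward"):
    """AMD_H <-> AM/AMD (second sub-stroke, before ADP release), s^-1.

    Reverse rate constant k5_minus; forward rate by detailed balance between
    the AMD_H well (x2) and the rigor parabola centred on x3.
    """
    x = np.asarray(x, dtype=float)
    if direction == "reverse":
        return p.k5_minus * np.ones_like(x) if x.ndim else p.k5_minus
    if direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    gap = p.dG_HD + p.k_s * ((x - p.x2) ** 2 - (x - p.x3) ** 2) / (2.0 * p.kBT)
    return p.k5_minus * np.exp(gap)


def rate_detach(x, p: ModelParameters):
    """AM/AMD -> MT ATP-induced detachment rate, s^-1.

    k2(x) grows exponentially with |rigor strain| times x_crit; the overall
    rate saturates hyperbolically in [MgATP].
    """
    if p.mgatp < 0:
        raise ValueError("[MgATP] must be non-negative")
    x = np.asarray(x, dtype=float)
    k2 = p.k2_zero * np.exp(p.k_s * np.abs(x - p.x3) * p.x_crit / p.kBT)
    T = p.mgatp
    return k2 * T / (1.0 / p.K1 + (1.0 + k2 / p.k6) * T)


def rate_hydrolysis(p: ModelParameters, direction: str = "forward") -> float:
    """MT <-> MDP recovery stroke + hydrolysis, x-independent, s^-1."""
    if direction == "forward":
        return p.k3_plus
    if direction == "reverse":
        return p.k3_minus
    raise ValueError(f"unknown direction {direction!r}")


def clamp_rate(r, mode: str, p: ModelParameters):
    """Clamp a rate into [r_min, r_max(mode)] for numerical stability."""
    return np.clip(r, p.r_min, p.r_max(mode))


# ---------------------------------------------------------------------------
# generator assembly
# ---------------------------------------------------------------------------

# (from_state, to_state, rate callable) for the 6 reversible pairs + 1
# irreversible step of the cycle.  Indices are 0-based (state j -> j-1).
def _transition_rates(x: float, p: ModelParameters) -> list[tuple[int, int, float]]:
    s = State
    entries = [
        (s.MDP, s.AMDP_PP, float(rate_on(x, p))),
        (s.AMDP_PP, s.MDP, float(rate_on_rev(x, p))),
        (s.AMDP_PP, s.AMDP_PIR, float(rate_pir(x, p, "forward"))),
        (s.AMDP_PIR, s.AMDP_PP, float(rate_pir(x, p, "reverse"))),
        (s.AMDP_PIR, s.AMD_L, rate_pi_release(p, "forward")),
        (s.AMD_L, s.AMDP_PIR, rate_pi_release(p, "reverse")),
        (s.AMD_L, s.AMD_H, float(rate_powerstroke(x, p, "forward"))),
        (s.AMD_H, s.AMD_L, float(rate_powerstroke(x, p, "reverse"))),
        (s.AMD_H, s.AM_AMD, float(rate_second_stroke(x, p, "forward"))),
        (s.AM_AMD, s.AMD_H, float(rate_second_stroke(x, p, "reverse"))),
        (s.AM_AMD, s.MT, float(rate_detach(x, p))),  # irreversible ([MgADP] = 0)
        (s.MT, s.MDP, rate_hydrolysis(p, "forward")),
        (s.MDP, s.MT, rate_hydrolysis(p, "reverse")),
    ]
    return [(int(a) - 1, int(b) - 1, r) for a, b, r in entries]


def rate_matrix(x: float, p: ModelParameters, mode: str = "iso") -> np.ndarray:
    """7x7 generator of the cycle at strain offset x (rates clamped).

    Entry [j, k] for j != k is the rate of the j -> k transition; each row
    sums to zero.  For a probability column vector q the master equation
    therefore reads dq/dt = Q.T q.
    """
    Q = np.zeros((7, 7))
    for frm, to, r in _transition_rates(x, p):
        Q[frm, to] += float(clamp_rate(r, mode, p))
    Q[np.diag_indices(7)] -= Q.sum(axis=1)
    return Q
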