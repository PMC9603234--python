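"""Biochemical states of the actomyosin ATPase cycle.

The cycle is coarse-grained to seven states.  Five of them are
actin-attached (pre-power-stroke AMDP_PP, Pi-release AMDP_PiR, the low- and
high-force AMD states flanking the main power stroke, and the lumped
rigor-like AM/AMD state); two are detached (MT after ATP-induced
detachment, MDP after the recovery stroke and hydrolysis).  The weakly
bound AMDP state carries no free-energy drop relative to MDP and is lumped
with it, so it does not appear as a separate index.
"""

from __future__ import annotations

from enum import IntEnum


class State(IntEnum):
    """Cycle states, indexed 1..7 as in the master-equation formulation."""

    AMDP_PP = 1   # pre-power-stroke, strongly attached
    AMDP_PIR = 2  # Pi-release state
    AMD_L = 3     # low-force AMD, before the main power stroke
    AMD_H = 4     # high-force AMD, after the main power stroke
    AM_AMD = 5    # lumped rigor/ADP state (open nucleotide pocket)
    MT = 6        # detached, ATP bound
    MDP = 7       # detached, hydrolysis products bound

    @property
    def attached(self) -> bool:
        return self.value <= 5


#: States bound to actin (exert elastic force).
ATTACHED_STATES = tuple(s for s in State if s.attached)

#: Detached states (zero force).
DETACHED_STATES = (State.MT, State.MDP)

N_STATES = 7
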