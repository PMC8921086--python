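"""The five health states of the Markov cohort model."""

from __future__ import annotations

from enum import IntEnum

__all__ = ["StateId", "NONRES", "RES_NED", "RES_LOC", "RES_MET", "DEAD",
           "N_STATES", "STATE_NAMES"]


class StateId(IntEnum):
    """Health states after initial staging of pancreatic cancer.

    NONRES  — alive, non-resectable (metastatic disease, no surgery)
    RES_NED — alive, resected, no metastasis or local recurrence
    RES_LOC — alive, resected, R1 situation or local recurrence
    RES_MET — alive, resected, metastases present
    DEAD    — dead (absorbing)
    """

    NONRES = 0
    RES_NED = 1
    RES_LOC = 2
    RES_MET = 3
    DEAD = 4


NONRES = StateId.NONRES
RES_NED = StateId.RES_NED
RES_LOC = StateId.RES_LOC
RES_MET = StateId.RES_MET
DEAD = StateId.DEAD

N_STATES = len(StateId)
STATE_NAMES = [s.name for s in StateId]
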