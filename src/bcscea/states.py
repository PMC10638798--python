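"""Health states and surgical strategies of the six-state cohort model.

The model tracks a cohort of in situ breast cancer patients after their
first (successful) surgery through six mutually exclusive health states:

=====  ============================  =========================================
code   name                          meaning
=====  ============================  =========================================
A      cancer_free                   disease-free after the initial surgery
B      locoregional_recurrence       ipsilateral local/regional recurrence
C      remission_after_recurrence    stable remission following a recurrence
D      metastasis                    distant / contralateral disease
E      remission_after_metastasis    stable remission following metastasis
F      death                         absorbing
=====  ============================  =========================================

Remission states are one-way: patients in C or E never revert to A, and
repeated recurrences are modelled as continued occupancy of B (or D).
"""

from __future__ import annotations

import enum


class HealthState(enum.Enum):
    """One of the six Markov health states, ordered A..F."""

    CANCER_FREE = "A"
    LOCOREGIONAL_RECURRENCE = "B"
    REMISSION_AFTER_RECURRENCE = "C"
    METASTASIS = "D"
    REMISSION_AFTER_METASTASIS = "E"
    DEATH = "F"

    @property
    def index(self) -> int:
        """Position of the state in occupancy vectors / matrix rows (A=0 .. F=5)."""
        return _STATE_ORDER.index(self)

    @property
    def is_absorbing(self) -> bool:
        return self is HealthState.DEATH


_STATE_ORDER = list(HealthState)

#: Number of health states.
N_STATES = len(_STATE_ORDER)

#: Allowed (from, to) arcs of the model graph, excluding self-loops which are
#: always permitted.  Anything else is a structural zero of the transition
#: matrix.
ALLOWED_TRANSITIONS = frozenset(
    {
        ("A", "B"),
        ("A", "D"),
        ("A", "F"),
        ("B", "C"),
        ("B", "F"),
        ("C", "D"),
        ("C", "F"),
        ("D", "E"),
        ("D", "F"),
        ("E", "F"),
    }
)


class Strategy(enum.Enum):
    """The three surgical comparators."""

    MASTECTOMY = "mastectomy"
    LUMPECTOMY_NO_RT = "lumpectomy_no_rt"
    LUMPECTOMY_RT = "lumpectomy_rt"

    @property
    def is_lumpectomy(self) -> bool:
        return self in (Strategy.LUMPECTOMY_NO_RT, Strategy.LUMPECTOMY_RT)

    @property
    def label(self) -> str:
        return {
            Strategy.MASTECTOMY: "Mastectomy",
            Strategy.LUMPECTOMY_NO_RT: "Lumpectomy without irradiation",
            Strategy.LUMPECTOMY_RT: "Lumpectomy with irradiation",
        }[self]
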