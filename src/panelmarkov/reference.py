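"""Published reference estimates for the three-state postpartum-depression model.

These constants are the printed summary statistics of the cohort study this
package emulates (n=304 primiparous women, EPDS assessed at roughly 6, 13 and
26 weeks postpartum). The raw individual-level data are not public, so the
reference intensity matrix is reconstructed from the published embedded-chain
jump probabilities and mean sojourn times; it serves as the default ground
truth for the synthetic-cohort generator and for cross-consistency checks.
"""

from __future__ import annotations

import numpy as np

#: Weeks per month used when converting follow-up horizons (1 year = 52 weeks).
WEEKS_PER_MONTH = 52.0 / 12.0

#: Observed consecutive-visit transition counts (rows: from-state, cols:
#: to-state, states ordered normal < mild < severe). 608 pairs in total.
OBSERVED_TRANSITION_COUNTS = np.array(
    [
        [155, 9, 10],
        [88, 33, 19],
        [63, 92, 139],
    ],
    dtype=int,
)

#: Published next-state (embedded jump chain) probabilities; diagonal is
#: undefined for a jump chain and stored as 0.
PUBLISHED_JUMP_PROBABILITIES = np.array(
    [
        [0.0, 0.498, 0.502],
        [0.800, 0.0, 0.200],
        [0.064, 0.936, 0.0],
    ]
)

#: Published mean sojourn times per state, in weeks.
PUBLISHED_SOJOURN_WEEKS = np.array([64.12, 6.29, 9.37])

#: Deterministic split of OBSERVED_TRANSITION_COUNTS into the first
#: (6-week -> 3-month) and second (3-month -> 6-month) inter-visit intervals.
#: The published table aggregates both intervals; any split A + B = counts
#: with column-sums(A) == row-sums(B) yields a valid 304-subject panel. This
#: particular split is the integer solution closest (L1) to an even split,
#: frozen here so the fixture cohort is reproducible byte-for-byte.
FIRST_INTERVAL_COUNTS = np.array(
    [
        [45, 4, 5],
        [44, 17, 10],
        [31, 48, 100],
    ],
    dtype=int,
)

SECOND_INTERVAL_COUNTS = OBSERVED_TRANSITION_COUNTS - FIRST_INTERVAL_COUNTS

#: Cohort covariates: name -> (mean, sd, lower bound, upper bound) as
#: published for the study sample. Support subscales are 5-item Likert
#: totals bounded at 0-15; maternal age is bounded below at 18 (inclusion
#: criterion).
COVARIATE_DISTRIBUTIONS = {
    "age": (24.8, 2.89, 18.0, np.inf),
    "emotional_support": (10.2, 2.72, 0.0, 15.0),
    "material_support": (9.9, 3.43, 0.0, 15.0),
    "informational_support": (6.8, 3.14, 0.0, 15.0),
    "evaluation_support": (8.4, 2.92, 0.0, 15.0),
}

#: Nominal visit schedule, weeks postpartum.
VISIT_SCHEDULE_WEEKS = (6.0, 13.0, 26.0)

#: Follow-up horizons of the published interval-probability table.
INTERVAL_HORIZONS = ("1m", "3m", "6m", "9m", "1y", "2y", "3y")


def horizon_to_weeks(token: str) -> float:
    """Convert a horizon token like ``"3m"`` or ``"2y"`` to weeks.

    Months convert at 52/12 weeks per month, years at 52 weeks.
    """
    token = token.strip().lower()
    if not token or token[-1] not in "my":
        raise ValueError(f"horizon token must end in 'm' or 'y': {token!r}")
    try:
        amount = float(token[:-1])
    except ValueError as exc:
        raise ValueError(f"unparseable horizon token: {token!r}") from exc
    if amount <= 0:
        raise ValueError(f"horizon must be positive: {token!r}")
    return amount * (WEEKS_PER_MONTH if token[-1] == "m" else 52.0)


def reference_intensity_matrix():
    """Intensity matrix reconstructed from the published jump/sojourn table."""
    from .markov import (
        SojournTimes,
        TransitionTable,
        reconstruct_intensity,
    )

    jump = TransitionTable(PUBLISHED_JUMP_PROBABILITIES, kind="probabilities", jump=True)
    sojourn = SojournTimes(PUBLISHED_SOJOURN_WEEKS)
    return reconstruct_intensity(jump, sojourn)
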