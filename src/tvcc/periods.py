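"""Time-period grids, control-eligibility rules and period expansion.

The period-wise logistic analysis estimates a separate exposure log odds
ratio within L consecutive half-open time periods ``[tau_lA, tau_lB)``.
Cases belong to the single period containing their index time.  Controls may
be *reused*: one control can contribute a record to every period in which it
is eligible, under one of four printed eligibility definitions that differ
in how the control's entry time T_E and index time T_I are compared with the
period limits:

====  =================  =================
def   entry condition    index condition
====  =================  =================
i     T_E <  tau_lB      T_I >= tau_lA
ii    T_E <  tau_lB      T_I >  tau_lB
iii   T_E <= tau_lA      T_I >= tau_lA
iv    T_E <= tau_lA      T_I >  tau_lB
====  =================  =================

Definition (i) is the recommended one: a control interviewed at age 14 on a
5-year grid serves in the 0-4, 5-9 and 10-14 periods.  The strict/non-strict
distinctions are implemented exactly as printed — they are the experimental
contrast of the study, not an implementation detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import covariate_columns, validate_subjects
from .errors import ConfigurationError, PeriodAssignmentError

__all__ = [
    "PeriodGrid",
    "CONTROL_DEFINITIONS",
    "control_eligible",
    "control_eligibility_matrix",
    "expand_to_periods",
]

logger = logging.getLogger(__name__)

#: The four control-eligibility definitions, in increasing stringency order
#: (iv implies ii and iii, each of which implies i).
CONTROL_DEFINITIONS = ("i", "ii", "iii", "iv")


@dataclass(frozen=True)
class PeriodGrid:
    """L consecutive half-open time periods ``[tau_lA, tau_lB)``.

    Parameters
    ----------
    boundaries
        Strictly increasing sequence of L+1 times.  Period ``l`` (0-based in
        code) is ``[boundaries[l], boundaries[l+1])``; the periods partition
        ``[boundaries[0], boundaries[-1])``.
    """

    boundaries: tuple[float, ...]

    def __init__(self, boundaries):
        b = tuple(float(x) for x in boundaries)
        if len(b) < 2:
            raise ConfigurationError("a period grid needs at least 2 boundaries")
        if not all(x < y for x, y in zip(b, b[1:])):
            raise ConfigurationError(f"grid boundaries must be strictly increasing: {b}")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_periods(self) -> int:
        return len(self.boundaries) - 1

    @property
    def lower(self) -> np.ndarray:
        """Lower limits tau_lA, shape (L,)."""
        return np.asarray(self.boundaries[:-1])

    @property
    def upper(self) -> np.ndarray:
        """Upper limits tau_lB, shape (L,)."""
        return np.asarray(self.boundaries[1:])

    def label(self, period: int) -> str:
        return f"[{self.boundaries[period]:g},{self.boundaries[period + 1]:g})"

    @property
    def labels(self) -> list[str]:
        return [self.label(l) for l in range(self.n_periods)]

    def assign(self, times, ids=None):
        """Map times to 0-based period indices.

        Each time ``t`` with ``boundaries[0] <= t < boundaries[-1]`` maps to
        the unique period with ``tau_lA <= t < tau_lB``.  Scalar in, scalar
        out; array in, array out.

        Raises
        ------
        PeriodAssignmentError
            If any time lies outside the grid; the message names the
            offending time (and subject, when ``ids`` is given).
        """
        t = np.asarray(times, dtype=float)
        scalar = t.ndim == 0
        t1 = np.atleast_1d(t)
        idx = np.searchsorted(self.boundaries, t1, side="right") - 1
        bad = (t1 < self.boundaries[0]) | (t1 >= self.boundaries[-1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            who = f" (subject {np.atleast_1d(ids)[i]!r})" if ids is not None else ""
            raise PeriodAssignmentError(
                f"time {t1[i]:g}{who} lies outside the period grid "
                f"[{self.boundaries[0]:g}, {self.boundaries[-1]:g})"
            )
        return int(idx[0]) if scalar else idx


def _eligibility(entry, index, grid: PeriodGrid, definition: str):
    """Vectorised eligibility: (n, L) boolean matrix for controls."""
    t_e = np.atleast_1d(np.asarray(entry, dtype=float))[:, None]
    t_i = np.atleast_1d(np.asarray(index, dtype=float))[:, None]
    lo, hi = grid.lower[None, :], grid.upper[None, :]
    if definition == "i":
        return (t_e < hi) & (t_i >= lo)
    if definition == "ii":
        return (t_e < hi) & (t_i > hi)
    if definition == "iii":
        return (t_e <= lo) & (t_i >= lo)
    if definition == "iv":
        return (t_e <= lo) & (t_i > hi)
    raise ConfigurationError(
        f"unknown control definition {definition!r}; expected one of {CONTROL_DEFINITIONS}"
    )


def control_eligibility_matrix(subjects: pd.DataFrame, grid: PeriodGrid, definition: str):
    """Boolean (n_subjects, L) eligibility matrix for a table of controls."""
    if subjects["is_case"].any():
        raise ConfigurationError("eligibility is defined for controls only; cases present")
    return _eligibility(subjects["entry_time"], subjects["index_time"], grid, definition)


def control_eligible(subject, period: int, grid: PeriodGrid, definition: str) -> bool:
    """Whether a control may serve as a control in ``period`` under the given
    definition.

    ``subject`` is any mapping with ``is_case``, ``entry_time`` and
    ``index_time`` entries (e.g. a DataFrame row).  Cases never serve as
    controls, in any period.
    """
    if int(subject["is_case"]) != 0:
        raise ConfigurationError("cases never serve as controls")
    if not 0 <= period < grid.n_periods:
        raise ConfigurationError(f"period {period} outside grid with {grid.n_periods} periods")
    m = _eligibility(subject["entry_time"], subject["index_time"], grid, definition)
    return bool(m[0, period])


def _allocate_one_period(elig: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy balanced allocation of controls to a single period each.

    Controls are visited in a seeded random order; each is assigned to the
    eligible period currently holding the fewest controls, ties broken by the
    lowest period index.  Rows with no eligible period get -1.
    """
    n, L = elig.shape
    counts = np.zeros(L, dtype=int)
    chosen = np.full(n, -1, dtype=int)
    for i in rng.permutation(n):
        periods = np.flatnonzero(elig[i])
        if periods.size == 0:
            continue
        pick = periods[np.argmin(counts[periods])]
        chosen[i] = pick
        counts[pick] += 1
    return chosen


def expand_to_periods(
    subjects: pd.DataFrame,
    grid: PeriodGrid,
    definition: str = "i",
    reuse: bool = True,
    allocation_seed: int = 0,
) -> pd.DataFrame:
    """Expand a subject table into period-wise records for logistic analysis.

    Each case yields exactly one record, in the period containing its index
    time, with case indicator ``D = 1``.  With ``reuse=True`` each control
    yields one ``D = 0`` record per eligible period under ``definition``;
    with ``reuse=False`` each control yields a single record in one of its
    definition-(i)-eligible periods, chosen by a seeded greedy balancing
    algorithm that equalises per-period control counts as far as possible.

    Controls eligible in no period are dropped (a warning logs the count).
    The returned frame has columns ``subject_id, period, D, exposure,
    stratum`` plus any covariate columns, and carries the number of dropped
    controls in ``.attrs["n_dropped_controls"]``.
    """
    subjects = validate_subjects(subjects)
    zcols = covariate_columns(subjects)
    keep = ["id", "exposure", "stratum"] + zcols

    cases = subjects[subjects["is_case"] == 1]
    controls = subjects[subjects["is_case"] == 0]

    case_rec = cases[keep].rename(columns={"id": "subject_id"}).reset_index(drop=True)
    case_rec.insert(1, "period", grid.assign(cases["index_time"].to_numpy(), ids=cases["id"].to_numpy()))
    case_rec.insert(2, "D", 1)

    elig = _eligibility(controls["entry_time"], controls["index_time"], grid, definition)
    if reuse:
        rows, periods = np.nonzero(elig)
    else:
        elig_i = _eligibility(controls["entry_time"], controls["index_time"], grid, "i")
        rng = np.random.default_rng(allocation_seed)
        chosen = _allocate_one_period(elig_i, rng)
        rows = np.flatnonzero(chosen >= 0)
        periods = chosen[rows]
    n_dropped = controls.shape[0] - np.unique(rows).size
    if n_dropped:
        logger.warning(
            "%d of %d controls are eligible in no time period under definition %s "
            "and were dropped from the period expansion",
            n_dropped, controls.shape[0], definition if reuse else "i",
        )
    ctrl_rec = controls.iloc[rows][keep].rename(columns={"id": "subject_id"}).reset_index(drop=True)
    ctrl_rec.insert(1, "period", periods)
    ctrl_rec.insert(2, "D", 0)

    records = pd.concat([case_rec, ctrl_rec], ignore_index=True)
    records.attrs["n_dropped_controls"] = int(n_dropped)
    return records
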