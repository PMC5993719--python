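"""Mitotic phase durations from time-lapse event annotations.

Each dividing cell is annotated with the frame of DNA condensation (first
frame where the nucleus looks non-homogeneous), metaphase-plate formation
and anaphase onset (first frame with separated sister chromatids).
Prometaphase is condensation -> plate; metaphase is plate -> anaphase.
Frames are ``frame_interval_min`` minutes apart (default 4, the
acquisition interval).

Censoring: cells already condensing when the recording starts give only a
lower bound on prometaphase; cells whose plate never appears in the movie
give a lower bound from the last observed frame.  Cohort means/SDs cover
fully monitored cells only; the long-prometaphase fraction additionally
counts lower-bound cells whose bound already exceeds the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import EmptyInputError, SpheroidGeomError

__all__ = [
    "MitosisEvent",
    "PhaseDurations",
    "phase_durations",
    "long_prometaphase_fraction",
    "LongPrometaphaseResult",
    "cohort_summary",
    "PhaseSummary",
    "DEFAULT_FRAME_INTERVAL_MIN",
    "DEFAULT_LONG_CUTOFF_MIN",
]

DEFAULT_FRAME_INTERVAL_MIN = 4.0
DEFAULT_LONG_CUTOFF_MIN = 40.0

FLAG_PROMETAPHASE_LOWER_BOUND = "prometaphase-lower-bound"
FLAG_CONDENSATION_CENSORED = "condensation-censored"
FLAG_METAPHASE_MISSING = "metaphase-missing"


@dataclass(frozen=True)
class MitosisEvent:
    """Frame annotations of one dividing cell.

    ``condensation_censored`` marks cells whose condensation predates the
    recording (the starred cells in per-cell duration plots);
    ``last_observed_frame`` is the final frame of the movie for this cell,
    needed to bound prometaphase when the plate was never seen.
    """

    cell_id: str
    condensation_frame: int | None = None
    metaphase_frame: int | None = None
    anaphase_frame: int | None = None
    condensation_censored: bool = False
    last_observed_frame: int | None = None
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise SpheroidGeomError("frame_interval_min must be positive")
        c, m, a = self.condensation_frame, self.metaphase_frame, self.anaphase_frame
        if c is not None and m is not None and m < c:
            raise SpheroidGeomError("metaphase before condensation")
        if m is not None and a is not None and a < m:
            raise SpheroidGeomError("anaphase before metaphase")
        if c is not None and a is not None and a < c:
            raise SpheroidGeomError("anaphase before condensation")


@dataclass(frozen=True)
class PhaseDurations:
    """Per-cell prometaphase/metaphase durations (minutes) with flags.

    ``prometaphase_min`` is a lower bound rather than an observation when
    ``prometaphase-lower-bound`` is in ``flags``; either duration may be
    ``None`` when the defining frames are absent.
    """

    cell_id: str
    prometaphase_min: float | None
    metaphase_min: float | None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def prometaphase_observed(self) -> bool:
        return (
            self.prometaphase_min is not None
            and FLAG_PROMETAPHASE_LOWER_BOUND not in self.flags
        )

    @property
    def metaphase_observed(self) -> bool:
        return self.metaphase_min is not None


def phase_durations(e: MitosisEvent) -> PhaseDurations:
    """Convert one event record to phase durations in minutes.

    prometaphase = (metaphase - condensation) x interval,
    metaphase duration = (anaphase - metaphase) x interval.  A censored
    condensation, or a missing plate (lower bound from the last observed
    frame), turns prometaphase into a flagged lower bound.
    """
    dt = e.frame_interval_min
    flags: set[str] = set()
    prometa: float | None = None
    meta: float | None = None

    if e.metaphase_frame is not None:
        if e.condensation_frame is not None:
            prometa = (e.metaphase_frame - e.condensation_frame) * dt
            if e.condensation_censored:
                flags |= {FLAG_CONDENSATION_CENSORED, FLAG_PROMETAPHASE_LOWER_BOUND}
        if e.anaphase_frame is not None:
            meta = (e.anaphase_frame - e.metaphase_frame) * dt
    else:
        flags.add(FLAG_METAPHASE_MISSING)
        if e.condensation_frame is not None and e.last_observed_frame is not None:
            if e.last_observed_frame < e.condensation_frame:
                raise SpheroidGeomError("last observed frame before condensation")
            prometa = (e.last_observed_frame - e.condensation_frame) * dt
            flags.add(FLAG_PROMETAPHASE_LOWER_BOUND)
            if e.condensation_censored:
                flags.add(FLAG_CONDENSATION_CENSORED)
    return PhaseDurations(
        cell_id=e.cell_id,
        prometaphase_min=prometa,
        metaphase_min=meta,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class LongPrometaphaseResult:
    """Fraction of mitotic cells with prometaphase above the cutoff.

    ``fraction`` uses determinate cells as denominator: cells with an
    observed duration plus lower-bound cells whose bound already exceeds
    the cutoff (their status is known even though the duration is not).
    Lower-bound cells at or below the cutoff are indeterminate and counted
    separately.  ``fraction_all_cells`` divides by every cell instead,
    treating indeterminate cells as not-long (the most conservative
    denominator choice).
    """

    fraction: float
    n_long: int
    n_determinate: int
    n_indeterminate: int

    @property
    def fraction_all_cells(self) -> float:
        total = self.n_determinate + self.n_indeterminate
        return self.n_long / total if total else math.nan


def long_prometaphase_fraction(
    events: Iterable[MitosisEvent | PhaseDurations],
    cutoff_min: float = DEFAULT_LONG_CUTOFF_MIN,
) -> LongPrometaphaseResult:
    """Share of cells whose prometaphase exceeds ``cutoff_min`` minutes."""
    durations = [
        d if isinstance(d, PhaseDurations) else phase_durations(d) for d in events
    ]
    durations = [d for d in durations if d.prometaphase_min is not None]
    if not durations:
        raise EmptyInputError("no events with a prometaphase duration or bound")
    n_long = n_det = n_indet = 0
    for d in durations:
        if d.prometaphase_observed:
            n_det += 1
            if d.prometaphase_min > cutoff_min:
                n_long += 1
        elif d.prometaphase_min > cutoff_min:  # lower bound already long
            n_det += 1
            n_long += 1
        else:  # bound below cutoff: could be long or not
            n_indet += 1
    return LongPrometaphaseResult(
        fraction=n_long / n_det if n_det else math.nan,
        n_long=n_long,
        n_determinate=n_det,
        n_indeterminate=n_indet,
    )


@dataclass(frozen=True)
class PhaseSummary:
    """mean/SD/median/n of one phase over fully monitored cells."""

    n: int
    mean_min: float
    sd_min: float | None  # sample SD; None when n < 2
    median_min: float


def cohort_summary(
    events: Iterable[MitosisEvent | PhaseDurations],
) -> dict[str, PhaseSummary]:
    """Cohort statistics per phase, censored durations excluded.

    Returns ``{"prometaphase": PhaseSummary, "metaphase": PhaseSummary}``;
    a phase with no fully monitored cell is absent from the dict.
    """
    durations = [
        d if isinstance(d, PhaseDurations) else phase_durations(d) for d in events
    ]
    if not durations:
        raise EmptyInputError("no events to summarise")
    out: dict[str, PhaseSummary] = {}
    pro = [d.prometaphase_min for d in durations if d.prometaphase_observed]
    met = [d.metaphase_min for d in durations if d.metaphase_observed]
    for name, values in (("prometaphase", pro), ("metaphase", met)):
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        out[name] = PhaseSummary(
            n=len(arr),
            mean_min=float(arr.mean()),
            sd_min=float(arr.std(ddof=1)) if len(arr) > 1 else None,
            median_min=float(np.median(arr)),
        )
    return out
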