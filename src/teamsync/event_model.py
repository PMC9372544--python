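"""Domain types and CSV I/O for possession-level match events and Stroop trials.

The atomic unit of the small-sided soccer analysis is one *ball possession*:
an uninterrupted spell of one team's ball control during a 10-minute third,
annotated with the number of completed passes, the number of ball contacts
and whether the possession ended in a goal.  Per (match, team, condition)
these are aggregated into a :class:`ThirdSummary`, which carries everything
the downstream connectivity and scoring statistics need: total passes
``n_p``, total contacts ``n_c``, goals, and ``N0`` — the number of
possessions without any pass, an indicator of team segregation.

Two CSV dialects are defined (UTF-8, ``.`` decimal separator, mandatory
header row); machine-readable schema files ship under
``teamsync/schemas/``:

* possession table: ``match_id,team_id,condition,order_index,n_passes,
  n_contacts,goal`` with ``condition`` in ``{wR, Sy, nS}`` and ``goal``
  in ``{0, 1}``;
* Stroop trial table: ``participant_id,gender,phase,tempo_bpm,block,run,
  congruent,rt_s`` where ``tempo_bpm`` is empty outside the music block.

Structural invariants are enforced on read and on record construction:
every possession has at least one contact, and a pass count never exceeds
the contact count (every pass is initiated by a contact; one-touch play,
where the reception simultaneously is the pass, makes equality legal).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import Union

import pandas as pd

from .errors import SchemaError, ValidationError

#: Experimental conditions: without rhythmic stimulation, synchronous
#: rhythm (140 bpm for every player), non-synchronous rhythm (one tempo
#: per player).
CONDITIONS = ("wR", "Sy", "nS")

#: Per-player tempi (beats per minute) of the non-synchronous condition
#: for a 5-player team.
NS_TEMPI = (119, 133, 147, 154, 161)

#: Menstrual-cycle strata of the Stroop analysis; male participants carry
#: ``not_applicable``.
PHASES = ("menstrual", "folicular", "ovulatory", "luteal", "not_applicable")

GENDERS = ("male", "female")

#: Tempi probed in the Stroop experiment (bpm).
STROOP_TEMPI = (100, 140, 180)

STROOP_RUNS = ("neutral", "stroop")

POSSESSION_COLUMNS = (
    "match_id",
    "team_id",
    "condition",
    "order_index",
    "n_passes",
    "n_contacts",
    "goal",
)

STROOP_COLUMNS = (
    "participant_id",
    "gender",
    "phase",
    "tempo_bpm",
    "block",
    "run",
    "congruent",
    "rt_s",
)

#: Length of one third in minutes.
THIRD_MINUTES = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Possession:
    """One team ball possession within a third.

    Parameters
    ----------
    match_id, team_id
        Identifiers; any non-empty string.
    condition
        One of ``wR``, ``Sy``, ``nS``.
    order_index
        Position of the possession within its third (0-based).
    n_passes
        Completed passes during the possession (the possession's
        *pass-sequence length*); ``>= 0``.
    n_contacts
        Ball contacts during the possession; ``>= 1`` and
        ``>= n_passes``.
    goal
        Whether the possession ended with a goal.  Scoring after zero
        passes is legal in the data model.
    """

    match_id: str
    team_id: str
    condition: str
    order_index: int
    n_passes: int
    n_contacts: int
    goal: bool

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.order_index < 0:
            raise ValidationError("order_index must be >= 0")
        if self.n_passes < 0:
            raise ValidationError("n_passes must be >= 0")
        if self.n_contacts < 1:
            raise ValidationError(
                "n_contacts must be >= 1 (a possession implies at least one contact)"
            )
        if self.n_passes > self.n_contacts:
            raise ValidationError(
                f"n_passes ({self.n_passes}) exceeds n_contacts ({self.n_contacts})"
            )


@dataclass(frozen=True)
class ThirdSummary:
    """Aggregate of one (match, team, condition) third.

    ``n_p`` and ``n_c`` are the total pass and contact counts, ``goals``
    the goals scored, and ``N0`` the number of possessions without any
    pass.  A valid experiment table contains exactly one summary per
    (match, team, condition).
    """

    match_id: str
    team_id: str
    condition: str
    n_p: int
    n_c: int
    goals: int
    N0: int
    duration_min: float = THIRD_MINUTES

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if min(self.n_p, self.n_c, self.goals, self.N0) < 0:
            raise ValidationError("counts must be >= 0")
        if self.n_p > self.n_c:
            raise ValidationError("n_p must not exceed n_c")
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be positive")


@dataclass(frozen=True)
class ConditionSchedule:
    """Chronological condition order of one match, from one team's
    perspective, plus the per-player tempo map of its non-synchronous
    third.

    While one team plays its synchronous third the opponent plays its
    non-synchronous one and vice versa; the third without stimulation is
    shared.  Hence each of ``wR``, ``Sy``, ``nS`` occurs exactly once in
    ``thirds`` and the mirrored schedule (``Sy`` and ``nS`` swapped)
    describes the opposing team.
    """

    match_id: str
    thirds: tuple[str, str, str]
    ns_tempi: Mapping[str, int]

    def __post_init__(self) -> None:
        if sorted(self.thirds) != sorted(CONDITIONS):
            raise ValidationError(
                f"schedule {self.thirds} must contain each condition exactly once"
            )
        if len(self.ns_tempi) == 5 and tuple(sorted(self.ns_tempi.values())) != NS_TEMPI:
            raise ValidationError(
                f"nS tempo set for a 5-player team must be {NS_TEMPI}"
            )

    def mirrored(self) -> "ConditionSchedule":
        """Schedule of the opposing team (``Sy`` and ``nS`` swapped)."""
        swap = {"Sy": "nS", "nS": "Sy", "wR": "wR"}
        return dataclasses.replace(
            self, thirds=tuple(swap[c] for c in self.thirds)
        )


@dataclass(frozen=True)
class StroopTrial:
    """A single timed response in the color-word matching Stroop task.

    ``tempo_bpm`` is the tempo of the rhythm playing during the trial and
    is therefore only set in block 2 (the music block); blocks 1 and 3
    are silent.  Each participant hears exactly one tempo.
    """

    participant_id: str
    gender: str
    phase: str
    tempo_bpm: Union[int, None]
    block: int
    run: str
    congruent: bool
    rt: float

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.block not in (1, 2, 3):
            raise ValidationError("block must be 1, 2 or 3")
        if self.run not in STROOP_RUNS:
            raise ValidationError(f"run must be one of {STROOP_RUNS}")
        if self.rt <= 0:
            raise ValidationError("rt must be > 0")
        if self.block == 2:
            if self.tempo_bpm not in STROOP_TEMPI:
                raise ValidationError(
                    f"block-2 trials need a tempo from {STROOP_TEMPI}"
                )
        elif self.tempo_bpm is not None:
            raise ValidationError("tempo is assigned only in block 2")


# ---------------------------------------------------------------------------
# frame conversion helpers
# ---------------------------------------------------------------------------


def possessions_to_frame(possessions) -> pd.DataFrame:
    """Return a possession table as a canonical DataFrame.

    Accepts an iterable of :class:`Possession` or an existing DataFrame
    with the dialect's columns (checked, extra columns dropped).
    """
    if isinstance(possessions, pd.DataFrame):
        missing = [c for c in POSSESSION_COLUMNS if c not in possessions.columns]
        if missing:
            raise SchemaError(f"possession table misses column(s) {missing}")
        return possessions.loc[:, list(POSSESSION_COLUMNS)].reset_index(drop=True)
    records = list(possessions)
    return pd.DataFrame(
        {
            "match_id": [p.match_id for p in records],
            "team_id": [p.team_id for p in records],
            "condition": [p.condition for p in records],
            "order_index": [p.order_index for p in records],
            "n_passes": [p.n_passes for p in records],
            "n_contacts": [p.n_contacts for p in records],
            "goal": [int(p.goal) for p in records],
        },
        columns=list(POSSESSION_COLUMNS),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Third summaries as a DataFrame (pass-through for DataFrames)."""
    if isinstance(summaries, pd.DataFrame):
        return summaries.reset_index(drop=True)
    records = list(summaries)
    return pd.DataFrame(
        {
            "match_id": [s.match_id for s in records],
            "team_id": [s.team_id for s in records],
            "condition": [s.condition for s in records],
            "n_p": [s.n_p for s in records],
            "n_c": [s.n_c for s in records],
            "goals": [s.goals for s in records],
            "N0": [s.N0 for s in records],
            "duration_min": [s.duration_min for s in records],
        }
    )


def stroop_to_frame(trials) -> pd.DataFrame:
    """Return a Stroop trial table as a canonical DataFrame."""
    if isinstance(trials, pd.DataFrame):
        missing = [c for c in STROOP_COLUMNS if c not in trials.columns]
        if missing:
            raise SchemaError(f"Stroop table misses column(s) {missing}")
        return trials.loc[:, list(STROOP_COLUMNS)].reset_index(drop=True)
    records = list(trials)
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in records],
            "gender": [t.gender for t in records],
            "phase": [t.phase for t in records],
            "tempo_bpm": [t.tempo_bpm for t in records],
            "block": [t.block for t in records],
            "run": [t.run for t in records],
            "congruent": [int(t.congruent) for t in records],
            "rt_s": [t.rt for t in records],
        },
        columns=list(STROOP_COLUMNS),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _require_columns(frame: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _int_field(raw: str, field: str, row: int) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: field {field!r} must be an integer, got {raw!r}"
        ) from None


def read_possession_table(path) -> list[Possession]:
    """Read and validate a possession CSV.

    Row order is preserved.  A missing column raises
    :class:`~teamsync.errors.SchemaError` naming the column; an invalid
    record raises :class:`~teamsync.errors.ValidationError` with its row
    number (1-based, excluding the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, POSSESSION_COLUMNS, "possession table")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        goal = _int_field(row.goal, "goal", i)
        if goal not in (0, 1):
            raise ValidationError(f"row {i}: goal must be 0 or 1, got {row.goal!r}")
        try:
            records.append(
                Possession(
                    match_id=row.match_id,
                    team_id=row.team_id,
                    condition=row.condition,
                    order_index=_int_field(row.order_index, "order_index", i),
                    n_passes=_int_field(row.n_passes, "n_passes", i),
                    n_contacts=_int_field(row.n_contacts, "n_contacts", i),
                    goal=bool(goal),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_possession_table(possessions, path) -> None:
    """Write a possession table in canonical form (fixed column order,
    ``\\n`` line endings), such that write-read round-trips are
    byte-identical."""
    frame = possessions_to_frame(possessions)
    frame.to_csv(path, index=False, lineterminator="\n")


def read_stroop_table(path) -> list[StroopTrial]:
    """Read and validate a Stroop trial CSV (same error contract as
    :func:`read_possession_table`)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, STROOP_COLUMNS, "Stroop table")
    records = []
    tempo_of: dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        tempo = None if row.tempo_bpm == "" else _int_field(row.tempo_bpm, "tempo_bpm", i)
        congruent = _int_field(row.congruent, "congruent", i)
        if congruent not in (0, 1):
            raise ValidationError(f"row {i}: congruent must be 0 or 1")
        try:
            rt = float(row.rt_s)
        except ValueError:
            raise ValidationError(
                f"row {i}: rt_s must be a number, got {row.rt_s!r}"
            ) from None
        try:
            trial = StroopTrial(
                participant_id=row.participant_id,
                gender=row.gender,
                phase=row.phase,
                tempo_bpm=tempo,
                block=_int_field(row.block, "block", i),
                run=row.run,
                congruent=bool(congruent),
                rt=rt,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if trial.tempo_bpm is not None:
            known = tempo_of.setdefault(trial.participant_id, trial.tempo_bpm)
            if known != trial.tempo_bpm:
                raise ValidationError(
                    f"row {i}: participant {trial.participant_id!r} has two "
                    f"tempi ({known} and {trial.tempo_bpm}); each participant "
                    "hears exactly one tempo"
                )
        records.append(trial)
    return records


def write_stroop_table(trials, path) -> None:
    """Write a Stroop trial table in canonical form."""
    frame = stroop_to_frame(trials).copy()
    frame["tempo_bpm"] = frame["tempo_bpm"].map(
        lambda t: "" if pd.isna(t) or t is None else str(int(t))
    )
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def summarize_thirds(possessions, duration_min: float = THIRD_MINUTES) -> pd.DataFrame:
    """Aggregate possessions into one row per (match, team, condition).

    Returns a DataFrame with columns ``match_id, team_id, condition,
    n_p, n_c, goals, N0, duration_min`` where ``n_p``/``n_c``/``goals``
    are sums and ``N0`` counts the possessions with zero passes.  The
    operation is additive: summaries of a partition of the possessions
    sum to the summary of the whole.  Empty input yields an empty frame.
    """
    frame = possessions_to_frame(possessions)
    if frame.empty:
        return pd.DataFrame(
            columns=[
                "match_id", "team_id", "condition",
                "n_p", "n_c", "goals", "N0", "duration_min",
            ]
        )
    frame = frame.assign(_no_pass=(frame["n_passes"] == 0).astype(int))
    grouped = (
        frame.groupby(["match_id", "team_id", "condition"], sort=False)
        .agg(
            n_p=("n_passes", "sum"),
            n_c=("n_contacts", "sum"),
            goals=("goal", "sum"),
            N0=("_no_pass", "sum"),
        )
        .reset_index()
    )
    grouped["duration_min"] = duration_min
    return grouped


def third_summaries(possessions, duration_min: float = THIRD_MINUTES) -> list[ThirdSummary]:
    """Like :func:`summarize_thirds` but returning typed records."""
    frame = summarize_thirds(possessions, duration_min)
    return [
        ThirdSummary(
            match_id=r.match_id,
            team_id=r.team_id,
            condition=r.condition,
            n_p=int(r.n_p),
            n_c=int(r.n_c),
            goals=int(r.goals),
            N0=int(r.N0),
            duration_min=float(r.duration_min),
        )
        for r in frame.itertuples(index=False)
    ]


def rate_normalize(summaries, total_minutes: float) -> pd.DataFrame:
    """Convert count columns to per-minute rates.

    Used for the male-vs-female comparison, whose total playing times
    differ (16 vs 14 matches): dividing by the total playing time makes
    the count columns comparable across experiments of different size.
    """
    if total_minutes <= 0:
        raise ValueError("total_minutes must be positive")
    frame = summaries_to_frame(summaries)
    rates = frame.copy()
    for col in ("n_p", "n_c", "goals", "N0"):
        rates[col + "_per_min"] = frame[col] / total_minutes
    return rates
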