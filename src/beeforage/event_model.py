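"""Domain types for bees, treatments, behavioral events, flower visits,
and the event → visit → choice aggregation rules, plus CSV readers/writers.

An event log holds one row per timestamped behavioral activity interval.
Timestamps are integer milliseconds since the start of the foraging trip;
they are converted to seconds only by downstream physiology/energetics.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from beeforage.errors import SchemaError, ValidationError

# Tongue-contact threshold separating tasting from drinking (seconds).
CHOICE_THRESHOLD_S = 2.0
# A return to the same flower within this gap (from the end of the previous
# interaction with it), with no other flower interaction in between, is
# merged into the original visit.
RETURN_MERGE_GAP_S = 10.0


class Phase(str, Enum):
    FAMILIARIZATION = "familiarization"
    TEST = "test"


class Activity(str, Enum):
    FLY = "fly"
    VISIT = "visit"
    DRINK = "drink"
    REST = "rest"
    NEST_OTHER = "nest_other"
    OFFLOAD = "offload"


#: Activities that count as flower interaction (handling).
FLOWER_ACTIVITIES = frozenset({Activity.VISIT, Activity.DRINK})


class LocomotorState(str, Enum):
    LANDED = "landed"
    HOVER = "hover"
    NA = "n/a"


class Orientation(str, Enum):
    VERTICAL = "vertical"
    HORIZONTAL = "horizontal"
    NONE = "none"


class TreatmentName(str, Enum):
    CONTROL = "control"
    LOW_DIFFERENCE = "low_difference"
    HIGH_DIFFERENCE = "high_difference"


@dataclass(frozen=True)
class Bee:
    """A focal worker bee."""

    bee_id: str
    colony_id: str
    treatment: TreatmentName
    unladen_mass: float  # grams

    def __post_init__(self) -> None:
        if self.unladen_mass <= 0:
            raise ValidationError(
                f"bee {self.bee_id}: unladen_mass must be > 0 g, "
                f"got {self.unladen_mass}"
            )
        object.__setattr__(self, "treatment", TreatmentName(self.treatment))


@dataclass(frozen=True)
class Treatment:
    """Sucrose concentrations (% w/w) assigned to each flower orientation."""

    name: TreatmentName
    conc_vertical: float
    conc_horizontal: float
    reward_volume: float = 15.0  # microlitres per flower per trip

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", TreatmentName(self.name))
        for c in (self.conc_vertical, self.conc_horizontal):
            if not 0 < c <= 70:
                raise ValidationError(
                    f"treatment {self.name.value}: concentration {c} outside (0, 70]"
                )
        if self.reward_volume <= 0:
            raise ValidationError("reward_volume must be > 0")
        if (
            self.name is TreatmentName.CONTROL
            and self.conc_vertical != self.conc_horizontal
        ):
            raise ValidationError(
                "control treatment requires equal vertical/horizontal concentrations"
            )

    def concentration(self, orientation: Orientation) -> float:
        if orientation is Orientation.VERTICAL:
            return self.conc_vertical
        if orientation is Orientation.HORIZONTAL:
            return self.conc_horizontal
        raise ValidationError(f"no concentration for orientation {orientation!r}")


#: The three treatments of the experimental design.
STANDARD_TREATMENTS: Mapping[TreatmentName, Treatment] = {
    TreatmentName.CONTROL: Treatment(TreatmentName.CONTROL, 35.0, 35.0),
    TreatmentName.LOW_DIFFERENCE: Treatment(TreatmentName.LOW_DIFFERENCE, 50.0, 35.0),
    TreatmentName.HIGH_DIFFERENCE: Treatment(TreatmentName.HIGH_DIFFERENCE, 50.0, 20.0),
}


@dataclass(frozen=True)
class BehavioralEvent:
    """One timestamped activity interval of one bee within one trip."""

    bee_id: str
    phase: Phase
    trip_index: int
    start_ms: int
    duration_ms: int
    activity: Activity
    state: LocomotorState = LocomotorState.NA
    orientation: Orientation = Orientation.NONE
    flower_id: str | None = None

    @property
    def end_ms(self) -> int:
        return self.start_ms + self.duration_ms

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def is_flower_interaction(self) -> bool:
        return self.activity in FLOWER_ACTIVITIES

    def validate(self) -> None:
        if self.trip_index < 1:
            raise ValidationError(
                f"bee {self.bee_id}: trip_index must be >= 1, got {self.trip_index}"
            )
        if self.duration_ms < 0:
            raise ValidationError(
                f"bee {self.bee_id} trip {self.trip_index}: negative duration "
                f"{self.duration_ms} ms at t={self.start_ms}"
            )
        if self.start_ms < 0:
            raise ValidationError(
                f"bee {self.bee_id} trip {self.trip_index}: negative start time"
            )
        if self.is_flower_interaction:
            if self.flower_id is None:
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: flower interaction "
                    "without flower_id"
                )
            if self.orientation is Orientation.NONE:
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: flower interaction "
                    "without orientation"
                )
            if self.state is LocomotorState.NA:
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: flower interaction "
                    "without locomotor state"
                )
            # Hover interactions only ever occur at vertical flowers.
            if (
                self.state is LocomotorState.HOVER
                and self.orientation is not Orientation.VERTICAL
            ):
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: hover interaction "
                    f"at {self.orientation.value} flower"
                )
        else:
            if self.state is not LocomotorState.NA:
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: "
                    f"{self.activity.value} event carries locomotor state"
                )
            if self.orientation is not Orientation.NONE or self.flower_id is not None:
                raise ValidationError(
                    f"bee {self.bee_id} trip {self.trip_index}: "
                    f"{self.activity.value} event carries flower fields"
                )


@dataclass
class FlowerVisit:
    """Events aggregated into one visit to one flower.

    ``total_drink_time`` sums the drink-activity durations of the visit;
    ``landed_time``/``hover_time`` split all interaction time by locomotor
    state.  ``is_choice`` applies the > 2 s drinking rule.  ``choice_ordinal``
    numbers a bee's choices consecutively within a phase (1-based), across
    trips.
    """

    bee_id: str
    phase: Phase
    trip_index: int
    flower_id: str
    orientation: Orientation
    start_ms: int
    end_ms: int
    total_drink_time: float  # seconds
    landed_time: float  # seconds
    hover_time: float  # seconds
    visit_ordinal: int
    event_indices: tuple[int, ...]
    is_choice: bool = field(init=False)
    choice_ordinal: int | None = None

    def __post_init__(self) -> None:
        self.is_choice = self.total_drink_time > CHOICE_THRESHOLD_S

    @property
    def interaction_time(self) -> float:
        return self.landed_time + self.hover_time

    @property
    def involves_hover(self) -> bool:
        return self.hover_time > 0


# ---------------------------------------------------------------------------
# CSV dialects


@dataclass(frozen=True)
class EventLogDialect:
    """Column-name and value mappings for an event-log CSV.

    The canonical dialect writes one row per event with columns
    ``bee_id, phase, trip, t_start_ms, duration_ms, activity, state,
    orientation, flower_id``.  A custom dialect adapts an externally
    produced file without code changes: ``columns`` maps canonical field
    names to the file's column names, and the ``*_map`` dictionaries
    translate the file's category labels to canonical ones.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "bee_id": "bee_id",
            "phase": "phase",
            "trip": "trip",
            "t_start_ms": "t_start_ms",
            "duration_ms": "duration_ms",
            "activity": "activity",
            "state": "state",
            "orientation": "orientation",
            "flower_id": "flower_id",
        }
    )
    activity_map: Mapping[str, str] = field(default_factory=dict)
    state_map: Mapping[str, str] = field(default_factory=dict)
    orientation_map: Mapping[str, str] = field(default_factory=dict)
    phase_map: Mapping[str, str] = field(default_factory=dict)
    na_values: tuple[str, ...] = ("", "NA", "none", "n/a")

    @classmethod
    def from_dict(cls, d: Mapping) -> "EventLogDialect":
        base = cls()
        return cls(
            columns={**base.columns, **d.get("columns", {})},
            activity_map=d.get("activity_map", {}),
            state_map=d.get("state_map", {}),
            orientation_map=d.get("orientation_map", {}),
            phase_map=d.get("phase_map", {}),
            na_values=tuple(d.get("na_values", base.na_values)),
        )


CANONICAL_DIALECT = EventLogDialect()

_PHASE_ORDER = {Phase.FAMILIARIZATION: 0, Phase.TEST: 1}


class EventLog:
    """A validated, chronologically ordered collection of events."""

    def __init__(self, events: Iterable[BehavioralEvent], validate: bool = True):
        self._events = sorted(
            events,
            key=lambda e: (
                e.bee_id,
                _PHASE_ORDER[e.phase],
                e.trip_index,
                e.start_ms,
                e.end_ms,
            ),
        )
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[BehavioralEvent]:
        return iter(self._events)

    @property
    def events(self) -> list[BehavioralEvent]:
        return list(self._events)

    def bees(self) -> list[str]:
        return sorted({e.bee_id for e in self._events})

    def events_for(
        self, bee_id: str, phase: Phase | None = None
    ) -> list[BehavioralEvent]:
        return [
            e
            for e in self._events
            if e.bee_id == bee_id and (phase is None or e.phase == phase)
        ]

    def by_trip(
        self, bee_id: str, phase: Phase | None = None
    ) -> dict[int, list[BehavioralEvent]]:
        """Events of one bee grouped by trip, in chronological trip order."""
        out: dict[int, list[BehavioralEvent]] = {}
        for e in self.events_for(bee_id, phase):
            out.setdefault(e.trip_index, []).append(e)
        return out

    def validate(self) -> None:
        for e in self._events:
            e.validate()
        # Non-overlap within each bee-trip; trip ordering across phases.
        key = None
        prev_end = -1
        seen_test_trip: dict[str, int] = {}
        for e in self._events:
            k = (e.bee_id, e.phase, e.trip_index)
            if k != key:
                key = k
                prev_end = -1
            if e.start_ms < prev_end:
                raise ValidationError(
                    f"bee {e.bee_id} trip {e.trip_index}: overlapping events at "
                    f"t={e.start_ms} ms (previous event ends at {prev_end} ms)"
                )
            prev_end = e.end_ms
            if e.phase is Phase.TEST:
                seen_test_trip.setdefault(e.bee_id, e.trip_index)
        for e in self._events:
            if (
                e.phase is Phase.FAMILIARIZATION
                and e.bee_id in seen_test_trip
                and e.trip_index >= seen_test_trip[e.bee_id]
            ):
                raise ValidationError(
                    f"bee {e.bee_id}: familiarization trip {e.trip_index} does not "
                    f"precede first test trip {seen_test_trip[e.bee_id]}"
                )


def _map_value(raw: str, mapping: Mapping[str, str]) -> str:
    return mapping.get(raw, raw)


def read_event_log(
    path: str | Path,
    dialect: EventLogDialect = CANONICAL_DIALECT,
    validate: bool = True,
) -> EventLog:
    """Read an event-log CSV into a validated :class:`EventLog`.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` if events violate structural invariants.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [
            col
            for col in dialect.columns.values()
            if col not in reader.fieldnames
        ]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        cols = dialect.columns
        events = []
        for lineno, row in enumerate(reader, start=2):
            try:
                flower_raw = row[cols["flower_id"]]
                flower = None if flower_raw in dialect.na_values else flower_raw
                state_raw = _map_value(row[cols["state"]], dialect.state_map)
                orient_raw = _map_value(
                    row[cols["orientation"]], dialect.orientation_map
                )
                events.append(
                    BehavioralEvent(
                        bee_id=row[cols["bee_id"]],
                        phase=Phase(_map_value(row[cols["phase"]], dialect.phase_map)),
                        trip_index=int(row[cols["trip"]]),
                        start_ms=int(row[cols["t_start_ms"]]),
                        duration_ms=int(row[cols["duration_ms"]]),
                        activity=Activity(
                            _map_value(row[cols["activity"]], dialect.activity_map)
                        ),
                        state=(
                            LocomotorState.NA
                            if state_raw in dialect.na_values
                            else LocomotorState(state_raw)
                        ),
                        orientation=(
                            Orientation.NONE
                            if orient_raw in dialect.na_values
                            else Orientation(orient_raw)
                        ),
                        flower_id=flower,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: bad value ({exc})") from exc
    return EventLog(events, validate=validate)


def write_event_log(events: Iterable[BehavioralEvent], path: str | Path) -> None:
    """Write events as a canonical-dialect CSV (UTF-8, header row)."""
    path = Path(path)
    cols = CANONICAL_DIALECT.columns
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(cols.values()))
        for e in events:
            writer.writerow(
                [
                    e.bee_id,
                    e.phase.value,
                    e.trip_index,
                    e.start_ms,
                    e.duration_ms,
                    e.activity.value,
                    e.state.value,
                    e.orientation.value,
                    "" if e.flower_id is None else e.flower_id,
                ]
            )


def read_bee_table(path: str | Path) -> dict[str, Bee]:
    """Read bee metadata (bee_id, colony_id, treatment, unladen_mass_mg).

    Masses are stored in milligrams in the file and converted to grams.
    """
    path = Path(path)
    required = ["bee_id", "colony_id", "treatment", "unladen_mass_mg"]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        bees = {}
        for row in reader:
            bee = Bee(
                bee_id=row["bee_id"],
                colony_id=row["colony_id"],
                treatment=TreatmentName(row["treatment"]),
                unladen_mass=float(row["unladen_mass_mg"]) / 1000.0,
            )
            if bee.bee_id in bees:
                raise SchemaError(f"{path}: duplicate bee_id {bee.bee_id}")
            bees[bee.bee_id] = bee
    return bees


def write_bee_table(bees: Iterable[Bee], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bee_id", "colony_id", "treatment", "unladen_mass_mg"])
        for b in bees:
            writer.writerow(
                [b.bee_id, b.colony_id, b.treatment.value, f"{b.unladen_mass * 1000:g}"]
            )


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_visits(events: Sequence[BehavioralEvent]) -> list[FlowerVisit]:
    """Aggregate one bee-trip's events into flower visits.

    Consecutive interactions with the same flower separated by less than
    ``RETURN_MERGE_GAP_S`` (measured from the end of the previous interaction
    with that flower) with no intervening interaction with another flower are
    merged into one visit.  Drinking durations within a visit are summed and
    the > 2 s choice rule applied to the sum.
    """
    if not events:
        return []
    bee_ids = {e.bee_id for e in events}
    trips = {(e.phase, e.trip_index) for e in events}
    if len(bee_ids) > 1 or len(trips) > 1:
        raise ValidationError(
            "aggregate_visits expects events of exactly one bee-trip, got "
            f"bees={sorted(bee_ids)} trips={sorted(trips)}"
        )
    ordered = sorted(enumerate(events), key=lambda ie: (ie[1].start_ms, ie[1].end_ms))

    visits: list[FlowerVisit] = []
    current: dict | None = None  # accumulator for the open visit

    def close(acc: dict) -> None:
        e0 = events[acc["idx"][0]]
        visits.append(
            FlowerVisit(
                bee_id=e0.bee_id,
                phase=e0.phase,
                trip_index=e0.trip_index,
                flower_id=acc["flower"],
                orientation=acc["orientation"],
                start_ms=acc["start"],
                end_ms=acc["end"],
                total_drink_time=acc["drink"],
                landed_time=acc["landed"],
                hover_time=acc["hover"],
                visit_ordinal=len(visits) + 1,
                event_indices=tuple(acc["idx"]),
            )
        )

    for idx, e in ordered:
        if not e.is_flower_interaction:
            continue
        if current is not None:
            same_flower = e.flower_id == current["flower"]
            gap_s = (e.start_ms - current["end"]) / 1000.0
            if not (same_flower and gap_s < RETURN_MERGE_GAP_S):
                close(current)
                current = None
        if current is None:
            current = {
                "flower": e.flower_id,
                "orientation": e.orientation,
                "start": e.start_ms,
                "end": e.end_ms,
                "drink": 0.0,
                "landed": 0.0,
                "hover": 0.0,
                "idx": [],
            }
        current["end"] = max(current["end"], e.end_ms)
        current["idx"].append(idx)
        if e.activity is Activity.DRINK:
            current["drink"] += e.duration_s
        if e.state is LocomotorState.HOVER:
            current["hover"] += e.duration_s
        else:
            current["landed"] += e.duration_s
    if current is not None:
        close(current)
    return visits


def assign_choice_ordinals(
    visits_by_trip: Mapping[int, Sequence[FlowerVisit]],
) -> list[FlowerVisit]:
    """Number one bee-phase's choices consecutively across trips (1-based).

    Returns a flat, chronologically ordered visit list with
    ``choice_ordinal`` set on drinking visits.
    """
    flat: list[FlowerVisit] = []
    ordinal = 0
    for trip in sorted(visits_by_trip):
        for v in visits_by_trip[trip]:
            if v.is_choice:
                ordinal += 1
                v = replace_choice(v, ordinal)
            flat.append(v)
    return flat


def replace_choice(v: FlowerVisit, ordinal: int | None) -> FlowerVisit:
    out = replace(v)
    out.choice_ordinal = ordinal
    return out


def aggregate_bee_phase(
    events_by_trip: Mapping[int, Sequence[BehavioralEvent]],
) -> list[FlowerVisit]:
    """Aggregate all trips of one bee-phase and assign choice ordinals."""
    visits_by_trip = {t: aggregate_visits(evs) for t, evs in events_by_trip.items()}
    return assign_choice_ordinals(visits_by_trip)


def proportion_vertical(visits: Sequence[FlowerVisit], unit: str = "choices"):
    """Per-trip proportions of vertical-flower choices (or visits).

    Parameters
    ----------
    visits
        One bee's visits for one phase, chronological, with choice ordinals
        assigned.
    unit
        ``"choices"`` counts drinking visits only; ``"visits"`` counts all
        visits.

    Returns
    -------
    pandas.DataFrame
        Columns ``trip_index, k_vertical, n, proportion, cum_drinks`` where
        ``cum_drinks`` is the cumulative number of completed drinking visits
        by the end of the trip (the choice-curve predictor).  Trips with no
        qualifying event are omitted.
    """
    import pandas as pd

    if unit not in ("choices", "visits"):
        raise ValueError(f"unit must be 'choices' or 'visits', got {unit!r}")
    rows = []
    per_trip: dict[int, dict] = {}
    cum_drinks = 0
    for v in sorted(visits, key=lambda v: (v.trip_index, v.start_ms)):
        acc = per_trip.setdefault(v.trip_index, {"k": 0, "n": 0, "cum": 0})
        if v.is_choice:
            cum_drinks += 1
        if v.is_choice or unit == "visits":
            acc["n"] += 1
            if v.orientation is Orientation.VERTICAL:
                acc["k"] += 1
        acc["cum"] = cum_drinks
    for trip in sorted(per_trip):
        acc = per_trip[trip]
        if acc["n"] == 0:
            continue
        rows.append(
            {
                "trip_index": trip,
                "k_vertical": acc["k"],
                "n": acc["n"],
                "proportion": acc["k"] / acc["n"],
                "cum_drinks": acc["cum"],
            }
        )
    return pd.DataFrame(
        rows, columns=["trip_index", "k_vertical", "n", "proportion", "cum_drinks"]
    )


def check_phase_boundaries(
    log: EventLog,
    familiarization_choices: int = 60,
    test_choices: int = 90,
) -> dict[str, dict[str, int]]:
    """Recompute per-bee choice counts and check phase-boundary invariants.

    Each phase must end at the end of the trip in which the bee completed
    its target drinking visit (60th for familiarization, 90th for test).
    Returns per-bee counts; raises :class:`ValidationError` on violation.
    """
    out: dict[str, dict[str, int]] = {}
    for bee_id in log.bees():
        counts = {}
        for phase, target in (
            (Phase.FAMILIARIZATION, familiarization_choices),
            (Phase.TEST, test_choices),
        ):
            by_trip = log.by_trip(bee_id, phase)
            if not by_trip:
                counts[phase.value] = 0
                continue
            visits = aggregate_bee_phase(by_trip)
            n_choices = sum(1 for v in visits if v.is_choice)
            counts[phase.value] = n_choices
            if n_choices < target:
                raise ValidationError(
                    f"bee {bee_id}: only {n_choices} {phase.value} choices, "
                    f"expected >= {target}"
                )
            # The target choice must fall in the final trip of the phase.
            last_trip = max(by_trip)
            target_trip = next(
                v.trip_index for v in visits if v.choice_ordinal == target
            )
            if target_trip != last_trip:
                raise ValidationError(
                    f"bee {bee_id}: choice {target} of {phase.value} occurred in "
                    f"trip {target_trip} but the phase ran to trip {last_trip}"
                )
        out[bee_id] = counts
    return out
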