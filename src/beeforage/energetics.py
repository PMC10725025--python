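"""Per-trip energy budgets and foraging currencies.

Builds trip-level energy intake/expenditure with in-trip mass updating,
computes the two candidate currencies (rate of energy return, RER, and
energetic efficiency, EE), event-weighted per-ten-choice window series,
counterfactual alternative-strategy energetics, and the slippery-flower
cost estimator.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beeforage import physiology
from beeforage.errors import (
    ConfigError,
    MissingWindowError,
    UndefinedCurrencyError,
    ValidationError,
)
from beeforage.event_model import (
    Activity,
    BehavioralEvent,
    Bee,
    FlowerVisit,
    LocomotorState,
    Phase,
    Treatment,
    aggregate_bee_phase,
)
from beeforage.physiology import DEFAULT_PARAMS, PhysiologyParams

#: Metrics supported by :func:`window_series`.
WINDOW_METRICS = (
    "rer",
    "ee",
    "handling_time",
    "handling_energy",
    "between_flight_time",
)

DEFAULT_WINDOW = 10


def power_class(event: BehavioralEvent) -> str:
    """Metabolic class of an event: flight for flying and any hover
    interaction, probe for landed interaction, rest, and nest activities."""
    if event.activity is Activity.FLY:
        return "flight"
    if event.is_flower_interaction:
        return "flight" if event.state is LocomotorState.HOVER else "probe"
    return "probe"  # rest, nest_other, offload


def rer(intake: float, expenditure: float, time: float) -> float:
    """Rate of energy return (J/s): net energy gain per unit trip time."""
    if time <= 0:
        raise UndefinedCurrencyError(f"RER undefined for trip time {time} s")
    return (intake - expenditure) / time


def ee(intake: float, expenditure: float) -> float:
    """Energetic efficiency (dimensionless): net gain per unit energy spent."""
    if expenditure <= 0:
        raise UndefinedCurrencyError(
            f"EE undefined for expenditure {expenditure} J"
        )
    return (intake - expenditure) / expenditure


@dataclass
class TripEnergetics:
    """Energy budget of one foraging trip.

    ``trip_time`` is arena time (first to last logged event) plus modelled
    offloading time and other nest time; experimenter gate-holding time is
    not logged and therefore never enters.  ``event_costs`` holds the
    energetic cost of every event of the trip, aligned with the
    chronologically ordered event list.
    """

    bee_id: str
    phase: Phase
    trip_index: int
    intake: float  # J
    expenditure: float  # J
    trip_time: float  # s
    arena_time: float  # s
    offload_time: float  # s
    nest_other_time: float  # s
    total_volume: float  # uL consumed (counted drinks only)
    end_mass: float  # g, laden mass at the end of the arena period
    rer: float = field(init=False)
    ee: float = field(init=False)
    event_costs: tuple[float, ...] = ()
    visit_volumes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.rer = rer(self.intake, self.expenditure, self.trip_time)
        self.ee = ee(self.intake, self.expenditure)


def trip_energetics(
    events: Sequence[BehavioralEvent],
    visits: Sequence[FlowerVisit],
    bee: Bee,
    treatment: Treatment,
    params: PhysiologyParams = DEFAULT_PARAMS,
    mass_updating: bool = True,
) -> TripEnergetics:
    """Energy budget of one bee-trip.

    Intake sums the estimated volume of each drinking visit (the > 2 s rule
    excludes tastes; per-visit estimates are capped at the reward cap, and
    cumulative consumption per flower per trip cannot exceed the flower's
    reward volume) converted to sucrose energy at the orientation's
    concentration.  Expenditure integrates mass-specific metabolic power
    over every event using the bee's current mass: unladen at trip start,
    increasing after each drinking visit by consumed volume times solution
    density.  Set ``mass_updating=False`` to hold mass at unladen throughout
    (the load-independent robustness condition).
    """
    if not events:
        raise ValidationError(
            f"bee {bee.bee_id}: cannot compute energetics for an empty trip"
        )
    ordered = sorted(range(len(events)), key=lambda i: (events[i].start_ms, events[i].end_ms))
    arena_time = (
        max(e.end_ms for e in events) - min(e.start_ms for e in events)
    ) / 1000.0
    if arena_time <= 0:
        raise ValidationError(
            f"bee {bee.bee_id} trip {events[0].trip_index}: zero-duration trip"
        )

    # Per-visit consumed volumes, chronological, with per-flower depletion.
    visit_order = sorted(range(len(visits)), key=lambda i: visits[i].start_ms)
    # Mass at the start of each visit: walk visits and events jointly.
    mass = bee.unladen_mass
    flower_remaining: dict[str, float] = {}
    visit_volume = [0.0] * len(visits)
    visit_start_mass = [bee.unladen_mass] * len(visits)
    intake = 0.0
    per_conc_volume: dict[float, float] = {}
    for vi in visit_order:
        v = visits[vi]
        visit_start_mass[vi] = mass
        if v.total_drink_time <= params.taste_threshold:
            continue
        conc = treatment.concentration(v.orientation)
        remaining = flower_remaining.setdefault(v.flower_id, treatment.reward_volume)
        raw = physiology.drinking_rate(mass, conc, params) * v.total_drink_time
        vol = min(raw, params.reward_cap, remaining)
        flower_remaining[v.flower_id] = remaining - vol
        visit_volume[vi] = vol
        per_conc_volume[conc] = per_conc_volume.get(conc, 0.0) + vol
        intake += physiology.energy_intake(vol, conc, params)
        if mass_updating:
            mass += vol * physiology.sucrose_density(conc, params) / 1000.0

    end_mass = mass

    # Event-level expenditure: events within a visit are costed at the
    # visit-start mass (mass increments at the end of each drinking visit).
    event_mass = np.full(len(events), bee.unladen_mass)
    if mass_updating:
        visit_of_event: dict[int, int] = {}
        for vi, v in enumerate(visits):
            for ei in v.event_indices:
                visit_of_event[ei] = vi
        for ei in ordered:
            vi = visit_of_event.get(ei)
            if vi is not None:
                event_mass[ei] = visit_start_mass[vi]
            else:
                event_mass[ei] = _mass_at(
                    events[ei].start_ms, visits, visit_volume,
                    bee.unladen_mass, treatment, params,
                )

    costs = np.empty(len(events))
    for ei, e in enumerate(events):
        rate = (
            params.mr_flight if power_class(e) == "flight" else params.mr_probe
        )
        costs[ei] = event_mass[ei] * rate * e.duration_s
    expenditure = float(costs.sum())

    # Nest terms: offloading (per concentration) and fixed other nest time,
    # both at probe rate.  Mass during offloading defaults to laden.
    offload_s = 0.0
    for conc, vol in per_conc_volume.items():
        offload_s += physiology.offloading_time(vol, conc, params)
    offload_mass = end_mass if params.offload_mass_mode == "laden" else bee.unladen_mass
    if not mass_updating:
        offload_mass = bee.unladen_mass
    expenditure += physiology.metabolic_power(offload_mass, "probe", params) * offload_s
    expenditure += (
        physiology.metabolic_power(bee.unladen_mass, "probe", params)
        * params.nest_other_time
    )

    trip_time = arena_time + offload_s + params.nest_other_time
    e0 = events[0]
    return TripEnergetics(
        bee_id=bee.bee_id,
        phase=e0.phase,
        trip_index=e0.trip_index,
        intake=intake,
        expenditure=expenditure,
        trip_time=trip_time,
        arena_time=arena_time,
        offload_time=offload_s,
        nest_other_time=params.nest_other_time,
        total_volume=sum(visit_volume),
        end_mass=end_mass,
        event_costs=tuple(costs),
        visit_volumes=tuple(visit_volume),
    )


def _mass_at(
    t_ms: int,
    visits: Sequence[FlowerVisit],
    visit_volume: Sequence[float],
    unladen: float,
    treatment: Treatment,
    params: PhysiologyParams,
) -> float:
    """Bee mass at time ``t_ms``: unladen plus solution mass of every
    drinking visit that ended at or before ``t_ms``."""
    mass = unladen
    for vi, v in enumerate(visits):
        if v.end_ms <= t_ms and visit_volume[vi] > 0:
            conc = treatment.concentration(v.orientation)
            mass += visit_volume[vi] * physiology.sucrose_density(conc, params) / 1000.0
    return mass


# ---------------------------------------------------------------------------
# Per-bee pipeline


@dataclass
class BeePhaseEnergetics:
    """Full energetics of one bee over one phase: ordered events, visits
    with choice ordinals, and per-trip budgets."""

    bee: Bee
    phase: Phase
    treatment: Treatment
    events_by_trip: dict[int, list[BehavioralEvent]]
    visits: list[FlowerVisit]  # flat, chronological, choice ordinals set
    trips: dict[int, TripEnergetics]

    @property
    def n_choices(self) -> int:
        return sum(1 for v in self.visits if v.is_choice)

    def trip_table(self) -> pd.DataFrame:
        rows = [
            {
                "bee_id": t.bee_id,
                "phase": t.phase.value,
                "trip_index": t.trip_index,
                "intake_J": t.intake,
                "expenditure_J": t.expenditure,
                "trip_time_s": t.trip_time,
                "arena_time_s": t.arena_time,
                "offload_time_s": t.offload_time,
                "total_volume_ul": t.total_volume,
                "rer_J_per_s": t.rer,
                "ee": t.ee,
            }
            for _, t in sorted(self.trips.items())
        ]
        return pd.DataFrame(rows)


def analyze_bee_phase(
    events_by_trip: Mapping[int, Sequence[BehavioralEvent]],
    bee: Bee,
    treatment: Treatment,
    phase: Phase,
    params: PhysiologyParams = DEFAULT_PARAMS,
    mass_updating: bool = True,
) -> BeePhaseEnergetics:
    """Run the event -> visit -> trip-energetics pipeline for one bee-phase."""
    events_by_trip = {t: list(evs) for t, evs in sorted(events_by_trip.items())}
    visits = aggregate_bee_phase(events_by_trip)
    trips = {}
    for trip_index, evs in events_by_trip.items():
        trip_visits = [v for v in visits if v.trip_index == trip_index]
        trips[trip_index] = trip_energetics(
            evs, trip_visits, bee, treatment, params, mass_updating=mass_updating
        )
    return BeePhaseEnergetics(
        bee=bee,
        phase=phase,
        treatment=treatment,
        events_by_trip=events_by_trip,
        visits=visits,
        trips=trips,
    )


# ---------------------------------------------------------------------------
# Window series


def _assign_events_to_choices(
    result: BeePhaseEnergetics,
) -> tuple[list[BehavioralEvent], np.ndarray, np.ndarray, list[int]]:
    """Flatten a bee-phase's events and assign each to a choice ordinal.

    An event belongs to the first choice whose final interaction ends at or
    after the event ends; events trailing the last choice are assigned to
    the last choice.  Returns (events, choice_ordinal per event, per-event
    trip index array, sorted trip order).
    """
    choices = [v for v in result.visits if v.is_choice]
    if not choices:
        raise MissingWindowError(
            f"bee {result.bee.bee_id}: no choices in {result.phase.value} phase"
        )
    trip_order = sorted(result.events_by_trip)
    trip_rank = {t: i for i, t in enumerate(trip_order)}
    # Global sort key: (trip rank, time within trip).
    choice_keys = [(trip_rank[c.trip_index], c.end_ms) for c in choices]
    flat_events: list[BehavioralEvent] = []
    event_keys: list[tuple[int, int]] = []
    for t in trip_order:
        for e in sorted(result.events_by_trip[t], key=lambda e: (e.start_ms, e.end_ms)):
            flat_events.append(e)
            event_keys.append((trip_rank[t], e.end_ms))
    ordinals = np.empty(len(flat_events), dtype=int)
    ci = 0
    for i, key in enumerate(event_keys):
        while ci < len(choices) - 1 and key > choice_keys[ci]:
            ci += 1
        ordinals[i] = choices[min(ci, len(choices) - 1)].choice_ordinal
        if key > choice_keys[-1]:
            ordinals[i] = choices[-1].choice_ordinal
    trips_arr = np.array([e.trip_index for e in flat_events])
    return flat_events, ordinals, trips_arr, trip_order


def window_series(
    result: BeePhaseEnergetics,
    metric: str,
    window: int = DEFAULT_WINDOW,
    weighting: str = "events",
) -> pd.DataFrame:
    """Event-weighted window series over consecutive blocks of choices.

    For ``rer``/``ee``, every behavioral event carries the value of the trip
    it occurred on; the window value is the weighted mean over all events
    assigned to the window's choices (weight 1 per event, or event duration
    with ``weighting="duration"``), so windows spanning a trip boundary are
    weighted between the two trips' values.  ``handling_time`` and
    ``handling_energy`` average all flower-interaction time (or its
    energetic cost) per choice; ``between_flight_time`` averages
    between-flower flight time per choice (hover interaction excluded by
    construction: it is visit/drink activity, not flight).

    A trailing window with fewer than ``window`` choices is reported with
    ``complete=False``; complete-window analyses should drop it.
    """
    if metric not in WINDOW_METRICS:
        raise ConfigError(f"unknown metric {metric!r}; expected one of {WINDOW_METRICS}")
    if weighting not in ("events", "duration"):
        raise ConfigError("weighting must be 'events' or 'duration'")
    events, ordinals, trips_arr, _ = _assign_events_to_choices(result)
    n_choices = max(int(ordinals.max()), result.n_choices)
    durations = np.array([e.duration_s for e in events])
    rows = []
    trip_value = None
    if metric in ("rer", "ee"):
        trip_value = {t: getattr(te, metric) for t, te in result.trips.items()}
        values = np.array([trip_value[t] for t in trips_arr])
    is_interaction = np.array([e.is_flower_interaction for e in events])
    is_fly = np.array([e.activity is Activity.FLY for e in events])
    costs = np.concatenate(
        [
            np.asarray(result.trips[t].event_costs)
            for t in sorted(result.events_by_trip)
        ]
    )
    n_windows = (n_choices + window - 1) // window
    for w in range(1, n_windows + 1):
        lo, hi = (w - 1) * window, w * window
        in_window = (ordinals > lo) & (ordinals <= hi)
        k = min(hi, n_choices) - lo
        if metric in ("rer", "ee"):
            vals = values[in_window]
            if weighting == "events":
                value = float(vals.mean()) if vals.size else np.nan
            else:
                wts = durations[in_window]
                value = float(np.average(vals, weights=wts)) if wts.sum() > 0 else np.nan
        elif metric == "handling_time":
            value = float(durations[in_window & is_interaction].sum()) / k
        elif metric == "handling_energy":
            value = float(costs[in_window & is_interaction].sum()) / k
        else:  # between_flight_time
            value = float(durations[in_window & is_fly].sum()) / k
        rows.append(
            {
                "bee_id": result.bee.bee_id,
                "phase": result.phase.value,
                "metric": metric,
                "window_index": w,
                "value": value,
                "n_choices": k,
                "complete": k == window,
            }
        )
    return pd.DataFrame(rows)


def window_series_table(
    results: Sequence[BeePhaseEnergetics],
    metrics: Sequence[str] = WINDOW_METRICS,
    window: int = DEFAULT_WINDOW,
    weighting: str = "events",
) -> pd.DataFrame:
    """Long-format window series for several bees and metrics."""
    frames = [
        window_series(r, m, window=window, weighting=weighting)
        for r in results
        for m in metrics
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Counterfactual strategies


@dataclass(frozen=True)
class CounterfactualSpec:
    """Recompute donor bees' energetics under substituted concentrations.

    ``concentration_map`` maps each orientation to the % w/w concentration
    of the target treatment; the donors' behavior (event timings, choices)
    is left unchanged, which is valid because drinking rate does not change
    with concentration below the ~35-40% w/w plateau.
    """

    target_treatment: str
    donor_treatment: str
    concentration_map: Mapping[str, float]  # orientation value -> % w/w
    phase: Phase = Phase.TEST

    def as_treatment(self, base: Treatment) -> Treatment:
        from beeforage.event_model import TreatmentName

        return Treatment(
            name=TreatmentName(self.target_treatment),
            conc_vertical=self.concentration_map["vertical"],
            conc_horizontal=self.concentration_map["horizontal"],
            reward_volume=base.reward_volume,
        )


def counterfactual_energetics(
    donor_results: Sequence[BeePhaseEnergetics],
    spec: CounterfactualSpec,
    params: PhysiologyParams = DEFAULT_PARAMS,
    metrics: Sequence[str] = ("rer", "ee"),
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Window series of donor bees re-evaluated under target concentrations.

    Volumes, intake, offloading, and mass updating are all recomputed on the
    donor event streams with the substituted concentration map; behavior is
    unchanged.  An identity map reproduces the observed energetics exactly.
    """
    frames = []
    for donor in donor_results:
        treatment = spec.as_treatment(donor.treatment)
        redone = analyze_bee_phase(
            donor.events_by_trip, donor.bee, treatment, donor.phase, params
        )
        for m in metrics:
            frame = window_series(redone, m, window=window)
            frame["donor_treatment"] = spec.donor_treatment
            frame["target_treatment"] = spec.target_treatment
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Slippery-flower cost estimator


def cost_of_slippery(
    control_series: pd.DataFrame,
    highdiff_series: pd.DataFrame,
    window_index: int = 9,
) -> dict[str, float]:
    """Cost of slippery vertical flowers from the final complete window.

    Takes per-bee window-series tables (long format with ``metric`` in
    {handling_time, handling_energy}) for the control treatment (the
    horizontal-flower baseline) and the high-difference treatment (the
    vertical-flower arm); returns the medians across bees of per-choice
    handling time and handling energy in the requested window, and their
    differences.
    """
    out: dict[str, float] = {}
    for label, series in (("control", control_series), ("high_difference", highdiff_series)):
        for metric in ("handling_time", "handling_energy"):
            sel = series[
                (series["metric"] == metric)
                & (series["window_index"] == window_index)
                & series["complete"]
            ]
            all_bees = set(series["bee_id"].unique())
            have = set(sel["bee_id"].unique())
            missing = sorted(all_bees - have)
            if missing:
                raise MissingWindowError(
                    f"{label}: window {window_index} ({metric}) missing for "
                    f"bee(s) {missing}"
                )
            out[f"{label}_median_{metric}"] = float(sel["value"].median())
    out["delta_median_handling_time"] = (
        out["high_difference_median_handling_time"]
        - out["control_median_handling_time"]
    )
    out["delta_median_handling_energy"] = (
        out["high_difference_median_handling_energy"]
        - out["control_median_handling_energy"]
    )
    return out
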