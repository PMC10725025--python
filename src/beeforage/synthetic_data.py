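"""Agent-based generator of complete experiment event logs.

Emulates the statistical structure of the two-phase foraging experiment
(36 bees, 12 per treatment across 3 colonies; a familiarization phase on
easy-grip flowers ending with the trip containing the 60th drinking visit,
then a test phase on slippery flowers ending with the 90th) with known
ground truth: drinking bout durations are generated by inverting the
physiological drinking-rate model from target volumes, so the downstream
energetics pipeline recovers true consumption exactly.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from beeforage import physiology
from beeforage.errors import ConfigError
from beeforage.event_model import (
    STANDARD_TREATMENTS,
    Activity,
    Bee,
    BehavioralEvent,
    EventLog,
    LocomotorState,
    Orientation,
    Phase,
    Treatment,
    TreatmentName,
    write_bee_table,
    write_event_log,
)
from beeforage.physiology import DEFAULT_PARAMS, PhysiologyParams

POLICY_NAMES = ("constant_p", "learning_sigmoid", "greedy_rer", "greedy_ee")


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class PolicySpec:
    """Flower-orientation choice policy for one phase.

    These policies generate data with known structure; they are not a model
    of bee cognition.  ``constant_p`` picks vertical with fixed probability;
    ``learning_sigmoid`` moves the probability from ``p_start`` to ``p_end``
    along a logistic trajectory in the cumulative phase choice count;
    ``greedy_rer``/``greedy_ee`` pick the orientation with the better
    expected per-visit currency score (epsilon-greedy).
    """

    name: str = "constant_p"
    p_vertical: float = 0.5
    p_start: float = 0.9
    p_end: float = 0.05
    rate: float = 0.12
    midpoint: float = 30.0
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ConfigError(f"unknown policy {self.name!r}; expected {POLICY_NAMES}")
        for attr in ("p_vertical", "p_start", "p_end", "epsilon"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"PolicySpec.{attr} must be in [0, 1], got {v}")

    def probability_vertical(
        self,
        n_choices: int,
        mass: float,
        treatment: Treatment,
        slippery: bool,
        config: "SimulationConfig",
        params: PhysiologyParams,
    ) -> float:
        if self.name == "constant_p":
            return self.p_vertical
        if self.name == "learning_sigmoid":
            frac = _expit(self.rate * (n_choices - self.midpoint))
            return self.p_start + (self.p_end - self.p_start) * frac
        currency = "rer" if self.name == "greedy_rer" else "ee"
        scores = expected_visit_scores(mass, treatment, slippery, config, params)
        sv, sh = scores[Orientation.VERTICAL][currency], scores[Orientation.HORIZONTAL][currency]
        if math.isclose(sv, sh, rel_tol=1e-6):
            return 0.5
        return 1.0 - self.epsilon if sv > sh else self.epsilon


def expected_visit_scores(
    mass: float,
    treatment: Treatment,
    slippery: bool,
    config: "SimulationConfig",
    params: PhysiologyParams,
) -> dict[Orientation, dict[str, float]]:
    """Expected per-visit RER/EE score for each flower orientation.

    Uses the configured median timings and the physiological model: a
    slippery vertical visit is hover-dominated with a partial expected
    volume; all other visits are landed and drain the full reward.
    """
    out = {}
    for orientation in (Orientation.VERTICAL, Orientation.HORIZONTAL):
        conc = treatment.concentration(orientation)
        hover = slippery and orientation is Orientation.VERTICAL
        volume = (
            config.slippery_volume_frac * treatment.reward_volume
            if hover
            else treatment.reward_volume
        )
        drink_s = volume / physiology.drinking_rate(mass, conc, params)
        overhead = (
            config.hover_overhead_median_s if hover else config.landed_overhead_median_s
        )
        handling = drink_s + overhead
        flight = config.flight_median_s
        if hover:
            cost = physiology.metabolic_power(mass, "flight", params) * (
                flight + handling
            )
        else:
            cost = (
                physiology.metabolic_power(mass, "flight", params) * flight
                + physiology.metabolic_power(mass, "probe", params) * handling
            )
        intake = physiology.energy_intake(volume, conc, params)
        out[orientation] = {
            "rer": (intake - cost) / (handling + flight),
            "ee": (intake - cost) / cost,
        }
    return out


def _default_test_policies() -> dict[str, PolicySpec]:
    return {
        "control": PolicySpec(
            name="learning_sigmoid", p_start=0.5, p_end=0.003, rate=0.15, midpoint=20.0
        ),
        "low_difference": PolicySpec(
            name="learning_sigmoid", p_start=0.9, p_end=0.05, rate=0.12, midpoint=30.0
        ),
        "high_difference": PolicySpec(name="constant_p", p_vertical=0.99),
    }


def _default_familiarization_policies() -> dict[str, PolicySpec]:
    return {
        "control": PolicySpec(name="constant_p", p_vertical=0.5),
        "low_difference": PolicySpec(
            name="learning_sigmoid", p_start=0.5, p_end=0.97, rate=0.2, midpoint=10.0
        ),
        "high_difference": PolicySpec(
            name="learning_sigmoid", p_start=0.5, p_end=0.995, rate=0.25, midpoint=8.0
        ),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment generator.

    Timing distributions are lognormal around configurable medians; crop
    capacity (the trip-ending consumption threshold) is a free parameter
    chosen so trips contain roughly 8-15 choices.  With
    ``deterministic_timing`` every duration collapses to its median and
    bee masses to the median mass (zero-heterogeneity mode).
    """

    n_colonies: int = 3
    bees_per_treatment_per_colony: int = 4
    familiarization_choices: int = 60
    test_choices: int = 90
    n_flowers_per_orientation: int = 15
    crop_capacity_ul: float = 120.0
    # Choice policies per treatment name, per phase.
    test_policies: dict[str, PolicySpec] = field(default_factory=_default_test_policies)
    familiarization_policies: dict[str, PolicySpec] = field(
        default_factory=_default_familiarization_policies
    )
    # Slippery vertical flower behavior (test phase).
    hover_prob_slippery_vertical: float = 0.98
    bout_interrupt_prob: float = 0.45
    bout_volume_mean_ul: float = 3.5
    slippery_volume_frac: float = 0.55  # expected fraction of the reward consumed
    # Timing distributions (lognormal medians / log-sd).
    flight_median_s: float = 3.0
    flight_sigma: float = 0.4
    landed_overhead_median_s: float = 2.5
    overhead_sigma: float = 0.4
    hover_overhead_median_s: float = 8.0
    hover_overhead_sigma: float = 0.4
    scrabble_gap_median_s: float = 1.5
    rest_prob: float = 0.08
    rest_median_s: float = 5.0
    rest_sigma: float = 0.5
    nondrink_visit_prob: float = 0.08
    nondrink_visit_median_s: float = 1.2
    # Bee masses (milligrams; lognormal around the median).
    mass_median_mg: float = 171.0
    mass_sigma: float = 0.12
    deterministic_timing: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for attr in (
            "hover_prob_slippery_vertical",
            "bout_interrupt_prob",
            "slippery_volume_frac",
            "rest_prob",
            "nondrink_visit_prob",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"SimulationConfig.{attr} must be in [0, 1], got {v}")
        per_orientation = self.n_flowers_per_orientation * 15.0
        if self.crop_capacity_ul > per_orientation:
            raise ConfigError(
                "crop_capacity_ul must not exceed the total reward available on "
                f"one orientation ({per_orientation} uL): a bee must be able to "
                "fill up solely on flowers of one orientation"
            )
        if self.crop_capacity_ul <= 0:
            raise ConfigError("crop_capacity_ul must be > 0")

    def policy_for(self, treatment: TreatmentName, phase: Phase) -> PolicySpec:
        table = (
            self.test_policies
            if phase is Phase.TEST
            else self.familiarization_policies
        )
        try:
            return table[treatment.value]
        except KeyError:
            raise ConfigError(
                f"no {phase.value} policy configured for treatment {treatment.value}"
            ) from None


@dataclass
class SimulatedDataset:
    """Output of :func:`simulate_experiment`."""

    bees: dict[str, Bee]
    treatments: Mapping[TreatmentName, Treatment]
    log: EventLog
    ground_truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": outdir / "events.csv",
            "bees": outdir / "bees.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        write_event_log(self.log, paths["events"])
        write_bee_table(
            [self.bees[k] for k in sorted(self.bees)], paths["bees"]
        )
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def _duration_s(rng: np.random.Generator, median: float, sigma: float, cfg: SimulationConfig) -> float:
    if cfg.deterministic_timing or sigma == 0:
        return median
    return median * math.exp(sigma * rng.standard_normal())


def _ms(seconds: float) -> int:
    return max(int(round(seconds * 1000.0)), 1)


def simulate_bee(
    bee: Bee,
    config: SimulationConfig,
    treatment: Treatment | None = None,
    params: PhysiologyParams = DEFAULT_PARAMS,
    rng: np.random.Generator | None = None,
) -> tuple[list[BehavioralEvent], pd.DataFrame]:
    """Simulate one bee's complete two-phase event log.

    Returns the chronological event stream and a ground-truth table with one
    row per flower visit (true consumed volume, concentration, whether the
    visit qualifies as a drinking visit under the > 2 s rule).
    """
    if treatment is None:
        treatment = STANDARD_TREATMENTS[bee.treatment]
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    events: list[BehavioralEvent] = []
    gt_rows: list[dict] = []
    trip_index = 0
    for phase, target in (
        (Phase.FAMILIARIZATION, config.familiarization_choices),
        (Phase.TEST, config.test_choices),
    ):
        policy = config.policy_for(treatment.name, phase)
        slippery = phase is Phase.TEST
        n_choices = 0
        while n_choices < target:
            trip_index += 1
            trip_events, trip_gt, new_choices = _simulate_trip(
                bee, treatment, config, params, rng, phase, trip_index,
                policy, slippery, n_choices,
            )
            events.extend(trip_events)
            gt_rows.extend(trip_gt)
            n_choices += new_choices
            if new_choices == 0:
                raise ConfigError(
                    f"bee {bee.bee_id}: trip {trip_index} produced no choices; "
                    "check crop capacity and timing configuration"
                )
    return events, pd.DataFrame(gt_rows)


def _simulate_trip(
    bee: Bee,
    treatment: Treatment,
    config: SimulationConfig,
    params: PhysiologyParams,
    rng: np.random.Generator,
    phase: Phase,
    trip_index: int,
    policy: PolicySpec,
    slippery: bool,
    phase_choices_so_far: int,
) -> tuple[list[BehavioralEvent], list[dict], int]:
    nf = config.n_flowers_per_orientation
    flowers = {f"V{i:02d}": treatment.reward_volume for i in range(1, nf + 1)}
    flowers.update({f"H{i:02d}": treatment.reward_volume for i in range(1, nf + 1)})
    orientation_of = {
        fid: Orientation.VERTICAL if fid.startswith("V") else Orientation.HORIZONTAL
        for fid in flowers
    }
    events: list[BehavioralEvent] = []
    gt: list[dict] = []
    t_ms = 0
    crop = 0.0
    mass = bee.unladen_mass
    prev_flower: str | None = None
    n_choices = 0

    def add_event(duration_ms: int, activity: Activity, state=LocomotorState.NA,
                  orientation=Orientation.NONE, flower_id=None) -> None:
        nonlocal t_ms
        events.append(
            BehavioralEvent(
                bee_id=bee.bee_id,
                phase=phase,
                trip_index=trip_index,
                start_ms=t_ms,
                duration_ms=duration_ms,
                activity=activity,
                state=state,
                orientation=orientation,
                flower_id=flower_id,
            )
        )
        t_ms += duration_ms

    for _ in range(500):
        if crop >= config.crop_capacity_ul - 0.5:
            break
        p_vertical = policy.probability_vertical(
            phase_choices_so_far + n_choices, mass, treatment, slippery, config, params
        )
        want = (
            Orientation.VERTICAL
            if rng.random() < p_vertical
            else Orientation.HORIZONTAL
        )
        # A drink must exceed the 2 s tasting threshold to count, so flowers
        # holding less than ~2.5 s worth of solution are not worth visiting.
        usable = {}
        for orientation in (want, _other(want)):
            conc = treatment.concentration(orientation)
            min_vol = 2.5 * physiology.drinking_rate(mass, conc, params)
            usable[orientation] = [
                fid
                for fid, vol in flowers.items()
                if orientation_of[fid] is orientation and vol >= min_vol
                and fid != prev_flower
            ]
        chosen_orientation = want if usable[want] else _other(want)
        candidates = usable[chosen_orientation]
        if not candidates:
            break
        flower_id = candidates[int(rng.integers(len(candidates)))]
        orientation = chosen_orientation
        conc = treatment.concentration(orientation)

        if rng.random() < config.rest_prob and not config.deterministic_timing:
            add_event(
                _ms(_duration_s(rng, config.rest_median_s, config.rest_sigma, config)),
                Activity.REST,
            )
        add_event(
            _ms(_duration_s(rng, config.flight_median_s, config.flight_sigma, config)),
            Activity.FLY,
        )
        # Occasional non-drinking inspection visit to some other flower.
        if rng.random() < config.nondrink_visit_prob and not config.deterministic_timing:
            others = [f for f in flowers if f not in (flower_id, prev_flower)]
            if others:
                other = others[int(rng.integers(len(others)))]
                o_orient = orientation_of[other]
                o_state = (
                    LocomotorState.HOVER
                    if slippery and o_orient is Orientation.VERTICAL
                    else LocomotorState.LANDED
                )
                add_event(
                    _ms(_duration_s(rng, config.nondrink_visit_median_s, 0.4, config)),
                    Activity.VISIT, o_state, o_orient, other,
                )
                gt.append(
                    _gt_row(bee, phase, trip_index, events[-1].start_ms, other,
                            o_orient, conc=treatment.concentration(o_orient),
                            drink_s=0.0, volume=0.0, counted=False,
                            hover=o_state is LocomotorState.HOVER)
                )
                prev_flower = other
                add_event(
                    _ms(_duration_s(rng, config.flight_median_s, config.flight_sigma, config)),
                    Activity.FLY,
                )
                if flower_id == prev_flower:  # pragma: no cover - excluded above
                    continue

        hover = (
            slippery
            and orientation is Orientation.VERTICAL
            and rng.random() < config.hover_prob_slippery_vertical
        )
        state = LocomotorState.HOVER if hover else LocomotorState.LANDED
        rate = physiology.drinking_rate(mass, conc, params)
        remaining = flowers[flower_id]
        target_vol = min(remaining, config.crop_capacity_ul - crop, params.reward_cap)

        overhead_median = (
            config.hover_overhead_median_s if hover else config.landed_overhead_median_s
        )
        overhead_sigma = config.hover_overhead_sigma if hover else config.overhead_sigma
        add_event(
            _ms(_duration_s(rng, overhead_median, overhead_sigma, config)),
            Activity.VISIT, state, orientation, flower_id,
        )
        total_drink_ms = 0
        if hover:
            # Partial-volume drinking: a sequence of interruptible bouts.
            consumed_target = 0.0
            while consumed_target < target_vol - 1e-9:
                if config.deterministic_timing:
                    bout_target = target_vol - consumed_target
                else:
                    bout_target = min(
                        0.5 + rng.exponential(config.bout_volume_mean_ul),
                        target_vol - consumed_target,
                    )
                bout_ms = _ms(bout_target / rate)
                add_event(bout_ms, Activity.DRINK, state, orientation, flower_id)
                total_drink_ms += bout_ms
                consumed_target += rate * bout_ms / 1000.0
                if config.deterministic_timing:
                    break
                if rng.random() < config.bout_interrupt_prob:
                    break
                add_event(
                    _ms(_duration_s(rng, config.scrabble_gap_median_s, 0.4, config)),
                    Activity.VISIT, state, orientation, flower_id,
                )
        else:
            bout_ms = _ms(target_vol / rate)
            add_event(bout_ms, Activity.DRINK, state, orientation, flower_id)
            total_drink_ms += bout_ms

        # Mirror the measurement model exactly: per-visit volume estimated
        # from summed drinking time at visit-start mass, capped by the
        # reward cap and the flower's remaining volume; visits at or below
        # the tasting threshold contribute nothing.
        drink_s = total_drink_ms / 1000.0
        if drink_s > params.taste_threshold:
            volume = min(rate * drink_s, params.reward_cap, remaining)
            counted = True
            flowers[flower_id] = remaining - volume
            crop += volume
            mass += volume * physiology.sucrose_density(conc, params) / 1000.0
            n_choices += 1
        else:
            volume = 0.0
            counted = False
        gt.append(
            _gt_row(bee, phase, trip_index, events[-1].start_ms, flower_id,
                    orientation, conc, drink_s, volume, counted, hover)
        )
        prev_flower = flower_id
        # If the remaining crop space no longer holds a countable drink the
        # bee cannot usefully continue: head home to offload.
        if not counted and target_vol < (params.taste_threshold + 0.5) * rate:
            break
    return events, gt, n_choices


def _other(orientation: Orientation) -> Orientation:
    return (
        Orientation.HORIZONTAL
        if orientation is Orientation.VERTICAL
        else Orientation.VERTICAL
    )


def _gt_row(bee, phase, trip_index, t_ms, flower_id, orientation, conc,
            drink_s, volume, counted, hover) -> dict:
    return {
        "bee_id": bee.bee_id,
        "phase": phase.value,
        "trip_index": trip_index,
        "t_ms": t_ms,
        "flower_id": flower_id,
        "orientation": orientation.value,
        "concentration": conc,
        "drink_time_s": round(drink_s, 6),
        "volume_ul": round(volume, 9),
        "energy_J": round(
            physiology.energy_intake(volume, conc) if counted else 0.0, 9
        ),
        "counted": counted,
        "hover": hover,
    }


def make_bees(config: SimulationConfig) -> dict[str, Bee]:
    """The experiment's bee roster: colonies x treatments x replicates."""
    bees = {}
    treatments = list(STANDARD_TREATMENTS)
    for ci in range(1, config.n_colonies + 1):
        for treatment in treatments:
            for bi in range(1, config.bees_per_treatment_per_colony + 1):
                bee_id = f"c{ci}-{treatment.value}-{bi}"
                rng = _bee_rng(config.rng_seed, bee_id)
                if config.deterministic_timing:
                    mass_mg = config.mass_median_mg
                else:
                    mass_mg = config.mass_median_mg * math.exp(
                        config.mass_sigma * rng.standard_normal()
                    )
                bees[bee_id] = Bee(
                    bee_id=bee_id,
                    colony_id=f"colony{ci}",
                    treatment=treatment,
                    unladen_mass=mass_mg / 1000.0,
                )
    return bees


def _bee_rng(seed: int, bee_id: str) -> np.random.Generator:
    # Stable per-bee substream derived from (seed, bee_id) bytes; independent
    # of Python's hash randomization.
    return np.random.default_rng(
        np.random.SeedSequence([seed, *bee_id.encode("utf-8")])
    )


def simulate_experiment(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full 36-bee experiment, deterministic under the seed."""
    bees = make_bees(config)
    all_events: list[BehavioralEvent] = []
    gt_frames = []
    for bee_id in sorted(bees):
        bee = bees[bee_id]
        rng = _bee_rng(config.rng_seed, bee_id + "/events")
        events, gt = simulate_bee(bee, config, rng=rng)
        all_events.extend(events)
        gt_frames.append(gt)
    return SimulatedDataset(
        bees=bees,
        treatments=STANDARD_TREATMENTS,
        log=EventLog(all_events),
        ground_truth=pd.concat(gt_frames, ignore_index=True),
        config=config,
    )


def simulate_treatment_group(
    config: SimulationConfig,
    treatment: TreatmentName,
    n_bees: int = 12,
    params: PhysiologyParams = DEFAULT_PARAMS,
) -> SimulatedDataset:
    """Simulate ``n_bees`` bees of a single treatment (smaller test harness)."""
    bees = {}
    all_events: list[BehavioralEvent] = []
    gt_frames = []
    for bi in range(1, n_bees + 1):
        bee_id = f"c{(bi - 1) % 3 + 1}-{treatment.value}-{bi}"
        rng = _bee_rng(config.rng_seed, bee_id)
        if config.deterministic_timing:
            mass_mg = config.mass_median_mg
        else:
            mass_mg = config.mass_median_mg * math.exp(
                config.mass_sigma * rng.standard_normal()
            )
        bee = Bee(bee_id, f"colony{(bi - 1) % 3 + 1}", treatment, mass_mg / 1000.0)
        bees[bee_id] = bee
        rng2 = _bee_rng(config.rng_seed, bee_id + "/events")
        events, gt = simulate_bee(bee, config, params=params, rng=rng2)
        all_events.extend(events)
        gt_frames.append(gt)
    return SimulatedDataset(
        bees=bees,
        treatments=STANDARD_TREATMENTS,
        log=EventLog(all_events),
        ground_truth=pd.concat(gt_frames, ignore_index=True),
        config=config,
    )
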