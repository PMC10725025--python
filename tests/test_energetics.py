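import numpy as np
import pytest

from beeforage import energetics as en
from beeforage import physiology as phys
from beeforage.errors import (
    MissingWindowError,
    UndefinedCurrencyError,
    ValidationError,
)
from beeforage.event_model import (
    STANDARD_TREATMENTS,
    Activity,
    Bee,
    BehavioralEvent,
    LocomotorState,
    Orientation,
    Phase,
    Treatment,
    TreatmentName,
    aggregate_visits,
)
from beeforage.physiology import DEFAULT_PARAMS


def ev(start_ms, duration_ms, activity, state=LocomotorState.NA,
       orientation=Orientation.NONE, flower=None, trip=1, bee="b1"):
    return BehavioralEvent(
        bee_id=bee, phase=Phase.TEST, trip_index=trip, start_ms=start_ms,
        duration_ms=duration_ms, activity=Activity(activity), state=state,
        orientation=orientation, flower_id=flower,
    )


BEE_1G = Bee("b1", "c1", TreatmentName.CONTROL, 1.0)
BEE_SMALL = Bee("b1", "c1", TreatmentName.CONTROL, 0.171)
CONTROL = STANDARD_TREATMENTS[TreatmentName.CONTROL]


class TestCurrencies:
    def test_break_even(self):
        assert en.rer(10.0, 10.0, 100.0) == 0.0
        assert en.ee(10.0, 10.0) == 0.0

    def test_arithmetic(self):
        assert en.rer(100.0, 10.0, 300.0) == pytest.approx(0.3)
        assert en.ee(100.0, 10.0) == pytest.approx(9.0)

    def test_ee_lower_bound(self):
        assert en.ee(0.0, 5.0) == -1.0

    def test_zero_denominators(self):
        with pytest.raises(UndefinedCurrencyError):
            en.rer(1.0, 1.0, 0.0)
        with pytest.raises(UndefinedCurrencyError):
            en.ee(1.0, 0.0)


class TestTripEnergetics:
    def _run(self, events, bee, treatment=CONTROL, **kw):
        visits = aggregate_visits(events)
        return en.trip_energetics(events, visits, bee, treatment, **kw)

    def test_single_visit_intake_oracle(self):
        # 1 g bee, 5 s drink of 35%: volume 2.991*5 = 14.955 uL.
        events = [
            ev(0, 10_000, "fly"),
            ev(10_000, 5_000, "drink", LocomotorState.LANDED,
               Orientation.HORIZONTAL, "H1"),
        ]
        trip = self._run(events, BEE_1G)
        assert trip.intake == pytest.approx(
            phys.energy_intake(14.955, 35.0), rel=1e-9
        )

    def test_all_rest_trip(self):
        events = [ev(0, 100_000, "rest")]
        trip = self._run(events, BEE_SMALL)
        assert trip.intake == 0.0
        expected = 0.034 * 0.171 * 100.0 + 0.034 * 0.171 * 83.8
        assert trip.expenditure == pytest.approx(expected, rel=1e-9)
        assert trip.trip_time == pytest.approx(100.0 + 83.8)
        assert trip.ee == -1.0

    def test_empty_trip_rejected(self):
        with pytest.raises(ValidationError):
            en.trip_energetics([], [], BEE_1G, CONTROL)

    def test_zero_duration_trip_rejected(self):
        events = [ev(0, 0, "rest")]
        with pytest.raises(ValidationError):
            self._run(events, BEE_1G)

    def test_currency_identity(self):
        events = [
            ev(0, 3_000, "fly"),
            ev(3_000, 6_000, "drink", LocomotorState.LANDED,
               Orientation.HORIZONTAL, "H1"),
        ]
        trip = self._run(events, BEE_SMALL)
        assert trip.ee == pytest.approx(
            trip.rer * trip.trip_time / trip.expenditure, rel=1e-12
        )

    def test_taste_excluded_from_intake(self):
        events = [ev(0, 2_000, "drink", LocomotorState.LANDED,
                     Orientation.HORIZONTAL, "H1"),
                  ev(20_000, 1_000, "rest")]
        trip = self._run(events, BEE_1G)
        assert trip.intake == 0.0
        assert trip.total_volume == 0.0
        assert trip.offload_time == 0.0

    def test_per_flower_cap_across_repeat_visits(self):
        # Two long drinking visits to the same flower in one trip cannot
        # yield more than the 15 uL reward in total.
        events = [
            ev(0, 60_000, "drink", LocomotorState.LANDED, Orientation.HORIZONTAL, "H1"),
            ev(75_000, 2_500, "drink", LocomotorState.LANDED, Orientation.HORIZONTAL, "H2"),
            ev(90_000, 60_000, "drink", LocomotorState.LANDED, Orientation.HORIZONTAL, "H1"),
        ]
        trip = self._run(events, BEE_1G)
        vols = dict(zip(["H1a", "H2", "H1b"], trip.visit_volumes))
        assert vols["H1a"] == pytest.approx(15.0)
        assert vols["H1b"] == pytest.approx(0.0)
        assert trip.total_volume == pytest.approx(15.0 + vols["H2"])

    def test_hover_costed_at_flight_rate_within_visit(self):
        events = [
            ev(0, 4_000, "drink", LocomotorState.HOVER, Orientation.VERTICAL, "V1"),
            ev(4_000, 4_000, "drink", LocomotorState.LANDED, Orientation.VERTICAL, "V1"),
        ]
        trip = self._run(events, BEE_SMALL, mass_updating=False)
        hover_cost, landed_cost = trip.event_costs
        assert hover_cost == pytest.approx(0.435 * 0.171 * 4.0, rel=1e-9)
        assert landed_cost == pytest.approx(0.034 * 0.171 * 4.0, rel=1e-9)

    def test_mass_updating_increases_late_costs(self):
        events = [
            ev(0, 10_000, "drink", LocomotorState.LANDED, Orientation.HORIZONTAL, "H1"),
            ev(25_000, 10_000, "fly"),
        ]
        with_update = self._run(events, BEE_SMALL)
        without = self._run(events, BEE_SMALL, mass_updating=False)
        # First visit costed at unladen mass either way; the fly event after
        # the drink is costlier once laden.
        assert with_update.event_costs[0] == pytest.approx(without.event_costs[0])
        assert with_update.event_costs[1] > without.event_costs[1]
        # Mass gain equals consumed solution mass.
        vol = with_update.total_volume
        rho = phys.sucrose_density(35.0)
        assert with_update.end_mass == pytest.approx(0.171 + vol * rho / 1000.0)

    def test_energy_conservation(self, small_dataset, params):
        ds = small_dataset
        bee_id = sorted(ds.bees)[0]
        bee = ds.bees[bee_id]
        treatment = STANDARD_TREATMENTS[bee.treatment]
        for trip_idx, events in ds.log.by_trip(bee_id, Phase.TEST).items():
            visits = aggregate_visits(events)
            trip = en.trip_energetics(events, visits, bee, treatment)
            # Intake equals the sum of per-visit energies.
            per_visit = sum(
                phys.energy_intake(v, treatment.concentration(visits[i].orientation))
                for i, v in enumerate(trip.visit_volumes)
            )
            assert trip.intake == pytest.approx(per_visit, rel=1e-9)
            # Expenditure equals event costs plus nest terms.
            nest = (
                phys.metabolic_power(trip.end_mass, "probe") * trip.offload_time
                + phys.metabolic_power(bee.unladen_mass, "probe") * 83.8
            )
            assert trip.expenditure == pytest.approx(
                sum(trip.event_costs) + nest, rel=1e-9
            )
            assert trip.ee >= -1.0


def make_two_trip_result(r_choices=(6, 4), drink_ms=3000):
    """Two trips with the given number of choices each; returns the analyzed
    bee-phase and the per-trip event counts."""
    events_by_trip = {}
    for trip, n in enumerate(r_choices, start=1):
        events = []
        t = 0
        for c in range(n):
            events.append(ev(t, 3000, "fly", trip=trip))
            t += 3000
            flower = f"H{c + 1:02d}"
            events.append(
                ev(t, drink_ms + 500 * trip, "drink", LocomotorState.LANDED,
                   Orientation.HORIZONTAL, flower, trip=trip)
            )
            t += drink_ms + 500 * trip + 11_000
        events_by_trip[trip] = events
    return en.analyze_bee_phase(
        events_by_trip, BEE_SMALL, CONTROL, Phase.TEST
    )


class TestWindowSeries:
    def test_single_trip_window_equals_trip_value(self):
        result = make_two_trip_result(r_choices=(10,))
        for metric in ("rer", "ee"):
            df = en.window_series(result, metric)
            assert len(df) == 1
            assert df.loc[0, "value"] == pytest.approx(
                getattr(result.trips[1], metric), rel=1e-12
            )
            assert bool(df.loc[0, "complete"])

    def test_cross_trip_event_weighted_mean(self):
        result = make_two_trip_result(r_choices=(6, 4))
        df = en.window_series(result, "rer")
        r1, r2 = result.trips[1].rer, result.trips[2].rer
        # 2 events per choice: 12 events at r1, 8 at r2.
        expected = (12 * r1 + 8 * r2) / 20
        assert df.loc[0, "value"] == pytest.approx(expected, rel=1e-12)
        assert r1 != r2

    def test_duration_weighting_switch(self):
        result = make_two_trip_result(r_choices=(6, 4))
        df = en.window_series(result, "rer", weighting="duration")
        events, ordinals, trips_arr, _ = en._assign_events_to_choices(result)
        durs = np.array([e.duration_s for e in events])
        vals = np.array([result.trips[t].rer for t in trips_arr])
        expected = np.average(vals, weights=durs)
        assert df.loc[0, "value"] == pytest.approx(expected, rel=1e-12)

    def test_partial_final_window_flagged(self):
        result = make_two_trip_result(r_choices=(6, 6))
        df = en.window_series(result, "rer")
        assert list(df["complete"]) == [True, False]
        assert df.loc[1, "n_choices"] == 2

    def test_handling_time_per_choice(self):
        result = make_two_trip_result(r_choices=(10,), drink_ms=3000)
        df = en.window_series(result, "handling_time")
        # Each choice contributes one 3.5 s drink; no other interactions.
        assert df.loc[0, "value"] == pytest.approx(3.5)

    def test_between_flight_time_per_choice(self):
        result = make_two_trip_result(r_choices=(10,))
        df = en.window_series(result, "between_flight_time")
        assert df.loc[0, "value"] == pytest.approx(3.0)

    def test_flat_series_for_constant_behavior(self):
        from beeforage.synthetic_data import (
            PolicySpec,
            SimulationConfig,
            simulate_treatment_group,
        )

        cfg = SimulationConfig(
            rng_seed=3,
            deterministic_timing=True,
            test_policies={
                t: PolicySpec(name="constant_p", p_vertical=0.0)
                for t in ("control", "low_difference", "high_difference")
            },
            familiarization_policies={
                t: PolicySpec(name="constant_p", p_vertical=0.0)
                for t in ("control", "low_difference", "high_difference")
            },
        )
        ds = simulate_treatment_group(cfg, TreatmentName.CONTROL, n_bees=1)
        bee_id = sorted(ds.bees)[0]
        bee = ds.bees[bee_id]
        result = en.analyze_bee_phase(
            ds.log.by_trip(bee_id, Phase.TEST), bee, CONTROL, Phase.TEST
        )
        df = en.window_series(result, "rer")
        complete = df[df["complete"]]["value"]
        assert complete.std() == pytest.approx(0.0, abs=1e-9)


class TestCounterfactual:
    def test_identity_map_reproduces_observed(self, small_dataset):
        ds = small_dataset
        bee_id = sorted(ds.bees)[0]
        bee = ds.bees[bee_id]
        treatment = STANDARD_TREATMENTS[bee.treatment]
        result = en.analyze_bee_phase(
            ds.log.by_trip(bee_id, Phase.TEST), bee, treatment, Phase.TEST
        )
        spec = en.CounterfactualSpec(
            target_treatment=treatment.name.value,
            donor_treatment=treatment.name.value,
            concentration_map={
                "vertical": treatment.conc_vertical,
                "horizontal": treatment.conc_horizontal,
            },
        )
        cf = en.counterfactual_energetics([result], spec)
        for metric in ("rer", "ee"):
            observed = en.window_series(result, metric)["value"].to_numpy()
            counter = cf[cf["metric"] == metric]["value"].to_numpy()
            np.testing.assert_allclose(counter, observed, rtol=0, atol=0)

    def test_substitution_scales_intake_by_sucrose_mass_ratio(self, small_dataset):
        # Control donors (35/35) mapped to 20% horizontal: with mass fixed at
        # unladen, volumes are unchanged (20% shares the 35% drinking model)
        # and each drink's energy scales by the closed-form ratio.
        ds = small_dataset
        bee_id = sorted(ds.bees)[0]
        bee = ds.bees[bee_id]
        by_trip = ds.log.by_trip(bee_id, Phase.TEST)
        base = en.analyze_bee_phase(
            by_trip, bee, CONTROL, Phase.TEST, mass_updating=False
        )
        swapped_treatment = Treatment(TreatmentName.HIGH_DIFFERENCE, 35.0, 20.0)
        swapped = en.analyze_bee_phase(
            by_trip, bee, swapped_treatment, Phase.TEST, mass_updating=False
        )
        ratio = (
            phys.sucrose_density(20.0) * 20.0
        ) / (phys.sucrose_density(35.0) * 35.0)
        for trip in base.trips:
            b, s = base.trips[trip], swapped.trips[trip]
            np.testing.assert_allclose(s.visit_volumes, b.visit_volumes, rtol=1e-12)
            horiz = [
                i for i, v in enumerate(base.visits)
                if v.trip_index == trip and v.orientation is Orientation.HORIZONTAL
            ]
            if b.intake > 0:
                # Every visit of a control bee is at 35%; horizontal drinks
                # scale by the ratio, vertical are unchanged.
                vols = b.visit_volumes
                trip_visits = [v for v in base.visits if v.trip_index == trip]
                expected = sum(
                    phys.energy_intake(
                        vol,
                        20.0 if v.orientation is Orientation.HORIZONTAL else 35.0,
                    )
                    for vol, v in zip(vols, trip_visits)
                )
                assert s.intake == pytest.approx(expected, rel=1e-12)
                h_energy = sum(
                    phys.energy_intake(vols[i], 35.0)
                    for i, v in enumerate(trip_visits)
                    if v.orientation is Orientation.HORIZONTAL
                )
                v_energy = b.intake - h_energy
                assert s.intake == pytest.approx(
                    v_energy + ratio * h_energy, rel=1e-12
                )
            del horiz

    def test_retained_concentration_leaves_vertical_unchanged(self, small_dataset):
        # Low-difference donors mapped to a scenario retaining 50% vertical:
        # vertical drink energies are identical (mass updating off).
        ds = small_dataset
        bee_id = sorted(ds.bees)[0]
        bee = ds.bees[bee_id]
        by_trip = ds.log.by_trip(bee_id, Phase.TEST)
        low = STANDARD_TREATMENTS[TreatmentName.LOW_DIFFERENCE]
        high = STANDARD_TREATMENTS[TreatmentName.HIGH_DIFFERENCE]
        a = en.analyze_bee_phase(by_trip, bee, low, Phase.TEST, mass_updating=False)
        b = en.analyze_bee_phase(by_trip, bee, high, Phase.TEST, mass_updating=False)
        for trip in a.trips:
            trip_visits = [v for v in a.visits if v.trip_index == trip]
            for i, v in enumerate(trip_visits):
                if v.orientation is Orientation.VERTICAL:
                    assert a.trips[trip].visit_volumes[i] == pytest.approx(
                        b.trips[trip].visit_volumes[i], rel=1e-12
                    )


class TestCostOfSlippery:
    @staticmethod
    def _series(values, metric="handling_time", window=9):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "bee_id": f"b{i}",
                    "metric": m,
                    "window_index": window,
                    "value": v,
                    "complete": True,
                }
                for m in (metric, "handling_energy" if metric == "handling_time" else "handling_time")
                for i, v in enumerate(values)
            ]
        )

    def test_identical_inputs_zero_cost(self):
        s = self._series([10.0, 12.0, 14.0])
        cost = en.cost_of_slippery(s, s)
        assert cost["delta_median_handling_time"] == 0.0
        assert cost["delta_median_handling_energy"] == 0.0

    def test_missing_window_lists_bees(self):
        import pandas as pd

        good = self._series([10.0, 12.0])
        extra = self._series([9.0], window=8)
        extra["bee_id"] = "b-missing"
        bad = pd.concat([self._series([10.0, 12.0]), extra])
        with pytest.raises(MissingWindowError, match="b-missing"):
            en.cost_of_slippery(good, bad)

    def test_hover_inflation_increases_time_cost(self):
        from beeforage.synthetic_data import SimulationConfig, simulate_treatment_group

        costs = []
        for overhead in (4.0, 12.0):
            cfg = SimulationConfig(rng_seed=5, hover_overhead_median_s=overhead)
            control = simulate_treatment_group(cfg, TreatmentName.CONTROL, n_bees=2)
            high = simulate_treatment_group(
                cfg, TreatmentName.HIGH_DIFFERENCE, n_bees=2
            )

            def series(ds):
                results = []
                for bee_id in sorted(ds.bees):
                    bee = ds.bees[bee_id]
                    results.append(
                        en.analyze_bee_phase(
                            ds.log.by_trip(bee_id, Phase.TEST), bee,
                            STANDARD_TREATMENTS[bee.treatment], Phase.TEST,
                        )
                    )
                return en.window_series_table(
                    results, metrics=("handling_time", "handling_energy")
                )

            cost = en.cost_of_slippery(series(control), series(high))
            costs.append(cost["delta_median_handling_time"])
        assert costs[1] > costs[0]


class TestRobustnessHarness:
    def test_load_independent_rates_preserve_conclusions(self, full_dataset):
        # Recomputing with mass fixed at unladen must not flip the
        # treatment-level ordering of final-window RER (low > high) nor the
        # benefit sign of the low-difference switch.
        ds = full_dataset

        def final_window_mean(metric, mass_updating):
            vals = {}
            for treatment in ("low_difference", "high_difference"):
                results = []
                for bee_id in sorted(ds.bees):
                    bee = ds.bees[bee_id]
                    if bee.treatment.value != treatment:
                        continue
                    results.append(
                        en.analyze_bee_phase(
                            ds.log.by_trip(bee_id, Phase.TEST), bee,
                            STANDARD_TREATMENTS[bee.treatment], Phase.TEST,
                            mass_updating=mass_updating,
                        )
                    )
                table = en.window_series_table(results, metrics=(metric,))
                sel = table[(table["window_index"] == 9) & table["complete"]]
                vals[treatment] = sel["value"].mean()
            return vals

        with_update = final_window_mean("rer", True)
        without = final_window_mean("rer", False)
        assert (
            with_update["low_difference"] > with_update["high_difference"]
        ) == (without["low_difference"] > without["high_difference"])
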