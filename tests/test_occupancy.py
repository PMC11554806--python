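"""Visit reconstruction, activity counting, and time budgets."""

import numpy as np
import pandas as pd
import pytest

from habsoc import (
    ProtocolWindows,
    SimConfig,
    compute_activity,
    compute_time_budget,
    reconstruct_visits,
    simulate_habitat,
    time_budgets,
)
from habsoc.io import events_frame
from .conftest import compartment_at, discretized_budget

HOUR = 3600.0


def visits_table(rows):
    return pd.DataFrame(rows, columns=["animal", "compartment", "start_s", "end_s"])


class TestReconstruction:
    def test_single_tube_crossing(self, apparatus, registry):
        # in compartment 1 since t=0; crossing tube 1 (antennas 1 then 2)
        events = events_frame([10.0, 12.0], [1, 2], ["TAG0000", "TAG0000"])
        visits, repairs = reconstruct_visits(
            events, apparatus, registry, session_end=20.0
        )
        visits = visits[visits["animal"] == "m00"]
        assert list(map(tuple, visits[["compartment", "start_s", "end_s"]].to_numpy())) \
            == [(1, 0.0, 10.0), (2, 12.0, 20.0)]
        assert repairs == []

    def test_lossless_channel_matches_ground_truth(self, sim_lossless):
        config, events, truth, visits, repairs = sim_lossless
        assert repairs == []
        a = visits.reset_index(drop=True)
        b = truth.visits.sort_values(["animal", "start_s"], ignore_index=True)
        pd.testing.assert_frame_equal(a, b)

    def test_back_out_of_tube_does_not_split_visit(self, apparatus, registry):
        # origin-side read, no destination read, then another origin-side read
        events = events_frame([5.0, 9.0, 11.0], [1, 1, 2],
                              ["TAG0000", "TAG0000", "TAG0000"])
        visits, _ = reconstruct_visits(events, apparatus, registry, session_end=15.0)
        v = visits[visits["animal"] == "m00"]
        assert list(v["compartment"]) == [1, 2]
        assert list(v["end_s"])[0] == 9.0  # visit ends at the final exit read

    def test_nonadjacent_jump_truncates_and_logs(self, apparatus, registry):
        # reads place the animal in compartment 1, then suddenly compartment 3
        events = events_frame([10.0, 30.0], [1, 4], ["TAG0000", "TAG0000"])
        assert apparatus.antenna_compartment(1) == 1
        assert apparatus.antenna_compartment(4) == 3
        visits, repairs = reconstruct_visits(events, apparatus, registry,
                                             session_end=40.0)
        v = visits[visits["animal"] == "m00"]
        assert list(map(tuple, v[["compartment", "start_s", "end_s"]].to_numpy())) \
            == [(1, 0.0, 10.0), (3, 30.0, 40.0)]
        assert [r.kind for r in repairs] == ["truncated_visit"]

    def test_dropped_reads_bounded_misassignment(self, apparatus):
        """With 5% dropped reads, misassigned dwell stays under
        2 x (dropped reads) x (median inter-read gap)."""
        base = dict(n_animals=10, seed=11)
        ev_full, truth = simulate_habitat(SimConfig(p_det=1.0, **base))
        ev_lossy, truth_lossy = simulate_habitat(SimConfig(p_det=0.95, **base))
        # identical dynamics, only the detection channel differs
        pd.testing.assert_frame_equal(truth.visits, truth_lossy.visits)
        n_dropped = len(ev_full) - len(ev_lossy)
        assert n_dropped > 0
        duration = SimConfig(**base).protocol().duration_s
        visits, _ = reconstruct_visits(ev_lossy, apparatus, truth.registry,
                                       session_end=duration)
        grid = np.arange(0.0, duration, 1.0) + 0.5
        misassigned = 0.0
        gaps = []
        for animal in truth.registry.animal_ids:
            ct = compartment_at(truth.visits[truth.visits["animal"] == animal], grid)
            cr = compartment_at(visits[visits["animal"] == animal], grid)
            misassigned += float(((cr != 0) & (ct != 0) & (cr != ct)).sum())
        for animal in truth.registry.animals:
            t = ev_lossy.loc[ev_lossy["tag"] == animal.tag, "time_s"].to_numpy()
            gaps.append(np.diff(t))
        median_gap = float(np.median(np.concatenate(gaps)))
        assert misassigned < 2.0 * n_dropped * median_gap

    def test_deterministic(self, apparatus, sim_lossless):
        config, events, truth, visits, _ = sim_lossless
        again, _ = reconstruct_visits(events, apparatus, truth.registry,
                                      session_end=config.protocol().duration_s)
        pd.testing.assert_frame_equal(visits, again)

    def test_zero_event_animal_warns(self, apparatus, registry):
        events = events_frame([1.0, 2.0], [1, 2], ["TAG0000", "TAG0000"])
        with pytest.warns(UserWarning, match="no antenna events"):
            visits, _ = reconstruct_visits(events, apparatus, registry)
        assert set(visits["animal"]) == {"m00"}

    def test_events_before_session_start_rejected(self, apparatus, registry):
        events = events_frame([-1.0, 2.0], [1, 2], ["TAG0000", "TAG0000"])
        with pytest.raises(ValueError, match="before session start"):
            reconstruct_visits(events, apparatus, registry)


class TestActivity:
    def test_counts_visit_starts_per_bin(self, protocol):
        visits = visits_table([
            ("a", 1, 0.0, 1 * HOUR),          # ongoing at t=0: not counted
            ("a", 2, 1 * HOUR, 2 * HOUR),
            ("a", 1, 2 * HOUR, 13 * HOUR),
            ("a", 2, 13 * HOUR, 84 * HOUR),
        ])
        act = compute_activity(visits, protocol)
        by_bin = act.set_index("bin")["visits"]
        assert by_bin[0] == 2 and by_bin[1] == 1 and by_bin[2:].sum() == 0

    def test_no_visits_gives_zero_rows_not_missing(self, protocol):
        visits = visits_table([("a", 1, 0.0, 84 * HOUR)])
        act = compute_activity(visits, protocol, animals=["a", "b"])
        assert len(act) == 2 * protocol.n_bins
        assert (act["visits"] == 0).all()

    def test_matches_true_transition_counts_at_perfect_detection(self, sim_lossless):
        config, events, truth, visits, _ = sim_lossless
        protocol = config.protocol()
        act = compute_activity(visits, protocol, animals=truth.registry.animal_ids)
        expected = truth.transition_counts(protocol)
        pd.testing.assert_frame_equal(act, expected)

    def test_circadian_modulation_visible(self, sim_lossless):
        """Dark-phase bins (even) show more visits than light bins (odd)."""
        config, events, truth, visits, _ = sim_lossless
        act = compute_activity(visits, config.protocol())
        per_bin = act.groupby("bin")["visits"].mean()
        assert per_bin[[0, 2, 4, 6]].min() > 2 * per_bin[[1, 3, 5]].max()


class TestTimeBudget:
    def test_full_window_single_compartment(self):
        visits = visits_table([("a", 1, 0.0, 12 * HOUR)])
        t = compute_time_budget(visits, (0.0, 12 * HOUR))
        assert np.array_equal(t, [1.0, 0.0, 0.0, 0.0])

    def test_split_window(self):
        visits = visits_table([("a", 2, 0.0, 6 * HOUR), ("a", 3, 6 * HOUR, 12 * HOUR)])
        t = compute_time_budget(visits, (0.0, 12 * HOUR))
        assert np.array_equal(t, [0.0, 0.5, 0.5, 0.0])

    def test_zero_length_window_rejected(self):
        visits = visits_table([("a", 1, 0.0, 10.0)])
        with pytest.raises(ValueError):
            compute_time_budget(visits, (5.0, 5.0))

    def test_transit_fraction_conserved(self, sim_lossless):
        """Sum of budget fractions equals 1 minus the true transit fraction."""
        config, events, truth, visits, _ = sim_lossless
        w = (24 * HOUR, 36 * HOUR)
        for animal in truth.registry.animal_ids[:4]:
            t = compute_time_budget(visits, w, animal=animal)
            tv = truth.visits[truth.visits["animal"] == animal]
            dwell = np.clip(tv["end_s"], *w) - np.clip(tv["start_s"], *w)
            transit = (w[1] - w[0]) - float(dwell[dwell > 0].sum())
            assert t.sum() == pytest.approx(1.0 - transit / (w[1] - w[0]), abs=1e-12)
            assert t.sum() < 1.0

    def test_sweep_matches_discretized_oracle(self, sim_lossless):
        config, events, truth, visits, _ = sim_lossless
        w = (24 * HOUR, 72 * HOUR)
        window_len = w[1] - w[0]
        for animal in truth.registry.animal_ids:
            sweep = compute_time_budget(visits, w, animal=animal)
            disc = discretized_budget(visits, animal, w)
            sub = visits[visits["animal"] == animal]
            n_bounds = ((sub["start_s"] < w[1]) & (sub["end_s"] > w[0])).sum() * 2
            bound = 2.0 * n_bounds * 1.0 / window_len
            assert np.abs(sweep - disc).max() <= bound

    def test_cohort_budgets_shape(self, sim_lossless, protocol):
        config, events, truth, visits, _ = sim_lossless
        tb = time_budgets(visits, protocol.testing_windows_s())
        assert len(tb) == 10 * 4
        assert ((tb[["t1", "t2", "t3", "t4"]].sum(axis=1) <= 1.0 + 1e-12)).all()
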