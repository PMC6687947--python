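import numpy as np
import pytest

from oracles import brute_force_parsimony, random_topology, topology_to_newick
from ycnv.events import (
    AMBIGUOUS,
    DECREASE,
    INCREASE,
    EventSet,
    TreeError,
    attach_tip_states,
    clade_mode_labeling,
    classify_events,
    count_events,
    filter_events,
    min_event_labeling,
    read_tree,
    scale_confident_histogram,
)


def tree_with_states(newick: str, states: dict[str, int]):
    return attach_tip_states(read_tree(newick), states)


class TestReadTree:
    def test_parse_round_trip(self):
        phylo = tree_with_states("((A:1,B:2):1,C:3);", {"A": 8, "B": 8, "C": 6})
        assert sorted(phylo.tip_labels()) == ["A", "B", "C"]
        assert phylo.tip_states == {"A": 8, "B": 8, "C": 6}

    def test_unknown_state_id_listed(self):
        phylo = read_tree("((A:1,B:2):1,C:3);")
        with pytest.raises(TreeError, match="Z"):
            attach_tip_states(phylo, {"A": 8, "Z": 9})

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_tree("((A:1,A:2):1,C:3);")

    def test_write_read_preserves_topology_and_lengths(self, tmp_path):
        phylo = read_tree("((A:1.25,B:2.5):0.75,(C:3.125,D:1.0):2.0);")
        path = tmp_path / "t.nwk"
        phylo.write(path)
        back = read_tree(path)
        assert sorted(back.tip_labels()) == sorted(phylo.tip_labels())
        assert back.total_branch_length() == pytest.approx(
            phylo.total_branch_length(), abs=1e-9
        )
        assert back.tree.as_string(schema="newick") == phylo.tree.as_string(
            schema="newick"
        )

    def test_prune_missing_tips(self):
        phylo = read_tree("((A:1,B:2):1,C:3);")
        pruned = attach_tip_states(phylo, {"A": 8, "B": 9}, prune_missing=True)
        assert sorted(pruned.tip_labels()) == ["A", "B"]


class TestMinEventLabeling:
    def test_constant_states_zero_events(self):
        phylo = tree_with_states("((A:1,B:1):1,(C:1,D:1):1);", dict.fromkeys("ABCD", 8))
        assignment, count = min_event_labeling(phylo)
        assert count == 0
        assert all(s == 8 for s in assignment.states.values())

    def test_single_change_on_edge_to_d(self):
        phylo = tree_with_states(
            "((A:1,B:1):1,(C:1,D:1):1);", {"A": 8, "B": 8, "C": 8, "D": 6}
        )
        assignment, count = min_event_labeling(phylo)
        assert count == 1
        events = classify_events(assignment, phylo)
        assert len(events) == 1
        event = events.events[0]
        assert event.child == "D"
        assert (event.parent_state, event.child_state) == (8, 6)
        assert event.direction == DECREASE
        assert event.magnitude == 2
        assert event.confident

    def test_sister_pair_increase(self):
        # tip values from a real sister pair: 11 vs 8 under an 8-state outgroup
        phylo = tree_with_states(
            "((HG02020:1,HG02032:1):1,OUT:1);",
            {"HG02020": 11, "HG02032": 8, "OUT": 8},
        )
        assignment, count = min_event_labeling(phylo)
        assert count == 1
        events = classify_events(assignment, phylo)
        event = events.events[0]
        assert event.child == "HG02020"
        assert event.direction == INCREASE
        assert event.magnitude == 3
        assert event.confident

    def test_requires_two_tips(self):
        phylo = tree_with_states("(A:1);", {"A": 8})
        with pytest.raises(TreeError):
            min_event_labeling(phylo)

    def test_requires_complete_states(self):
        phylo = read_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(TreeError):
            min_event_labeling(phylo)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n_tips = int(rng.integers(3, 9))
            topo = random_topology(n_tips, rng)
            lo = int(rng.integers(4, 10))
            states = {
                f"t{i + 1}": int(rng.integers(lo, lo + 4)) for i in range(n_tips)
            }
            phylo = tree_with_states(topology_to_newick(topo), states)
            _, count = min_event_labeling(phylo)
            assert count == brute_force_parsimony(topo, states)

    def test_multifurcation_handled(self):
        phylo = tree_with_states(
            "(A:1,B:1,C:1,D:1);", {"A": 8, "B": 8, "C": 8, "D": 10}
        )
        _, count = min_event_labeling(phylo)
        assert count == 1

    def test_not_more_than_true_event_count(self):
        from ycnv.simulate import evolve_cn, simulate_tree

        for seed in range(5):
            phylo = simulate_tree(30, seed=seed, total_generations_target=50_000)
            truth = evolve_cn(phylo, 1e-3, seed=100 + seed)
            _, count = min_event_labeling(truth.phylo)
            assert count <= truth.total_events


class TestCladeModeLabeling:
    def test_majority_state(self):
        phylo = tree_with_states(
            "((A:1,B:1,C:1):1,D:1);", {"A": 8, "B": 8, "C": 10, "D": 8}
        )
        assignment = clade_mode_labeling(phylo)
        internal = next(k for k in assignment.states if k.startswith("in") and k != "in0")
        assert assignment.states[internal] == 8

    def test_tie_resolves_toward_parent(self):
        phylo = tree_with_states(
            "((A:1,B:1):1,(C:1,D:1):1);", {"A": 8, "B": 10, "C": 10, "D": 10}
        )
        assignment = clade_mode_labeling(phylo)
        # root is 10 (global mode); the (A,B) clade ties {8,10} -> parent's 10
        labels = {k: v for k, v in assignment.states.items() if k.startswith("in")}
        assert set(labels.values()) == {10}

    def test_event_count_at_least_parsimony(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            topo = random_topology(20, rng)
            states = {f"t{i + 1}": int(rng.integers(6, 11)) for i in range(20)}
            phylo = tree_with_states(topology_to_newick(topo), states)
            _, parsimony_count = min_event_labeling(phylo)
            clade_events = classify_events(clade_mode_labeling(phylo), phylo)
            assert len(clade_events) >= parsimony_count


class TestClassifyEvents:
    def test_zero_event_tree_empty(self):
        phylo = tree_with_states("((A:1,B:1):1,C:1);", dict.fromkeys("ABC", 8))
        assignment, _ = min_event_labeling(phylo)
        assert classify_events(assignment, phylo).events == ()

    def test_chain_with_ambiguous_midpoint(self):
        # root fixed at 8 by two tips; a unifurcating chain to a 10-tip
        # leaves the intermediate node ambiguous between 8 and 10
        phylo = tree_with_states(
            "((A:1,B:1):1,(C:1):1);", {"A": 8, "B": 8, "C": 10}
        )
        assignment, count = min_event_labeling(phylo)
        assert count == 1
        events = classify_events(assignment, phylo)
        assert len(events) == 1
        event = events.events[0]
        assert event.direction == AMBIGUOUS
        assert not event.confident

    def test_direction_totals_sum(self):
        rng = np.random.default_rng(11)
        topo = random_topology(25, rng)
        states = {f"t{i + 1}": int(rng.integers(5, 12)) for i in range(25)}
        phylo = tree_with_states(topology_to_newick(topo), states)
        _, events = count_events(phylo)
        counts = events.direction_counts()
        assert counts[INCREASE] + counts[DECREASE] + counts[AMBIGUOUS] == events.total

    def test_confident_implies_unambiguous_direction(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            topo = random_topology(12, rng)
            states = {f"t{i + 1}": int(rng.integers(5, 10)) for i in range(12)}
            phylo = tree_with_states(topology_to_newick(topo), states)
            _, events = count_events(phylo)
            for e in events.events:
                if e.confident:
                    assert e.direction != AMBIGUOUS
                assert e.magnitude >= 1


def _event(parent, child, confident=True):
    from ycnv.events import Event

    direction = (
        INCREASE if child > parent else DECREASE if child < parent else AMBIGUOUS
    )
    return Event(
        child="x", parent_state=parent, child_state=child,
        magnitude=abs(child - parent), direction=direction, confident=confident,
    )


class TestFilterEvents:
    def test_kept_within_rules(self):
        events = EventSet((_event(8, 6),))
        kept = filter_events(events, min_magnitude=2, cn_range=(5, 12))
        assert len(kept) == 1

    def test_small_magnitude_dropped(self):
        events = EventSet((_event(8, 7),))
        assert len(filter_events(events, min_magnitude=2)) == 0

    def test_out_of_range_endpoint_dropped(self):
        events = EventSet((_event(13, 8),))
        assert len(filter_events(events, min_magnitude=2, cn_range=(5, 12))) == 0

    def test_matches_list_comprehension_oracle(self, rng):
        events = EventSet(
            tuple(
                _event(int(rng.integers(3, 15)), int(rng.integers(3, 15)))
                for _ in range(40)
                if True
            )
        )
        events = EventSet(tuple(e for e in events.events if e.magnitude >= 1))
        kept = filter_events(events, min_magnitude=2, cn_range=(5, 12))
        oracle = [
            e
            for e in events.events
            if e.magnitude >= 2
            and 5 <= e.parent_state <= 12
            and 5 <= e.child_state <= 12
        ]
        assert list(kept.events) == oracle
        assert len(kept) <= len(events)


class TestScaleConfidentHistogram:
    def test_integer_scale_factor(self):
        assert scale_confident_histogram({1: 10, 2: 5}, 30) == {1: 20, 2: 10}

    def test_largest_remainder_sums_exactly(self):
        out = scale_confident_histogram({1: 1, 2: 1, 3: 1}, 10)
        assert sum(out.values()) == 10
        assert all(abs(v - 10 / 3) <= 1 for v in out.values())

    def test_reported_event_size_classes(self):
        # published scaled size classes (1..5-copy decreases, 1..4 increases)
        published = {
            -1: 227, -2: 54, -3: 16, -4: 13, -5: 3,
            1: 185, 2: 42, 3: 19, 4: 4,
        }
        # a confident histogram proportional to these classes, 176 events
        confident = scale_confident_histogram(published, sum(published.values()))
        confident = {
            k: v for k, v in scale_confident_histogram(published, 563).items()
        }
        total = sum(published.values())
        scaled_down = {
            k: round(v * 176 / total) for k, v in published.items()
        }
        # repair rounding drift to land exactly on 176
        drift = 176 - sum(scaled_down.values())
        scaled_down[-1] += drift
        out = scale_confident_histogram(scaled_down, 562)
        for k, v in published.items():
            assert abs(out[k] - v) <= 2, (k, out[k], v)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            scale_confident_histogram({}, 10)

    def test_total_below_confident_rejected(self):
        with pytest.raises(ValueError):
            scale_confident_histogram({1: 10}, 5)
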