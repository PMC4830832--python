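"""Synchronous engine: stepping, attractors, oracle agreement, sampling."""

import numpy as np
import pytest

from boolfate.core import (BooleanNetwork, NetworkStructureError,
                           SimulationConfig, brute_force_attractors,
                           network_from_sif, path_to_attractor_matrix,
                           robustness_sample, run_to_attractor,
                           synchronous_step, write_logic, write_sif)
from boolfate.synth import random_network


def test_identity_self_loop():
    net = BooleanNetwork(["A"], {"A": "A"})
    assert synchronous_step(net, {"A": 1}) == {"A": 1}


def test_negative_loop_hand_truth_table(negative_loop):
    assert synchronous_step(negative_loop, {"A": 1, "B": 0}) == {"A": 1, "B": 1}


def test_step_is_deterministic(negative_loop):
    state = {"A": 0, "B": 1}
    results = {tuple(sorted(synchronous_step(negative_loop, state).items()))
               for _ in range(5)}
    assert len(results) == 1


def test_unknown_parent_rejected_at_construction():
    with pytest.raises(NetworkStructureError):
        BooleanNetwork(["A"], {"A": "A & Ghost"})


def test_input_node_defaults_to_self_maintenance():
    net = BooleanNetwork(["S", "X"], {"X": "S"})
    assert synchronous_step(net, {"S": 1, "X": 0}) == {"S": 1, "X": 1}
    assert synchronous_step(net, {"S": 0, "X": 1}) == {"S": 0, "X": 0}


def test_constant_rules_reach_fixed_point_fast():
    net = BooleanNetwork(["A", "B"], {"A": "0", "B": "0"})
    traj = run_to_attractor(net, {"A": 1, "B": 1})
    assert traj.attractor_start <= 1
    assert traj.attractor.cycle == [{"A": 0, "B": 0}]


def test_negative_loop_four_cycle(negative_loop):
    """The hand-enumerated orbit 11 -> 01 -> 00 -> 10 -> 11."""
    traj = run_to_attractor(negative_loop, {"A": 1, "B": 1})
    assert traj.attractor_start == 0
    cycle = traj.attractor.cycle
    assert len(cycle) == 4
    expected = [{"A": 1, "B": 1}, {"A": 0, "B": 1},
                {"A": 0, "B": 0}, {"A": 1, "B": 0}]
    assert cycle == expected


def test_cycle_property_step_of_last_yields_first(negative_loop):
    traj = run_to_attractor(negative_loop, {"A": 1, "B": 1})
    assert synchronous_step(negative_loop, traj.attractor.cycle[-1]) == \
        traj.attractor.cycle[0]


def test_max_steps_exceeded_raises(negative_loop):
    with pytest.raises(RuntimeError):
        # config bound of 1 cannot contain the 4-cycle
        run_to_attractor(negative_loop, {"A": 1, "B": 1},
                         SimulationConfig(max_steps=1))


def test_clamp_invariance(negative_loop):
    clamped = negative_loop.with_clamps({"A": 1})
    traj = run_to_attractor(clamped, {"A": 0, "B": 0})
    assert all(s["A"] == 1 for s in traj.states)


def test_termination_bound():
    """Any 3-node network halts within 2^3 + 1 recorded states."""
    for seed in range(10):
        _, truth = random_network(5, 5, inhibition_fraction=0.5, seed=seed)
        net = truth.network
        for start in range(2 ** net.n_nodes):
            init = {n: (start >> i) & 1 for i, n in enumerate(net.nodes)}
            traj = run_to_attractor(net, init)
            assert len(traj.states) <= 2 ** net.n_nodes + 1


# -- brute force oracle ----------------------------------------------------


def test_not_gate_single_two_cycle_attractor():
    net = BooleanNetwork(["A"], {"A": "!A"})
    atts = brute_force_attractors(net)
    assert len(atts) == 1
    assert len(atts[0].cycle) == 2
    assert atts[0].basin_fraction == 1.0


def test_two_self_activators_four_fixed_points():
    net = BooleanNetwork(["A", "B"], {"A": "A", "B": "B"})
    atts = brute_force_attractors(net)
    assert len(atts) == 4
    assert all(a.is_fixed_point for a in atts)
    assert all(a.basin_fraction == 0.25 for a in atts)


def test_brute_force_refuses_large_networks():
    net = BooleanNetwork([f"N{i}" for i in range(20)], {})
    with pytest.raises(ValueError):
        brute_force_attractors(net)


def test_brute_force_consistent_with_single_trajectories():
    """Attractors found exhaustively match run_to_attractor from every state."""
    for seed in range(5):
        _, truth = random_network(5, 5, inhibition_fraction=0.4, seed=seed)
        net = truth.network
        exact = {a.key(net.nodes) for a in brute_force_attractors(net)}
        walked = set()
        for start in range(2 ** net.n_nodes):
            init = {n: (start >> i) & 1 for i, n in enumerate(net.nodes)}
            walked.add(run_to_attractor(net, init).attractor.key(net.nodes))
        assert walked == exact


def test_basin_fractions_sum_to_one():
    _, truth = random_network(8, 10, inhibition_fraction=0.3, seed=11)
    atts = brute_force_attractors(truth.network)
    assert np.isclose(sum(a.basin_fraction for a in atts), 1.0)


# -- robustness sampling ---------------------------------------------------


def test_unique_attractor_sampled_at_frequency_one():
    net = BooleanNetwork(["A", "B"], {"A": "0", "B": "A"})
    atts = robustness_sample(net, {}, 500, SimulationConfig(seed=0))
    assert len(atts) == 1
    assert atts[0].basin_fraction == 1.0


def test_sampling_reproducible_for_fixed_seed(negative_loop):
    a = robustness_sample(negative_loop, {}, 1000, SimulationConfig(seed=42))
    b = robustness_sample(negative_loop, {}, 1000, SimulationConfig(seed=42))
    assert [(x.key(["A", "B"]), x.basin_fraction) for x in a] == \
        [(x.key(["A", "B"]), x.basin_fraction) for x in b]


def test_sampled_basins_converge_to_exact():
    """Sampled fractions approach exact basins within binomial error."""
    _, truth = random_network(7, 9, inhibition_fraction=0.3, seed=5)
    net = truth.network
    exact = {a.key(net.nodes): a.basin_fraction
             for a in brute_force_attractors(net)}
    n = 100_000
    sampled = robustness_sample(net, {}, n, SimulationConfig(seed=1))
    for att in sampled:
        p = exact[att.key(net.nodes)]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(att.basin_fraction - p) <= 3 * se + 1e-9


def test_sampling_respects_clamps():
    net = BooleanNetwork(["S", "X"], {"X": "S"})
    atts = robustness_sample(net, {"S": 1}, 200, SimulationConfig(seed=0))
    assert len(atts) == 1
    assert atts[0].cycle[0] == {"S": 1, "X": 1}


# -- path matrix and I/O ---------------------------------------------------


def test_path_matrix_fixed_point_single_column():
    net = BooleanNetwork(["A"], {"A": "A"})
    traj = run_to_attractor(net, {"A": 1})
    m = path_to_attractor_matrix(traj)
    assert m.shape == (1, 1)
    assert m.loc["A", 0] == 1


def test_path_matrix_reproduces_enumerated_orbit(negative_loop):
    traj = run_to_attractor(negative_loop, {"A": 1, "B": 1})
    m = path_to_attractor_matrix(traj)
    assert list(m[0]) == [1, 1]  # the orbit entry state


def test_sif_logic_round_trip(tmp_path, negative_loop):
    sif = tmp_path / "net.sif"
    logic = tmp_path / "net.logic"
    write_sif(negative_loop, sif)
    write_logic(negative_loop, logic)
    back = network_from_sif(sif, logic)
    assert set(back.nodes) == {"A", "B"}
    traj = run_to_attractor(back, {"A": 1, "B": 1})
    assert len(traj.attractor.cycle) == 4


def test_sif_default_logic_synthesis(tmp_path):
    sif = tmp_path / "net.sif"
    sif.write_text("S\t1\tX\nY\t-1\tX\n")
    net = network_from_sif(sif)
    assert synchronous_step(net, {"S": 1, "X": 0, "Y": 0})["X"] == 1
    assert synchronous_step(net, {"S": 1, "X": 0, "Y": 1})["X"] == 0


def test_sif_parse_error_reports_line(tmp_path):
    sif = tmp_path / "bad.sif"
    sif.write_text("A\t1\tB\nA\tB\n")
    with pytest.raises(ValueError, match=":2"):
        network_from_sif(sif)
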