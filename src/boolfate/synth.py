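"""Synthetic ground truths and noisy time-course datasets.

The generators reproduce the statistical structure the analysis pipeline
assumes, so that topology training, discretization and clustering can be
validated against a known answer without any external download:

* :func:`random_network` builds a connected stimulus->measured ground-truth
  network wrapped in a prior-knowledge network that also carries decoy
  optional edges (the recovery task: find the planted optional edges);
* :func:`simulate_timecourse_expression` renders Boolean trajectories of the
  ground truth as continuous [0,1] values with additive Gaussian noise,
  per stimulus/inhibitor condition, on the study-style timepoint grid;
* :func:`planted_cluster_matrix` emits pulse-like (rise and return) and
  sustained (rise and hold) expression shapes with known cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BooleanNetwork
from .optimize import TrainingDataset
from .pkn import PKNEdge, PriorKnowledgeNetwork

__all__ = ["GroundTruth", "NoiseModel", "random_network",
           "simulate_timecourse_expression", "planted_cluster_matrix",
           "DEFAULT_TIMEPOINTS"]

# the study-style sampling grid, in hours
DEFAULT_TIMEPOINTS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the [0, 1] rendered signal."""

    sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class GroundTruth:
    """A true network, the PKN optional-edge truth labels, and scenarios."""

    network: BooleanNetwork
    pkn: PriorKnowledgeNetwork
    optional_edge_labels: dict[tuple, bool]
    scenarios: list[dict] = field(default_factory=list)

    def true_optional_edges(self) -> set[tuple]:
        return {e for e, truly in self.optional_edge_labels.items() if truly}


def random_network(
    n_nodes: int,
    n_edges: int,
    inhibition_fraction: float = 0.0,
    seed: int = 0,
    n_decoys: int = 0,
    n_inhibitor_conditions: int = 4,
) -> tuple[PriorKnowledgeNetwork, GroundTruth]:
    """Random ground-truth network embedded in a PKN with decoy edges.

    The ground truth consists of a random activating arborescence rooted at
    the single stimulus (these backbone edges are fixed in the PKN) plus
    ``n_edges - (n_nodes - 1)`` planted optional edges whose sources sit
    strictly shallower than the target's backbone parent, so every planted
    edge visibly accelerates its target in the unperturbed condition.  The
    PKN additionally carries ``n_decoys`` optional edges absent from the
    truth.  All non-stimulus nodes are measured.  Scenarios are the stimulus
    alone plus single-node inhibitions of the highest-out-degree internal
    nodes, which expose edges masked by OR-redundancy.
    """
    n_extra = n_edges - (n_nodes - 1)
    if n_nodes < 3 or n_extra < 0:
        raise ValueError("need n_nodes >= 3 and n_edges >= n_nodes - 1")
    max_extra = (n_nodes - 1) * (n_nodes - 2) // 2
    if n_extra + n_decoys > max_extra:
        raise ValueError("edge count infeasible without duplicates")
    rng = np.random.default_rng(seed)
    names = ["S"] + [f"N{i}" for i in range(1, n_nodes)]
    depth = {"S": 0}
    parent = {}
    backbone = []
    for i, node in enumerate(names[1:], start=1):
        p = names[int(rng.integers(0, i))]
        parent[node] = p
        depth[node] = depth[p] + 1
        backbone.append(PKNEdge(p, 1, node, fixed=True))

    existing = {(e.source, e.target) for e in backbone}
    candidates = []
    for u in names:
        for v in names[1:]:
            if u == v or (u, v) in existing or depth[u] >= depth[parent[v]]:
                continue
            candidates.append((u, v))
    rng.shuffle(candidates)

    def _stim_trajectory(edge_set, steps):
        bn = PriorKnowledgeNetwork(
            {n: ("stimulus" if n == "S" else "measured") for n in names},
            edge_set).to_boolean_network()
        clamped = bn.with_clamps({"S": 1})
        X = np.zeros((1, bn.n_nodes), dtype=np.uint8)
        X[0, bn.nodes.index("S")] = 1
        rows = []
        for _ in range(steps):
            X = clamped.step_matrix(X)
            rows.append(X.copy())
        return np.concatenate(rows)

    def _all_consequential(edge_set):
        steps = n_nodes + 2
        full = _stim_trajectory(backbone + edge_set, steps)
        for i in range(len(edge_set)):
            reduced = backbone + edge_set[:i] + edge_set[i + 1:]
            if np.array_equal(full, _stim_trajectory(reduced, steps)):
                return False
        return True

    planted = []
    used_targets: set[str] = set()
    for u, v in candidates:
        if len(planted) == n_extra:
            break
        # one planted edge per target keeps planted edges from OR-shadowing
        # each other; the simulation check below rejects any candidate that
        # leaves some planted edge without a visible trajectory effect
        if v in used_targets:
            continue
        sign = -1 if rng.random() < inhibition_fraction else 1
        candidate_edge = PKNEdge(u, sign, v, fixed=False)
        if not _all_consequential(planted + [candidate_edge]):
            continue
        planted.append(candidate_edge)
        existing.add((u, v))
        used_targets.add(v)
    if len(planted) < n_extra:
        raise ValueError("not enough shallow sources for the requested extra edges")

    decoy_pool = [(u, v) for u in names for v in names[1:]
                  if u != v and (u, v) not in existing]
    rng.shuffle(decoy_pool)
    if len(decoy_pool) < n_decoys:
        raise ValueError("not enough node pairs for the requested decoys")
    decoys = []
    for u, v in decoy_pool[:n_decoys]:
        sign = -1 if rng.random() < inhibition_fraction else 1
        decoys.append(PKNEdge(u, sign, v, fixed=False))

    roles = {"S": "stimulus"}
    roles.update({n: "measured" for n in names[1:]})
    pkn = PriorKnowledgeNetwork(roles, backbone + planted + decoys)
    truth_net = pkn.to_boolean_network(backbone + planted)

    labels = {(e.source, e.sign, e.target): True for e in planted}
    labels.update({(e.source, e.sign, e.target): False for e in decoys})

    outdeg: dict[str, int] = {}
    for e in backbone + planted:
        outdeg[e.source] = outdeg.get(e.source, 0) + 1
    internals = sorted((n for n in names[1:] if outdeg.get(n, 0) > 0),
                       key=lambda n: (-outdeg[n], n))
    scenarios = [{"name": "S", "stimuli": ["S"], "inhibitors": []}]
    for node in internals[:n_inhibitor_conditions]:
        scenarios.append({"name": f"S+{node}i", "stimuli": ["S"],
                          "inhibitors": [node]})
    truth = GroundTruth(network=truth_net, pkn=pkn,
                        optional_edge_labels=labels, scenarios=scenarios)
    return pkn, truth


def simulate_timecourse_expression(
    truth: GroundTruth,
    timepoints=DEFAULT_TIMEPOINTS,
    noise: NoiseModel = NoiseModel(),
    measured_nodes=None,
) -> TrainingDataset:
    """Noisy continuous rendering of the ground truth's Boolean dynamics.

    Each scenario starts from all-off with stimuli clamped on and inhibited
    nodes clamped off, takes one synchronous step per sorted timepoint, and
    reports value = state + N(0, sd) clipped to [0, 1] for every measured
    node; with sd = 0 the values binarize back to the simulated states.
    """
    times = np.asarray(sorted(timepoints), dtype=float)
    if times.size == 0:
        raise ValueError("timepoints must be non-empty")
    net = truth.network
    if measured_nodes is None:
        measured_nodes = truth.pkn.measured
    rng = np.random.default_rng(noise.seed)
    rows = []
    conditions = {}
    for scenario in truth.scenarios:
        name = scenario["name"]
        conditions[name] = {"stimuli": scenario["stimuli"],
                            "inhibitors": scenario["inhibitors"]}
        clamped = net.with_clamps(
            {**{s: 1 for s in scenario["stimuli"]},
             **{i: 0 for i in scenario["inhibitors"]}})
        index = {n: i for i, n in enumerate(net.nodes)}
        X = np.zeros((1, net.n_nodes), dtype=np.uint8)
        for s in scenario["stimuli"]:
            X[0, index[s]] = 1
        for t in times:
            X = clamped.step_matrix(X)
            for node in measured_nodes:
                value = float(X[0, index[node]])
                if noise.sd > 0:
                    value = float(np.clip(value + rng.normal(0, noise.sd), 0, 1))
                rows.append({"node": node, "condition": name,
                             "time_h": t, "value": value})
    measurements = pd.DataFrame(rows, columns=["node", "condition", "time_h", "value"])
    return TrainingDataset(conditions=conditions, measurements=measurements)


def _pulse(times, peak, width):
    return np.exp(-((times - peak) / width) ** 2)

def _sustained(times, onset, rate=1.0):
    return 1.0 / (1.0 + np.exp(-rate * (times - onset)))


def planted_cluster_matrix(
    n_clusters: int,
    genes_per_cluster: int,
    timepoints=DEFAULT_TIMEPOINTS,
    noise_sd: float = 0.05,
    seed: int = 0,
    amplitude: float = 3.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix of pulse-like and sustained response templates.

    Cluster templates alternate between a short pulse (rise and return, with
    shifting peak time) and a sustained response (rise and hold, with
    shifting onset); every second template pair is sign-flipped so that
    down-regulated shapes occur too.  Returns the genes x timepoints log2
    fold-change matrix and the planted integer labels.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    times = np.asarray(sorted(timepoints), dtype=float)
    rng = np.random.default_rng(seed)
    templates = []
    for c in range(n_clusters):
        kind = c % 2
        shift = c // 2
        sign = -1.0 if (c // 4) % 2 else 1.0
        if kind == 0:
            base = _pulse(times, peak=2.0 + 3.0 * shift, width=1.5 + shift)
        else:
            base = _sustained(times, onset=3.0 + 4.0 * shift)
        templates.append(sign * amplitude * base)
    rows, labels, names = [], [], []
    for c, template in enumerate(templates):
        for g in range(genes_per_cluster):
            rows.append(template + rng.normal(0, noise_sd, size=times.size))
            labels.append(c)
            names.append(f"gene_c{c}_{g}")
    matrix = pd.DataFrame(rows, index=names, columns=times)
    return matrix, pd.Series(labels, index=names, name="cluster")
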