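"""Topology training of a prior-knowledge network by genetic algorithm.

Candidate models are bitstrings over the PKN's optional edges (fixed edges
are always present).  Each candidate is synthesized into a Boolean network
with the default logic convention (OR over activating parents, AND NOT over
inhibiting parents), simulated per training condition from the all-off state
with stimuli clamped on and inhibited nodes clamped off, one synchronous
update step per sorted measurement timepoint.  The fitness is the mean
squared deviation between simulated 0/1 node activities and the [0,1]
training values, plus a small size penalty proportional to the fraction of
optional edges kept, so that equally fitting sparser models win.

The optimization is repeated over many independently seeded runs and an edge
enters the consensus when it is retained in at least a configured fraction
of the runs, which yields a sparse network of robust edges.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pkn import PKNEdge, PriorKnowledgeNetwork

__all__ = ["TrainingDataset", "GAConfig", "OptimizationResult",
           "score_model", "ga_optimize", "consensus_network"]


@dataclass
class TrainingDataset:
    """Perturbation conditions plus condition x timepoint x node values.

    ``conditions`` maps a condition label to its stimulus and inhibitor node
    sets; ``measurements`` is a long table with columns node, condition,
    time_h, value (values already discretized to [0, 1]).
    """

    conditions: dict[str, dict]
    measurements: pd.DataFrame

    def __post_init__(self):
        vals = self.measurements["value"].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("training values must lie in [0, 1]")
        unknown = set(self.measurements["condition"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"measurements reference unknown condition(s) {sorted(unknown)}")

    def timepoints(self, condition: str) -> np.ndarray:
        sub = self.measurements[self.measurements["condition"] == condition]
        return np.sort(sub["time_h"].unique())

    def measured_nodes(self) -> list[str]:
        return sorted(self.measurements["node"].unique())


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm controls.

    The two stopping controls are a wall-time cap per run and a relative
    fitness plateau: a run ends when the best fitness has improved by less
    than ``rel_tolerance`` (relatively) over ``patience`` generations.
    """

    max_cpu_time_s: float = 100.0
    rel_tolerance: float = 0.01
    runs: int = 100
    retention_fraction: float = 0.7
    size_penalty_weight: float = 1e-4
    population_size: int = 50
    mutation_rate: float = 0.01
    crossover_rate: float = 0.5
    elitism: int = 1
    patience: int = 10
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.retention_fraction <= 1:
            raise ValueError("retention_fraction must lie in (0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class OptimizationResult:
    pkn: PriorKnowledgeNetwork
    optional_edges: list[PKNEdge]
    best_bitstrings: list[np.ndarray]
    fitness_traces: list[list[float]]
    edge_frequency: dict[tuple, float]
    consensus: PriorKnowledgeNetwork

    def consensus_edges(self) -> list[PKNEdge]:
        return list(self.consensus.edges)


def _measurement_arrays(pkn: PriorKnowledgeNetwork, data: TrainingDataset):
    """Pre-index the training table: per condition, node indices and a
    (n_nodes_measured, n_timepoints) value matrix."""
    prepared = {}
    for cond, spec in data.conditions.items():
        sub = data.measurements[data.measurements["condition"] == cond]
        if sub.empty:
            continue
        times = np.sort(sub["time_h"].unique())
        wide = sub.pivot_table(index="node", columns="time_h", values="value")
        wide = wide.reindex(columns=times)
        prepared[cond] = {
            "stimuli": list(spec.get("stimuli", [])),
            "inhibitors": list(spec.get("inhibitors", [])),
            "nodes": list(wide.index),
            "values": wide.to_numpy(dtype=float),
            "n_steps": len(times),
        }
    return prepared


def _simulate_candidate(pkn, edges, prepared):
    """Simulated 0/1 values of measured nodes at each aligned step."""
    net = pkn.to_boolean_network(edges)
    index = {n: i for i, n in enumerate(net.nodes)}
    out = {}
    for cond, info in prepared.items():
        X = np.zeros((1, net.n_nodes), dtype=np.uint8)
        clamped = net.with_clamps(
            {**{s: 1 for s in info["stimuli"]}, **{i: 0 for i in info["inhibitors"]}})
        for s in info["stimuli"]:
            X[0, index[s]] = 1
        node_idx = [index[n] for n in info["nodes"]]
        sim = np.empty((len(node_idx), info["n_steps"]), dtype=float)
        for step in range(info["n_steps"]):
            X = clamped.step_matrix(X)
            sim[:, step] = X[0, node_idx]
        out[cond] = sim
    return out


def score_model(
    bitstring,
    pkn: PriorKnowledgeNetwork,
    data: TrainingDataset,
    config: GAConfig = GAConfig(),
    _prepared=None,
) -> float:
    """Fitness of a candidate edge selection (lower is better).

    Deviation term: mean squared difference between simulated activities and
    the training values over all (condition, node, timepoint) entries.  A
    measured node with no selected incoming edge stays off and contributes
    its squared data value.  Size term: ``size_penalty_weight`` times the
    fraction of optional edges selected.
    """
    bits = np.asarray(bitstring, dtype=np.uint8)
    optional = pkn.optional_edges()
    if len(bits) != len(optional):
        raise ValueError(
            f"bitstring length {len(bits)} != {len(optional)} optional edges")
    edges = pkn.fixed_edges() + [e for e, b in zip(optional, bits) if b]
    prepared = _prepared if _prepared is not None else _measurement_arrays(pkn, data)
    sims = _simulate_candidate(pkn, edges, prepared)
    sq_sum, count = 0.0, 0
    for cond, info in prepared.items():
        diff = sims[cond] - info["values"]
        mask = ~np.isnan(info["values"])
        sq_sum += float((diff[mask] ** 2).sum())
        count += int(mask.sum())
    mse = sq_sum / count if count else 0.0
    size = bits.sum() / len(bits) if len(bits) else 0.0
    return mse + config.size_penalty_weight * float(size)


def _ga_single_run(pkn, data, config, rng, prepared, cache):
    n_bits = len(pkn.optional_edges())
    pop = rng.integers(0, 2, size=(config.population_size, n_bits), dtype=np.uint8)

    def fitness(bits):
        key = bits.tobytes()
        if key not in cache:
            cache[key] = score_model(bits, pkn, data, config, _prepared=prepared)
        return cache[key]

    fits = np.array([fitness(ind) for ind in pop])
    best_bits = pop[int(np.argmin(fits))].copy()
    trace = [float(fits.min())]
    start = time.process_time()
    stalled_ref = fits.min()
    stalled_for = 0
    for _ in range(config.max_generations):
        if time.process_time() - start > config.max_cpu_time_s:
            break
        order = np.argsort(fits)
        elite = pop[order[: config.elitism]].copy()
        # tournament selection (size 2)
        idx = rng.integers(0, len(pop), size=(len(pop), 2))
        winners = np.where(fits[idx[:, 0]] <= fits[idx[:, 1]], idx[:, 0], idx[:, 1])
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, len(children) - 1, 2):
            if rng.random() < config.crossover_rate:
                mask = rng.integers(0, 2, size=n_bits, dtype=np.uint8).astype(bool)
                a, b = children[i].copy(), children[i + 1].copy()
                children[i][mask], children[i + 1][mask] = b[mask], a[mask]
        # per-bit mutation
        flips = rng.random(children.shape) < config.mutation_rate
        children = children ^ flips.astype(np.uint8)
        children[: config.elitism] = elite
        pop = children
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = float(fits.min())
        if gen_best < trace[-1]:
            best_bits = pop[int(np.argmin(fits))].copy()
        trace.append(min(gen_best, trace[-1]))
        # plateau stopping on the best-so-far fitness
        denom = abs(stalled_ref) if stalled_ref else 1.0
        if (stalled_ref - trace[-1]) / denom < config.rel_tolerance:
            stalled_for += 1
            if stalled_for >= config.patience:
                break
        else:
            stalled_ref = trace[-1]
            stalled_for = 0
    return best_bits, trace


def consensus_network(pkn: PriorKnowledgeNetwork,
                      edge_frequency: dict[tuple, float],
                      retention_fraction: float) -> PriorKnowledgeNetwork:
    """Fixed edges plus optional edges retained in >= the given run fraction."""
    kept = list(pkn.fixed_edges())
    for e in pkn.optional_edges():
        if edge_frequency.get((e.source, e.sign, e.target), 0.0) >= retention_fraction:
            kept.append(e)
    used = {e.source for e in kept} | {e.target for e in kept} | pkn.designated
    nodes = {n: r for n, r in pkn.nodes.items() if n in used}
    return PriorKnowledgeNetwork(nodes, kept)


def ga_optimize(
    pkn: PriorKnowledgeNetwork,
    data: TrainingDataset,
    config: GAConfig = GAConfig(),
) -> OptimizationResult:
    """Multi-run GA training with consensus edge retention.

    Each run draws its generator from a sub-seed derived from the master
    seed and the run index, so the full consensus is bit-reproducible.
    """
    optional = pkn.optional_edges()
    prepared = _measurement_arrays(pkn, data)
    cache: dict[bytes, float] = {}
    best_bits, traces = [], []
    if optional:
        for run in range(config.runs):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, run)))
            bits, trace = _ga_single_run(pkn, data, config, rng, prepared, cache)
            best_bits.append(bits)
            traces.append(trace)
        counts = np.sum(best_bits, axis=0) / config.runs
        freq = {(e.source, e.sign, e.target): float(c)
                for e, c in zip(optional, counts)}
    else:
        freq = {}
    cons = consensus_network(pkn, freq, config.retention_fraction)
    return OptimizationResult(
        pkn=pkn, optional_edges=optional, best_bitstrings=best_bits,
        fitness_traces=traces, edge_frequency=freq, consensus=cons)
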