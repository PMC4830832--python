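"""Packaged PC12 networks and perturbation scenarios.

Ships two fixtures: the prior-knowledge network for NGF-driven PC12
differentiation (63 nodes, 109 signed interactions) and the trained,
re-expanded final Boolean model (32 nodes, 52 interactions).  Both are
synthetic reconstructions assembled from the primary literature on PC12
signaling; transcription choices are logged in the fixture file headers.

The four perturbation scenarios clamp the NGF stimulus on and optionally
clamp an inhibited kinase off for the whole run (inhibitors are applied
before stimulation, so inhibition is sustained, not transient): NGF alone,
NGF+MEKi (the lumped MEK_ERK node), NGF+JNKi, and NGF+PI3Ki.  Cells are
called differentiated when a strict majority of the late differentiation
genes is active together with uPAR signaling in the attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .core import (Attractor, BooleanNetwork, SimulationConfig, Trajectory,
                   network_from_sif, run_to_attractor)
from .pkn import PriorKnowledgeNetwork

__all__ = ["ScenarioSpec", "PhenotypeCall", "SCENARIOS", "LATE_GENES",
           "UPAR_NODE", "UPAR_FEEDBACK_EDGES", "load_fixture",
           "differentiation_readout", "run_scenario", "feedback_knockout",
           "bistability_check", "load_training_foldchanges"]

#: Late, differentiation-related transcripts used for the majority readout
#: (immediate-early genes such as Egr1, Fos or Cited2 are excluded: they
#: respond to ERK alone and do not report the late differentiation program).
LATE_GENES = ("Klf2", "Klf5", "Klf6", "Klf10", "Maff", "Npy")

#: The node reporting uPAR signaling activity.
UPAR_NODE = "uPAR"

#: Autocrine uPAR/integrin feedback loop: AP1-driven uPA expression,
#: plasmin-mediated MMP activation, integrin engagement and FAK signaling
#: back into RAS/JNK.
UPAR_FEEDBACK_EDGES = (
    ("AP1", "uPA"), ("uPA", "uPAR"), ("uPA", "Plasmin"),
    ("Plasmin", "Mmp10"), ("Mmp10", "Itga1"), ("Itga1", "FAK"),
    ("FAK", "RAS"), ("FAK", "JNK"), ("Mmp10", "RAS"),
)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    stimuli: tuple[str, ...] = ("NGF",)
    inhibited: tuple[str, ...] = ()

    def clamps(self) -> dict[str, int]:
        return {**{s: 1 for s in self.stimuli}, **{i: 0 for i in self.inhibited}}


SCENARIOS: dict[str, ScenarioSpec] = {
    "NGF": ScenarioSpec("NGF"),
    "NGF+MEKi": ScenarioSpec("NGF+MEKi", inhibited=("MEK_ERK",)),
    "NGF+JNKi": ScenarioSpec("NGF+JNKi", inhibited=("JNK",)),
    "NGF+PI3Ki": ScenarioSpec("NGF+PI3Ki", inhibited=("PI3K",)),
}


@dataclass
class PhenotypeCall:
    differentiation: bool
    active_late_genes: list[str]
    upar_active: bool
    attractor: Attractor


def _data_path(name: str):
    return resources.files("boolfate.data") / name


def load_fixture(which: str):
    """Load a packaged network: ``"pkn"`` or ``"final"``.

    Returns a :class:`PriorKnowledgeNetwork` for the PKN and a simulatable
    :class:`BooleanNetwork` for the final model.
    """
    if which == "pkn":
        with resources.as_file(_data_path("pkn_synthetic.sif")) as sif, \
                resources.as_file(_data_path("pkn_synthetic_nodes.tsv")) as ann:
            return PriorKnowledgeNetwork.from_files(sif, ann)
    if which == "final":
        with resources.as_file(_data_path("final_model_synthetic.sif")) as sif, \
                resources.as_file(_data_path("final_model_synthetic_logic.txt")) as logic:
            return network_from_sif(sif, logic)
    raise ValueError(f"unknown fixture {which!r}; expected 'pkn' or 'final'")


def load_training_foldchanges():
    """Packaged fold-change training table (long format DataFrame)."""
    import pandas as pd
    with resources.as_file(_data_path("training_foldchange_synthetic.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def _active_in_attractor(attractor: Attractor, node: str) -> bool:
    return all(state[node] == 1 for state in attractor.cycle)


def differentiation_readout(
    attractor: Attractor,
    late_gene_set=LATE_GENES,
    upar_node: str = UPAR_NODE,
) -> PhenotypeCall:
    """Strict-majority differentiation call on an attractor.

    Differentiation requires strictly more than half of the late genes to be
    active together with the uPAR signaling node; an exact half (even-sized
    set) is conservatively called non-differentiated.
    """
    late_gene_set = list(late_gene_set)
    if not late_gene_set:
        raise ValueError("late_gene_set must be non-empty")
    missing = [g for g in late_gene_set + [upar_node]
               if g not in attractor.cycle[0]]
    if missing:
        raise ValueError(f"node(s) {missing} not in the attractor states")
    active = [g for g in late_gene_set if _active_in_attractor(attractor, g)]
    upar = _active_in_attractor(attractor, upar_node)
    call = len(active) > len(late_gene_set) / 2 and upar
    return PhenotypeCall(differentiation=call, active_late_genes=active,
                         upar_active=upar, attractor=attractor)


def run_scenario(
    spec: ScenarioSpec | str,
    network: BooleanNetwork | None = None,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[Trajectory, PhenotypeCall]:
    """Run one perturbation scenario from the all-off state.

    All nodes start at 0, the scenario clamps are applied (NGF on,
    inhibited kinase off), the network is iterated to its attractor, and
    the differentiation phenotype is called.
    """
    if isinstance(spec, str):
        spec = SCENARIOS[spec]
    net = load_fixture("final") if network is None else network
    clamped = net.with_clamps(spec.clamps())
    initial = {n: 0 for n in net.nodes}
    trajectory = run_to_attractor(clamped, initial, config)
    return trajectory, differentiation_readout(trajectory.attractor)


def feedback_knockout(
    network: BooleanNetwork | None = None,
    feedback_edges=UPAR_FEEDBACK_EDGES,
) -> PhenotypeCall:
    """Phenotype under NGF after removing the uPAR/integrin feedback edges."""
    net = load_fixture("final") if network is None else network
    for src, dst in feedback_edges:
        net = net.remove_edge(src, dst)
    _, phenotype = run_scenario(SCENARIOS["NGF"], network=net)
    return phenotype


def bistability_check(network: BooleanNetwork | None = None) -> dict:
    """Resting vs differentiation attractors and feedback-sustained memory.

    Reports (i) the resting attractor from all-off without NGF, (ii) the
    differentiation attractor with NGF clamped on, and (iii) whether the
    differentiation state persists once NGF is withdrawn after the attractor
    is reached — with the autocrine feedback intact and with it removed.
    Persistent memory with feedback and loss without it is the operational
    signature of positive-feedback bistability.
    """
    net = load_fixture("final") if network is None else network
    all_off = {n: 0 for n in net.nodes}

    resting = run_to_attractor(net, all_off).attractor
    ngf_traj, ngf_call = run_scenario(SCENARIOS["NGF"], network=net)
    diff_state = dict(ngf_traj.attractor.cycle[0])

    def persists(candidate: BooleanNetwork) -> bool:
        released = dict(diff_state)
        released["NGF"] = 0  # withdraw the stimulus, no clamps
        att = run_to_attractor(candidate, released).attractor
        try:
            return differentiation_readout(att).differentiation
        except ValueError:
            return False

    no_feedback = net
    for src, dst in UPAR_FEEDBACK_EDGES:
        no_feedback = no_feedback.remove_edge(src, dst)

    return {
        "resting_attractor": resting,
        "resting_is_all_off": all(v == 0 for v in resting.cycle[0].values()),
        "differentiation_attractor": ngf_traj.attractor,
        "differentiation_on": ngf_call.differentiation,
        "memory_with_feedback": persists(net),
        "memory_without_feedback": persists(no_feedback),
    }
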