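"""Regenerate the packaged PC12 network fixtures.

Builds the synthetic-reconstruction fixtures (prior-knowledge network,
final Boolean model, training fold-change table), asserting the expected
node/edge counts and the final model's scenario dynamics before writing.
"""
import os

import numpy as np

from boolfate.core import BooleanNetwork, run_to_attractor, SimulationConfig
from boolfate.pkn import PKNEdge, PriorKnowledgeNetwork

DATA = os.path.join(os.path.dirname(__file__), "..", "src", "boolfate", "data")
os.makedirs(DATA, exist_ok=True)

# ---------------- final model: 32 nodes, 52 edges ----------------
FINAL_LOGIC = [
    ("NGF", "NGF"),
    ("RAS", "NGF | Mmp10 | FAK"),
    ("MEK_ERK", "RAS | PLC"),
    ("PI3K", "NGF"),
    ("AKT", "PI3K"),
    ("JNK", "NGF | FAK"),
    ("PLC", "NGF | Npy1r"),
    ("FAK", "Itga1"),
    ("uPA", "AP1"),
    ("Plasmin", "uPA"),
    ("Mmp10", "Plasmin"),
    ("Itga1", "Mmp10"),
    ("uPAR", "uPA"),
    ("Fosl1", "MEK_ERK"),
    ("Fos", "MEK_ERK"),
    ("Junb", "MEK_ERK & JNK"),
    ("Jund", "MEK_ERK & JNK"),
    ("AP1", "Fosl1 & Jund & !Zfp36"),
    ("Egr1", "MEK_ERK"),
    ("Klf2", "JNK | uPAR"),
    ("Klf4", "MEK_ERK & !GrowthArrest"),
    ("Btg2", "MEK_ERK & !GrowthArrest"),
    ("Zfp36", "MEK_ERK & !GrowthArrest"),
    ("GrowthArrest", "GrowthArrest | Klf4 | Btg2"),
    ("Klf5", "uPAR & AP1"),
    ("Klf6", "JNK | AP1"),
    ("Klf10", "AKT & JNK"),
    ("Maff", "AKT & JNK"),
    ("Cited2", "MEK_ERK"),
    ("Npy", "AP1"),
    ("Npy1r", "Npy"),
    ("CellDifferentiation", "uPAR & Klf5 & Npy"),
]

net = BooleanNetwork([n for n, _ in FINAL_LOGIC], dict(FINAL_LOGIC))
edges = net.edges()
assert net.n_nodes == 32, net.n_nodes
assert len(edges) == 52, len(edges)

# dynamics sanity
def scenario(clamps):
    init = {n: 0 for n in net.nodes}
    traj = run_to_attractor(net.with_clamps(clamps), init, SimulationConfig(max_steps=500))
    att = traj.attractor
    assert att.is_fixed_point
    return traj, att.cycle[0]

traj, ngf = scenario({"NGF": 1})
assert ngf["CellDifferentiation"] == 1
for g in ("Klf4", "Btg2", "Zfp36"):
    assert ngf[g] == 0
    assert any(s[g] == 1 for s in traj.states[: traj.attractor_start])
_, meki = scenario({"NGF": 1, "MEK_ERK": 0})
assert meki["CellDifferentiation"] == 0
_, jnki = scenario({"NGF": 1, "JNK": 0})
assert jnki["CellDifferentiation"] == 0
late = ["Klf2", "Klf5", "Klf6", "Klf10", "Maff", "Npy", "Egr1", "Cited2"]
assert all(jnki[g] == 0 for g in ["Klf2", "Klf5", "Klf6", "Klf10", "Maff", "Npy"])
_, pi3ki = scenario({"NGF": 1, "PI3K": 0})
assert pi3ki["CellDifferentiation"] == 1
diff_nodes = sorted(n for n in net.nodes if ngf[n] != pi3ki[n])
assert diff_nodes == sorted(["PI3K", "AKT", "Maff", "Klf10"]), diff_nodes
# AP1 delay via Zfp36
first_on = lambda t, n: next(i for i, s in enumerate(t.states) if s[n] == 1)
no_delay = net.remove_edge("Zfp36", "AP1").with_clamps({"NGF": 1})
traj2 = run_to_attractor(no_delay, {n: 0 for n in net.nodes}, SimulationConfig(max_steps=500))
assert first_on(traj, "AP1") > first_on(traj2, "AP1")
# majority readout numbers
assert sum(ngf[g] for g in late) == 8 and sum(pi3ki[g] for g in late) == 6
assert sum(meki[g] for g in late) == 4 and sum(jnki[g] for g in late) == 2

HEADER = """# Final Boolean model of NGF-driven PC12 differentiation (synthetic reconstruction).
# 32 nodes, 52 interactions. Transcription choices:
# - MEK and ERK are lumped as MEK_ERK (compressed linear transition).
# - Transient genes Klf4/Btg2/Zfp36 are shut off by a latching GrowthArrest
#   effect node (auto-inhibition once their growth-arrest effect is mediated);
#   Zfp36 additionally delays AP1 assembly (AP1 = Fosl1 & Jund & !Zfp36).
# - Autocrine positive feedback: AP1 -> uPA -> plasmin -> Mmp10 -> Itga1 ->
#   FAK -> RAS/JNK, plus AP1 -> Npy -> Npy1r -> PLC -> MEK_ERK.
# - CellDifferentiation requires uPAR signaling together with late genes.
"""

with open(os.path.join(DATA, "final_model_synthetic.sif"), "w") as fh:
    fh.write(HEADER)
    for s, sign, t in edges:
        fh.write(f"{s}\t{sign}\t{t}\n")
with open(os.path.join(DATA, "final_model_synthetic_logic.txt"), "w") as fh:
    fh.write(HEADER)
    for n, expr in FINAL_LOGIC:
        fh.write(f"{n} = {expr}\n")

# ---------------- PKN: 63 nodes, 109 edges ----------------
F = True
P = [
    ("NGF", 1, "TrkA"), ("TrkA", 1, "SHC"), ("TrkA", 1, "SRC"),
    ("SHC", 1, "GRB2"), ("GRB2", 1, "SOS"), ("SOS", 1, "RAS"),
    ("NGF", 1, "RAS", F), ("NGF", 1, "PI3K", F), ("NGF", 1, "PLC", F),
    ("RAS", 1, "RAF"), ("RAF", 1, "MEK"), ("RAS", 1, "MEK", F),
    ("PLC", 1, "MEK", F), ("MEK", 1, "ERK"), ("ERK", 1, "RSK"),
    ("RSK", 1, "CREB"), ("ERK", 1, "ELK1"), ("ERK", 1, "SRF"),
    ("ELK1", 1, "Fos"), ("SRF", 1, "Fos"), ("CREB", 1, "Fos"),
    ("Dusp6", -1, "ERK"),
    ("PI3K", 1, "PDK1"), ("PDK1", 1, "AKT"), ("PI3K", 1, "AKT"),
    ("PTEN", -1, "PI3K"), ("AKT", 1, "CREB"), ("AKT", 1, "Maff"),
    ("AKT", 1, "Klf10"),
    ("RAS", 1, "MEKK1"), ("MEKK1", 1, "MKK4"), ("MEKK1", 1, "MKK7"),
    ("MKK4", 1, "JNK"), ("MKK7", 1, "JNK"), ("MKK4", 1, "P38"),
    ("P38", 1, "MK2"), ("MK2", 1, "Zfp36"),
    ("ERK", 1, "Junb", F), ("JNK", 1, "Junb", F),
    ("ERK", 1, "Jund", F), ("JNK", 1, "Jund", F),
    ("P38", 1, "Atf3"), ("JNK", 1, "Atf3"),
    ("PLC", 1, "PKC"), ("PKC", 1, "RAF"), ("NPY1R", 1, "PLC"),
    ("Npy", 1, "NPY1R"),
    ("Fosl1", 1, "AP1", F), ("Jund", 1, "AP1", F), ("Fos", 1, "AP1"),
    ("Junb", 1, "AP1"), ("Zfp36", -1, "AP1"), ("Atf3", -1, "AP1"),
    ("ERK", 1, "Fosl1"), ("ERK", 1, "Egr1"), ("JNK", 1, "Egr1"),
    ("ERK", 1, "Klf4"), ("ERK", 1, "Btg2"), ("JNK", 1, "Btg2"),
    ("ERK", 1, "Zfp36"), ("JNK", 1, "Klf2"), ("JNK", 1, "Klf6"),
    ("ERK", 1, "Cited2"), ("ERK", 1, "Dusp6"), ("JNK", 1, "Fosl1"),
    ("AP1", 1, "Npy", F), ("AP1", 1, "Plau"), ("AP1", 1, "Plaur"),
    ("AP1", 1, "Serpine1"), ("AP1", 1, "Plat"), ("AP1", 1, "Vgf"),
    ("AP1", 1, "Gadd45a"), ("AP1", 1, "Dclk1"), ("AP1", 1, "Klf5"),
    ("AP1", 1, "Mmp3"),
    ("Plau", 1, "Plasmin"), ("Plat", 1, "Plasmin"),
    ("Plasminogen", 1, "Plasmin"), ("Serpine1", -1, "Plasmin"),
    ("Plasmin", 1, "Mmp3"), ("Plasmin", 1, "Mmp10"),
    ("Mmp3", 1, "Itga1"), ("Mmp10", 1, "Itga1"), ("Mmp10", 1, "RAS", F),
    ("Plaur", 1, "Itga1"), ("Itga1", 1, "ITGB1"), ("ITGB1", 1, "FAK"),
    ("Plaur", 1, "FAK"), ("FAK", 1, "SRC"), ("SRC", 1, "SHC"),
    ("FAK", 1, "SHC"), ("FAK", 1, "MEKK1"),
    ("AP1", 1, "IL6"), ("IL6", 1, "IL6R"), ("IL6R", 1, "STAT3"),
    ("STAT3", 1, "Klf5"), ("STAT3", 1, "Vgf"),
    ("AP1", 1, "TNFRSF12A"), ("TNFRSF12A", 1, "MEKK1"),
    ("CREB", 1, "Npy"), ("CREB", 1, "Vgf"),
    ("JNK", 1, "Cited2"), ("ERK", 1, "Klf2"), ("P38", 1, "Gadd45a"),
    ("AP1", 1, "Mmp10"), ("JNK", 1, "Klf4"), ("STAT3", 1, "Dclk1"),
    ("AP1", 1, "Itga1"), ("AP1", 1, "Fosl1"),
]
edges = [PKNEdge(e[0], e[1], e[2], len(e) == 4) for e in P]
assert len(edges) == 109, len(edges)
MEASURED = ["Fos", "Fosl1", "Junb", "Jund", "Egr1", "Klf2", "Klf4", "Klf5",
            "Klf6", "Klf10", "Maff", "Btg2", "Zfp36", "Cited2", "Atf3",
            "Dusp6", "Mmp3", "Mmp10", "Plat", "Plau", "Plaur", "Serpine1",
            "Itga1", "Npy", "Vgf", "Gadd45a", "Dclk1"]
roles = {}
names = []
for e in edges:
    for n in (e.source, e.target):
        if n not in roles:
            roles[n] = "hidden"
            names.append(n)
roles["NGF"] = "stimulus"
for n in ("MEK", "JNK", "PI3K"):
    roles[n] = "inhibited"
for n in MEASURED:
    assert n in roles, n
    roles[n] = "measured"
assert len(roles) == 63, len(roles)
pkn = PriorKnowledgeNetwork(roles, edges)
assert len(pkn.fixed_edges()) == 13

PKN_HEADER = """# Prior-knowledge network for NGF-driven PC12 differentiation
# (synthetic reconstruction): 63 nodes, 109 signed interactions.
# Columns: source <TAB> sign(+1/-1) <TAB> target <TAB> fixed(0/1).
# Transcription choices:
# - Fixed interactions (column 4 = 1): NGF->PI3K, NGF->RAS, NGF->PLC,
#   AP1->Npy, MEK/ERK & JNK -> Jund, MEK/ERK & JNK -> Junb,
#   Fosl1 & Jund -> AP1, Mmp10->RAS, RAS->MEK, PLC->MEK (the '&' gates are
#   realized as paired edges; logic synthesis is OR over activators).
# - Pathways: TrkA/SHC/GRB2/SOS adapters, RAF/MEK/ERK, PI3K/PDK1/AKT,
#   MEKK1/MKK4/MKK7 -> JNK and P38/MK2, PLC/PKC, uPA-plasmin-MMP-integrin-FAK
#   autocrine loop, IL6/STAT3, NPY/NPY1R, TNFRSF12A.
# - Roles are in the sidecar annotation table (stimulus NGF; inhibited MEK,
#   JNK, PI3K; 27 measured transcripts; linker nodes hidden).
"""
with open(os.path.join(DATA, "pkn_synthetic.sif"), "w") as fh:
    fh.write(PKN_HEADER)
    for e in edges:
        fh.write(f"{e.source}\t{e.sign}\t{e.target}\t{int(e.fixed)}\n")
with open(os.path.join(DATA, "pkn_synthetic_nodes.tsv"), "w") as fh:
    fh.write("# Node roles for pkn_synthetic.sif (synthetic reconstruction).\n")
    fh.write("node\trole\n")
    for n in names:
        fh.write(f"{n}\t{roles[n]}\n")

# ---------------- training fold-change table ----------------
rng = np.random.default_rng(20160414)
genes = ["Fosl1", "Fos", "Junb", "Jund", "Egr1", "Klf2", "Klf4", "Klf5",
         "Klf6", "Klf10", "Maff", "Btg2", "Zfp36", "Cited2", "Npy"]
times = [1, 2, 3, 4, 5, 6, 8, 12, 24]
conds = {"NGF": {}, "NGF+MEKi": {"MEK_ERK": 0}, "NGF+JNKi": {"JNK": 0},
         "NGF+PI3Ki": {"PI3K": 0}}
amp = {g: float(rng.uniform(3.0, 8.0)) for g in genes}
rows = []
for cond, extra in conds.items():
    cn = net.with_clamps({"NGF": 1, **extra})
    X = cn.state_to_row({n: 0 for n in net.nodes})
    X[0, cn._index["NGF"]] = 1
    for t in times:
        X = cn.step_matrix(X)
        for g in genes:
            s = int(X[0, cn._index[g]])
            fc = (1.0 + s * (amp[g] - 1.0)) * float(np.exp(rng.normal(0, 0.08)))
            rows.append((g, cond, t, round(fc, 4)))
with open(os.path.join(DATA, "training_foldchange_synthetic.tsv"), "w") as fh:
    fh.write("# Synthetic qRT-PCR-style linear fold changes (2^-ddCt scale) for the\n")
    fh.write("# final-model transcript nodes under NGF and kinase-inhibitor conditions,\n")
    fh.write("# rendered from the packaged final model with lognormal measurement noise.\n")
    fh.write("node\tcondition\ttime_h\tvalue\n")
    for r in rows:
        fh.write("\t".join(map(str, r)) + "\n")

print("fixtures written OK")
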