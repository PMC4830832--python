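# boolfate

Boolean-network modeling of the NGF-driven cell-fate decision in PC12 cells.

PC12 cells (a rat pheochromocytoma line) differentiate into sympathetic
neuron-like cells under nerve growth factor (NGF) but proliferate under EGF.
The decision is not made by the immediate kinase response alone: it depends
on late transcription and on autocrine feedback — AP1-driven expression of
the urokinase plasminogen activator (uPA) system feeds back through plasmin,
matrix metalloproteinases, integrin and FAK into MAPK and JNK signaling,
locking the cell into the differentiation program. `boolfate` implements
this biology as a deterministic synchronous Boolean model together with the
full analysis pipeline around it:

* **`boolfate.core`** — synchronous Boolean engine: named nodes with
  AND/OR/NOT rules, stimulus/inhibitor clamping, trajectory simulation with
  first-repeat attractor detection, exhaustive attractor/basin enumeration
  (the oracle), and vectorized random-initialization robustness sampling.
* **`boolfate.discretize`** — 2^-ddCt fold changes, per-node rescaling to
  [0, 1], the Hill transform f(x) = x^n / (x^n + k^n) (defaults n = 2,
  k = 0.5) and strict binarization.
* **`boolfate.pkn` / `boolfate.optimize`** — prior-knowledge network (PKN)
  compression (unobservable-node removal, hidden-chain collapse), topology
  training by a multi-run genetic algorithm against time-course data
  (fitness = MSE of simulated vs. measured node activities + size penalty),
  and consensus edge retention (default: kept in >= 70% of 100 runs).
* **`boolfate.expression`** — polynomial smoothing (order 5), top-regulation
  filtering (|log2 FC| > 1.7 at two consecutive same-sign timepoints),
  HiT-MDS embedding (maximizes distance correlation), bivariate skew-normal
  uniqueness p-values, CAST clustering (affinity threshold t = 0.8), and
  inverse-regulation detection (opposite significant slopes, r² > 0.7).
* **`boolfate.pc12`** — packaged fixtures: the 63-node / 109-edge PKN and
  the trained 32-node / 52-edge final model (synthetic reconstructions, see
  fixture headers), the four perturbation scenarios (NGF, NGF+MEKi,
  NGF+JNKi, NGF+PI3Ki), the differentiation readout, and the
  feedback-necessity / bistability analyses.
* **`boolfate.synth`** — ground-truth network generators and noisy
  continuous time-course rendering for recovery experiments.
* **`boolfate.cli`** — `boolfate simulate | optimize | analyze | synth`.

## Worked example

```python
from boolfate.pc12 import run_scenario

for name in ("NGF", "NGF+MEKi", "NGF+JNKi", "NGF+PI3Ki"):
    traj, ph = run_scenario(name)
    print(f"{name:10s} differentiation={ph.differentiation!s:5s} "
          f"steps_to_attractor={traj.attractor_start:2d} "
          f"late_genes_on={len(ph.active_late_genes)}/6 uPAR={ph.upar_active}")
```

prints

```
NGF        differentiation=True  steps_to_attractor=11 late_genes_on=6/6 uPAR=True
NGF+MEKi   differentiation=False steps_to_attractor= 3 late_genes_on=4/6 uPAR=False
NGF+JNKi   differentiation=False steps_to_attractor= 5 late_genes_on=0/6 uPAR=False
NGF+PI3Ki  differentiation=True  steps_to_attractor=11 late_genes_on=4/6 uPAR=True
```

Each scenario starts from the all-off state with NGF clamped on (plus the
inhibited kinase clamped off) and runs synchronous updates to a fixed point.
Differentiation requires a strict majority of the late genes (Klf2, Klf5,
Klf6, Klf10, Maff, Npy) active together with uPAR signaling: NGF and
NGF+PI3Ki differentiate, MEK or JNK inhibition blocks the uPAR feedback and
with it the phenotype. Under PI3K inhibition exactly four nodes (PI3K, AKT,
Maff, Klf10) differ from the plain NGF attractor. On the way to the NGF
attractor Klf4, Btg2 and Zfp36 switch on transiently and off again, with
Zfp36 delaying AP1 assembly by two update steps.

The same run from the command line:

```sh
boolfate simulate --scenario NGF --out runs/ngf
```

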