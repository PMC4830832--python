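# Methods

## The Boolean model and its update semantics

The model is a deterministic synchronous Boolean network: every node carries
a rule over its parents built from AND/OR/NOT, all nodes update
simultaneously, and a trajectory is followed until the first repeated state.
The segment from the first occurrence of the repeated state is the
attractor; a cycle of length one is a fixed point. Stimuli and inhibitors
are *clamps*: a clamped node holds its forced value (stimulus = 1,
inhibitor = 0) at every step regardless of its rule, modeling sustained
ligand exposure and pre-incubated kinase inhibitors. Input nodes — nodes
without parents — default to holding their value, so an unclamped stimulus
that starts "on" persists. Asynchronous updating, probabilistic rules and
ODE refinements are deliberately out of scope: the questions addressed here
(attractor identity, reachability order, feedback dependence) are posed and
answered in the synchronous semantics.

Attractor landscapes are computed three ways, and the implementations
cross-check each other in the test suite:

* single-trajectory simulation with hash-based first-repeat detection
  (memory proportional to trajectory length; 2^N + 1 steps always suffice);
* exhaustive enumeration for networks with at most 16 unclamped nodes: all
  2^k states are advanced in one vectorized step, and the successor table is
  resolved as a functional graph, giving exact attractors and basin
  fractions;
* Monte-Carlo robustness sampling: uniform random initial states over the
  unclamped nodes, vectorized over all samples. For small state spaces the
  sampler reuses the exhaustive successor table (exact per-sample
  resolution); for larger networks it iterates all samples in a batched
  matrix until the rows reach fixed points, falling back to scalar
  trajectory simulation for any rows still moving (cycles).

## The PC12 network fixtures

The package ships a 63-node / 109-edge prior-knowledge network (PKN) and a
32-node / 52-edge final model for NGF-driven PC12 differentiation. Both are
**synthetic reconstructions**: curated interaction tables matching the
published topology statistics and every main-text mechanism (the fixed
literature edges, the uPA/plasmin/MMP/integrin/FAK autocrine loop, the
NPY→PLC/PKC loop, MEK/ERK lumping, transient Klf4/Btg2/Zfp36 dynamics, the
Zfp36 delay on AP1), with the remaining interactions filled from the named
pathways. Each fixture header logs the transcription choices. The final
model's differentiation readout requires a strict majority of the late genes
(Klf2, Klf5, Klf6, Klf10, Maff, Npy) together with uPAR signaling;
immediate-early genes (Egr1, Fos, Fosl1, Cited2) are excluded from the
readout set because they respond to ERK alone.

**Transient genes.** Klf4, Btg2 and Zfp36 are growth-arrest / mRNA-decay
mediators that act once and switch off. A literal synchronous
self-inhibition (`X = trigger & !X`) oscillates forever under a sustained
trigger and would preclude the fixed-point attractor the model must reach.
The fixtures therefore implement "auto-inhibition once the effect is
mediated" with a latching effect node: `GrowthArrest = GrowthArrest | Klf4 |
Btg2`, and each transient gene is `trigger & !GrowthArrest`. The genes fire,
the latch engages one step later, and they shut off permanently — on-then-off
dynamics with a fixed-point attractor. `expand_network` applies the same
mechanism when asked to attach negative autoregulation to transient nodes.

**Bistability.** With NGF off the all-off state is a fixed point; with NGF
on every initial state reaches the differentiation attractor. The package
reports both readings of bistability: the resting/differentiation attractor
pair, and feedback-sustained memory — after the differentiation attractor is
reached, NGF is released and the simulation continues without clamps. With
the autocrine loop intact the differentiation state persists (the loop
replaces the receptor input into RAS and JNK); with the loop edges removed
the network decays to rest. Which reading the original analysis intended is
not fully specified; reporting both makes the claim testable either way.

**Edge removal semantics.** `BooleanNetwork.remove_edge(src, dst)` replaces
the source literal by the constant 0 in the target's rule (so `!src` terms
become 1) and simplifies. For the edges the analyses remove — OR-members of
activation rules and NOT-guards — this is exactly "delete the influence"; a
node whose rule collapses to constant 0 stays off, matching the all-off
initial conditions used throughout.

## Discretization

qRT-PCR fold changes (2^-ddCt) are rescaled per node to [0, 1] across all
conditions and timepoints jointly — per-node rescaling preserves the
cross-condition contrast that training exploits; whether rescaling should be
per node, per condition or global is not externally fixed, so the choice is
a documented switch. The Hill transform x^n/(x^n + k^n) (defaults n = 2,
k = 0.5) sharpens values toward 0/1; binarization is strictly greater-than
the 0.5 threshold. Because k = 0.5 makes `hill(x) > 0.5` equivalent to
`x > 0.5` for every n >= 1, the binarized pipeline output is provably
independent of the Hill coefficient — the coefficient-invariance check in
the acceptance script verifies this on the packaged training table.
Degenerate (constant) series map to all-zero with a warning rather than an
exception so whole-table processing never aborts.

## Topology training

Candidates are bitstrings over the PKN's optional edges; fixed edges are
always present. Logic is synthesized from edges as OR over activating
parents AND NOT each inhibiting parent. Each condition is simulated from
all-off with stimuli clamped on and inhibited nodes clamped off, taking
**one synchronous step per sorted measurement timepoint**; this
step-to-time alignment is the key modeling convention and is shared by the
synthetic data generator, so training and generation agree by construction.
Fitness is the mean squared deviation over all (condition, node, timepoint)
entries plus `size_penalty_weight` (default 1e-4) times the selected
fraction of optional edges — small enough never to trade fit for size,
large enough to drop edges with no dynamic effect.

The GA uses population 50, tournament selection (size 2), uniform crossover
(rate 0.5), per-bit mutation 0.01 and elitism 1; each run stops at a
wall-time cap (default 100 s) or when the best fitness improves by less than
the relative tolerance (default 0.01) over 10 consecutive generations.
Hyperparameters beyond the two stopping controls are package defaults, all
configurable. Runs derive their generators from (master seed, run index),
so the consensus is bit-reproducible. An edge enters the consensus when it
appears in at least `retention_fraction` (default 0.7) of the run-best
models; fixed edges are exempt by construction and raising the retention
threshold can only remove edges.

## Synthetic data and what recovery does (and does not) show

`random_network` builds an activating random arborescence rooted at the
stimulus (fixed edges) plus planted optional edges and decoy optional edges
absent from the truth. Planted edges are constructed to be *identifiable*:
at most one optional edge per target (two optional activators of one node
would OR-shadow each other), sources strictly shallower than the target's
backbone parent, and a simulation check that rejects any candidate whose
addition leaves some planted edge without a visible effect on the
unperturbed trajectory. Scenarios are the stimulus alone plus single-node
inhibitions of the highest-out-degree internal nodes, mirroring the
kinase-inhibitor design of the biological training data. Continuous values
are rendered as Boolean state + N(0, sd) clipped to [0, 1] (default
sd = 0.05, at which binarization errors are vanishingly rare); the default
timepoint grid is the study-style 1, 2, 3, 4, 5, 6, 8, 12, 24 h.

This generator validates the *optimizer*: that the GA-plus-consensus
machinery finds exactly the planted edges under the package's own logic
conventions and noise model. It does not emulate probe-level microarray
artifacts, batch effects, unmodeled dynamics or mis-specified logic, so
recovery on synthetic data does not bound performance on real transcriptome
data, where identifiability is not guaranteed by construction.

## Expression analytics

Smoothing is an order-5 least-squares polynomial evaluated at the original
timepoints (requires at least order + 1 points). The top-regulation filter
keeps genes with |log2 FC| above 1.7 at two consecutive timepoints *of the
same sign* — mixed signs would conflate inverse regulation with sustained
response. CAST affinity is (Pearson r + 1)/2, so the default threshold
t = 0.8 corresponds to r = 0.6; the affinity normalization is a documented
choice. The greedy CAST loop adds the unassigned gene of maximal total
affinity while it clears t·|cluster|, expels members that fall below, and
closes on stability; constant series are excluded with a warning. The
anti-correlation rule fits linear models to both smoothed series and
requires significant slopes (alpha = 0.05 on the slope t-test, the adopted
default) of opposite sign with both r² strictly above 0.7.

HiT-MDS maximizes the Pearson correlation between input and embedded
pairwise distances. The optimizer is deterministic full-gradient ascent
(L-BFGS on 1 − r with an analytic gradient) from a classical-MDS start —
the classical start is permutation-equivariant and close enough to the
optimum that convergence is reliable; a seeded random start is used only
for degenerate inputs, and an input with zero distance variance falls back
to direct residual minimization. Reported stress is 1 − r with a
non-increasing per-iteration trace.

Uniqueness of a gene's temporal profile is scored by fitting a bivariate
skew-normal (location, Cholesky-parametrized scale, skew vector) by
maximum likelihood (Nelder-Mead) to the embedded point cloud, and defining
each point's p-value as the fitted-distribution probability of landing at
equal or lower density, estimated by seeded Monte Carlo with an add-one
correction so p is in (0, 1]. The density-quantile definition makes "low p"
mean "in the low-density tail" in any direction, which is the natural
outlier reading when only the distribution family is specified; p-values
are invariant under rigid motions of the embedding up to Monte-Carlo noise.
Collinear clouds are rejected as degenerate.

## Problem sizes

The packaged experiments use desk-scale sizes chosen to give tight
statistical conclusions while remaining quick to rerun: robustness sampling
at 10^5 random initializations (the sampler resolves ~10^5 32-node
trajectories in seconds); engine-vs-oracle agreement on 50 random networks
of 6-12 nodes at 10^5 samples against exact basins with a 3x binomial
standard-error band; topology recovery on a 15-node truth with 10 optional
edges (5 planted, 5 decoys) over 20 GA runs; cluster recovery on 50 genes
in 2 planted shape groups. The genome-scale analyses (15,348-gene
embeddings, the published cluster counts) require the original microarray
deposit and are documented as out of desk-scale scope; the property-based
synthetic experiments above stand in for them.

## Known limitations

* The network fixtures are reconstructions, not the original supplementary
  tables; conclusions about the *mechanisms* (feedback necessity, transient
  dynamics, robustness) are structural properties of the reconstruction
  that match the described biology, not re-derivations from the deposited
  data.
* Synchronous determinism compresses real kinetic time into update steps;
  the step-to-timepoint alignment is a convention, not a fit.
* The GA explores a small bitstring space in the packaged experiments;
  scaling to hundreds of optional edges would need the wall-time cap raised
  and possibly a larger population.
* The skew-normal uniqueness score assumes a unimodal embedded cloud;
  strongly multimodal embeddings would need a mixture model.
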