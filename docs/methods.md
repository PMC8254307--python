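# Methods

## The SD network

A segmental-duplication table is a list of pairwise local alignments,
each joining two genomic intervals with a reported identity. Alignments
are filtered with the standard SD definition (length ≥ 1 kbp, identity
≥ 0.90, autosomes only; both thresholds and a BED exclusion mask are
exposed). Coordinates are 0-based half-open throughout; "overlap" means
sharing at least one bp, so intervals that merely touch are not merged.

Every alignment contributes two *sides*. Sides on one chromosome are
merged transitively into maximal **duplicated regions**; a padding
parameter `P` (bp, signed) enlarges or shrinks sides *for clustering
only* — region bounds are always recorded as the union of the unpadded
sides, so `P` perturbs the topology without changing region lengths.
Each region becomes a node (annotated with chromosome, bounds and
length); each alignment increments the multiplicity of its region pair,
or the node's self-loop count when both sides fall into one region. All
topological analyses use the trimmed simple graph (no self-loops, one
edge per pair); the untrimmed multiplicity and self-loop counts feed the
region-length feature model only.

Strand is ignored. VCF minor allele counts are computed as
`min(c, 2n − c)` with `c` the non-reference allele occurrences over the
`n` called diploid samples; the CNV analysis assumes a 2504-individual
cohort for its upper MAC bound.

## Copying models and kinetic Monte Carlo

Network growth combines two processes: a fresh duplication that overlaps
nothing existing adds a two-node component C(2,1) with rate π, and an
existing node i ("mother") duplicates with rate δ_i, its "daughter"
always gaining the mother–daughter edge and inheriting each
mother–neighbor edge independently with probability f ∈ [0, 1]. The
**uniform copying model (UCM)** sets δ_i = δ; the **preferential copying
model (PCM)** sets δ_i = δ·k_i with k_i the current degree, so regions
with many long homologous copies duplicate proportionally more often.
Only δ/π matters, so π = 1.

Simulation is exact kinetic Monte Carlo: with rate vector
r = (π, δ_1, …, δ_N), event i is chosen with probability r_i/Σr and the
clock advances by Δt = −ln(u)/Σr, u ~ Uniform(0, 1]. Growth stops when
the node count reaches a target (node count, not time, is the stopping
rule). Degrees are maintained incrementally and are exactly equal to a
recomputation from the graph; the incremental path is tested
move-for-move against a naive loop built from the public primitives.
An optional robustness knob removes every edge with probability r after
each event; loss applies uniformly, including the edge just added.

Mean-field expectations for the small motifs under the PCM obey

    dn(2,1)/dt  = 1 − 2δ n(2,1)
    dn(3,2)/dt  = 2δ(1−f) n(2,1) − 4δ n(3,2)
    dn(3,3)/dt  = 2δ f n(2,1) − 6δ n(3,3)
    dn(>3,∗)/dt = 4δ n(3,2) + 6δ n(3,3)

with closed-form solution (from empty initial conditions)

    n(2,1)  = (1 − e^{−2δt}) / 2δ
    n(3,2)  = (1−f)(1 − 2e^{−2δt} + e^{−4δt}) / 4δ
    n(3,3)  = f(1 − 1.5e^{−2δt} + 0.5e^{−6δt}) / 6δ
    n(>3,∗) = t + (f − 9 + 3(4−f)e^{−2δt} − 3(1−f)e^{−4δt} − f e^{−6δt}) / 12δ

Note the count of components larger than three nodes grows linearly in t
once the small motifs saturate — the leading `t` term is required for
the solution to satisfy the system (and to be nonnegative); the
closed forms are verified against Runge–Kutta integration to 1e-8
relative accuracy.

## Parameter inference

**f by regression.** In the PCM the average number of edges in an
N-node component scales as E ∝ N^(1+f) as N → ∞, so f̂ = slope − 1 of
the OLS fit of log E̅(N) on log N, one point per observed component size
(giant component included; a flag excludes it). The scaling is
asymptotic: at small N the relation is convex (E̅(2) = 1 but
E̅(3) = 2 + f), which biases f̂ upward when most components are small.
At the human-fit rate scale (δ ≈ 5e-4, 5000-node targets) the bias is
about +0.03…+0.10 depending on f; in the longer-simulation regime
(δ ≈ 5e-3) recovery is within ±0.05 for f ∈ {0.3, 0.5, 0.7}. Parameter
recovery is therefore measured at δ = 5e-3.

**δ by rejection ABC.** δ ~ Uniform[5e-5, 9e-4] a priori; each draw
simulates the PCM at fixed f to the target node count and is accepted
when the Bray–Curtis dissimilarity D = Σ|X_i−Y_i| / Σ(X_i+Y_i) between
the sorted top-500 component-size vectors (zero-padded — simulations
stop on node count, so component counts differ) of simulation and
observation is below the 0.2 tolerance. The point estimate is the
posterior mean, the interval the 2.5/97.5 percentiles. The reference
protocol uses 5000 draws at the observed-network size; tests and the
acceptance script use a reduced 500 draws at 3000-node targets, at which
scale a planted δ is covered by the 95% interval in ≥90% of repeats.

**(f, δ, t) by loss minimisation.** The weighted city-block loss
L = Σ_i |n_t,i − n_obs,i| / n_obs,i over the four motif classes is
minimised by Nelder–Mead in transformed coordinates (logit f, log δ,
log t), start (0.5, e^{−1}·10^{−3}, 10^3) with five jittered restarts,
best minimum kept. On loss surfaces generated from the closed forms the
planted triple is recovered with loss < 1e-6. The loss is undefined when
an observed motif count is zero (it divides by the observation); such
inputs are rejected.

**Giant-component placement.** The observed largest-component size is
located in the simulated distribution of largest components by a
two-sided empirical p-value, p = 2·min(F̂(x), 1−F̂(x⁻)) capped at 1
(one-sided available by flag).

## Measuring spectrum exponents

Component-size distributions are log-binned (8 bins per decade by
default; density n_i/(N·b_i)) and the exponent is an OLS fit on the
nonempty bins in a fit window. The UCM prediction p(N) ∝ N^−1 and the
PCM prediction p(N) ∝ N^−(1+f) are *asymptotic, long-simulation*
statements: at small δ the distribution is dominated by an exponential
cutoff (the human-scale regime shows an effective slope near −2.7), and
at any δ the PCM's runaway giant component sits detached from the bulk.
The package therefore measures the UCM exponent at δ = 0.2 with fit
window N ∈ [2, 200] and the PCM exponent at δ = 0.1 with window
N ∈ [20, 1000] (excluding the discrete small-N regime and the giant
component), pooling 30 replicates of 5000-node runs. Pooling follows the
reference protocol of aggregating replicate networks before binning;
30 replicates keep the default suite within a normal CI budget while the
pooled spectra contain several thousand components.

## Synthetic duplication histories

The generator emulates what the copying models abstract: a linear
multi-chromosome genome (default 4 chromosomes × 1 Mb, half original
sequence, half reserved empty space) accumulates copy–paste events.
Sources are log-uniform in length on [1, 100] kb; in preferential mode
each event anchors, with probability 0.7, inside the already-duplicated
footprint (chosen proportionally to footprint length). Insertions
consume reserved empty space on a static coordinate frame (no coordinate
shifting), separated by 1 kb spacers so copies never merge by accident.
Ancestry is tracked per contiguous run down to original coordinates;
alignments are emitted for every pair of loci whose ancestral images
overlap, colinear fragments are merged, and records shorter than the
detection threshold (1 kb) are dropped — reproducing both primary and
*secondary* alignments (a new duplication overlapping an old region
aligns to all copies of that region). Emitted identities decay linearly
with event age (default range [0.92, 1.0]) and exist only to exercise
filters. Copy-number is exact by construction
(Σ(copy number − 1) over ancestral bases = Σ event lengths).

What this does *not* emulate: nucleotide sequence and alignment noise,
strand, inversions, deletions, coordinate drift from real insertions,
assembly artefacts, or mechanism-specific breakpoint structure
(NAHR/NHEJ). Passing the cross-path oracle test shows the construction
pipeline is exact on clean tables, not that it is robust to noisy real
annotations.

Synthetic CNV tables place variants on regions (probability 0.6) or
background, with geometric MACs whose success probability shrinks with
overlapped-region degree (`base_p / (1 + effect·log(1+degree))`), giving
a plantable monotone degree→frequency trend; effect 0 is degree-blind.

## The length model

Region length is regressed on untrimmed-network features (degree,
component size, mean copy number, intrachromosomal edge fraction,
self-loop count, double-edge count Σ(multiplicity−1)) with a
500-tree random forest (10-fold out-of-fold R²). Importances are
mean-decrease-in-accuracy permutation importances measured on a held-out
30% split; empirical p-values refit the whole procedure on 1000 shuffled
responses (tests use fewer) and count the fraction of shuffles whose
importance exceeds the real one. The copy-number feature is an external
per-region track; absent tracks are excluded with a warning.

## Species comparison

Per-species component spectra are compared by Bray–Curtis dissimilarity
of sorted top-500 size vectors (zero-padded) and clustered with average
linkage (UPGMA; complete/single by flag); the tree is exported as newick
and similarities are displayed as 1 − dissimilarity.

## Known limitations

* The PCM's giant component is intrinsically denser than the human SD
  giant component at matched node counts: because mothers are selected
  proportionally to degree, each duplication inside the giant component
  adds ≈ 1 + f·⟨k²⟩/⟨k⟩ edges, and the degree-squared feedback drives
  the giant component toward mean clustering ≈ 0.26 and mean shortest
  path ≈ 2.4 at the human parameters (f = 0.47, δ = 5.1e-4, 6656-node
  targets) — denser and more compact than the reference values (0.18,
  3.5) for this comparison. The simulated bulk — motif counts, elapsed
  time, spectrum shape, giant-component *size* distribution — does match
  the mean-field theory and the human-scale estimates; the discrepancy
  is confined to the internal wiring of the runaway component.
* Node deletion, edge rewiring and time-dependent rates are out of
  scope, as is SD detection itself (tables from WGAC/SEDEF are inputs).
* Label propagation is order-dependent; module results are reported for
  a fixed seed. The E̅(N) regression includes the giant component by
  default; both variants are exposed.
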