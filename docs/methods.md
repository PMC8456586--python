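# Methods

## Model

The classifier is a fully-connected network over standardized expression
values. The hidden architecture is dictated by a *layer schema* derived
from an ontology: a contiguous band of ontology levels, deepest first, with
one neuron per term and one hidden layer per level. The level of a term is
the length of the longest path from the root (root = 0), so every retained
edge runs from a deeper to a strictly shallower term. Hidden units are
ReLU; the output is a single logistic unit for two classes and a softmax
for more. (The logistic is the standard `1/(1+e^-z)`.)

Connectivity masks `C^(l)` mark the "GO connections": for the first layer,
probe *j* connects to term *i* iff *j* is in the *propagated* probe set of
*i* (a term inherits the probes of all its descendants, so annotations
deeper than the band still reach it); for layer *l* ≥ 2, term *j* of the
lower layer connects to term *i* of the upper one iff *i* is a **direct**
parent of *j* and their levels are the two adjacent band levels. Edges
that skip a level are not GO connections and are not rerouted. The output
layer's mask is all ones. Term order within a layer is lexicographic and
frozen; all reports index neurons in this order.

### Loss and training

The loss is cross-entropy plus `α · L_GO`, where
`L_GO = Σ_l ‖W^(l) ⊙ (1−C^(l))‖²_F` over hidden layers (biases and the
output layer excluded). `L1`/`L2` penalties with the same scope are
available for comparison; `none`/α=0 reduce exactly to a plain MLP — the
α=0 training trajectory is bit-identical across regularizer settings.

Each optimization step minimizes *batch-mean* cross-entropy plus
`α · penalty` — the convention of the major deep-learning frameworks —
so that α is calibrated against the per-sample loss and independent of the
batch size. Optimizers: Adam (lr 0.001) or SGD with momentum 0.9. He
initialization (variance `2/fan_in`) for weights, zeros for biases (a He
draw for a bias has no defined fan-in). Inverted dropout after each hidden
layer, rate interpreted as drop probability. Cross-entropy uses a 1e-12
probability floor. Training is deterministic given the seed, which drives
initialization, shuffling, and dropout. A non-finite loss aborts with a
diagnostic rather than returning garbage.

Splits are stratified (default 80/20). Standardization statistics are
computed on the training split and applied to held-out data by default;
a `global` mode standardizes before splitting for compatibility with
pipelines that do so.

### A note on optimizers and the penalty

SGD applies the penalty gradient `2αw` literally, so a dominant penalty
decays noGO weights geometrically toward true zero. Adam divides each
parameter's gradient by its own RMS, which decouples the effective decay
from the weight magnitude (the well-known reason decoupled weight decay
exists): under Adam, penalized weights that still receive a persistent
cross-entropy gradient settle at a floor of roughly `g/(2α)` instead of
zero. Penalty-dominance experiments (very large α) therefore use
SGD-momentum; ordinary training uses Adam.

## Interpretation

**LRP (ε-rule).** Relevance starts at the explained output's
pre-activation logit and is redistributed backwards proportionally to each
input's contribution `a_i w_ij`, with the stabilizer ε added with the sign
of the denominator. Biases are not part of the denominator, so relevance
is conserved exactly only on bias-free networks; the conservation tests
check this at ε=1e-7. For a binary head the logit of class 0 in the
single-logit parameterization is `−z`, so explaining a predicted-negative
sample seeds `−z` (`explain_class=0`); for multiclass only the explained
class's logit is seeded. Two ε regimes are deliberate: ε=1e-7 is the
formula's reference value used in conservation and oracle checks, while
cohort-level *reports* default to ε=0.1. On layers tens of neurons wide
the denominators regularly cross zero and the ε→0 rule becomes
ill-conditioned — single samples receive relevances two orders of
magnitude above the logit, with matching negative entries elsewhere — and
the report ranking is stable for ε anywhere in [0.03, 0.3].

**Connection norms.** The GO norm is the mean absolute weight over GO
entries, each hidden layer contributing its own mean with equal weight
(1/L), and likewise for noGO; the ratio of the two is the headline
diagnostic. Per-layer normalization keeps the statistic unbiased when the
GO fraction differs strongly across layers: deep layers have small fan-in
(hence intrinsically larger weights) and a much higher GO density, so
pooling all entries would inflate the GO mean by composition alone. At
random initialization the ratio is ~1 by construction; an untrained
network is not "ontology-faithful", and the diagnostic should say so.

**Target masks.** For each first-layer term, the mask zeroes every probe
outside its propagated probe set (zero = the training mean after
standardization). Each neuron's activation is averaged over the sample set
under every mask; the rank of the own mask in the decreasing ordering of a
neuron's row is its target-mask rank, NULL (coded −1) when the own-mask
activation is zero. Ties break by neuron index. Duplicate probe sets make
masks indistinguishable and raise by default (`allow_duplicate_masks`
overrides). LRP ranks order neurons by mean relevance over the same
samples.

**Clustering and reports.** Activation profiles are clustered with
average-linkage agglomerative clustering on euclidean distances
(scipy); trees are exported as Newick with branch lengths. Term reports
take the arithmetic mean relevance per neuron over a sample subset and
return the top-k per layer, ties broken by term ID.

## Synthetic benchmark

The generator emulates the three inputs of a real analysis.

*DAG*: 6 levels below the root with (6, 9, 12, 14, 16, 20) terms — level
sizes widen toward the middle/deep levels the way real GO level counts do,
avoiding degenerate few-neuron bottleneck layers. Every term has ≥1 parent
exactly one level up (so the longest-path level equals the construction
level), extra same-band parents with probability 0.25, and a skip-level
parent with probability 0.1. Emitted as standard OBO.

*Annotations*: 300 probes, of which 33% receive no annotation (mirroring
unannotated microarray probes). The annotated pool is dealt to the 20
deepest terms in disjoint blocks with lognormal sizes (median 8, σ=0.6);
leftover probes join random terms. Disjoint blocks reflect how little
sibling terms at the deepest level of a real ontology overlap; identical
probe sets are an error.

*Expression*: 600 samples, 66/34 class split (a realistic cancer
prevalence), iid Gaussian noise (sd 1). Each planted signal term shifts
its probes by 2 (in noise-sd units) in the samples of the class it marks —
"effect clearly above noise", giving near-perfect Bayes separability
through a realistic median-size probe set. A variant plants the signal in
unannotated probes instead, producing data whose signal the network can
only reach through noGO connections. The generator returns the ground
truth (which terms/probes carry signal), which is what interpretation
recovery is scored against.

Benchmark training uses the full band (levels 6..1), Adam, 600 epochs,
batch 128, and no dropout: the real-scale rate of 0.6 was tuned for layers
of 59–1574 neurons, and on 6–20-neuron layers it ablates entire layers per
batch; no configuration trained with it here.

What passing on this generator does *not* show: robustness to correlated
noise, batch effects, probe cross-hybridization, count-data likelihoods,
or annotation errors; the planted signal is a clean mean shift.

### Known limitations

* The sign of a GO connection is unconstrained, so a planted detector may
  learn to activate for the *complement* of its class (equally valid
  discrimination); recovery is therefore checked in both predicted-class
  cohort reports, and with two oppositely-planted terms the relevance can
  disperse across mixtures. This mirrors the substantial NULL-mask
  fraction seen on real data.
* ε-LRP on narrow layers needs the report-scale stabilizer above;
  attribution methods without a denominator (not implemented) would avoid
  this.
* Metrics use binary averaging for two classes and macro averaging
  one-vs-rest otherwise.

## Reference quantities

`scripts/acceptance.py` recomputes, from scratch each run: the two worked
ranking examples (target-mask rank of a neuron with mean masked
activations 0.9/0.7/0.8; LRP rank of the middle neuron with mean
relevances 1.9/2.5/0.3), and the median GO:noGO ratio of L1- and
L2-trained models over α ∈ {1e-4, 1e-2, 1} × 5 seeds on the default
benchmark — unstructured penalties do not separate the connection classes,
so this median sits near 1, while the structured penalty's ratio grows
with α by orders of magnitude (see the validation suite).
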