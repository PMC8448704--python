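# Methods

## The model

`cortexnet` simulates a single population of *N* = 100 binary-rate neurons
standing for a local patch of layer-2/3 neocortical pyramidal cells.  Each
neuron's dendrite carries three classes of synapse, `n_syn` = 100 of each:

* **forward** (`w_comp`) — afferents from the previous cortical area; this
  block self-organises by competitive learning and categorises the inputs;
* **recurrent** (`w_rec`) — collaterals from the same population; this block
  learns autoassociatively and turns the population into an attractor
  network that holds its firing pattern as a short-term memory;
* **backprojection** (`w_bp`) — top-down afferents from the next cortical
  area; this block learns by pattern association, so a top-down cue can
  later recall the stored output, and a weak cue can bias competition
  (attention).

The activation of neuron *i* is the gain-weighted sum of the three block
products,

    h_i = g_comp Σ_k x_k w_comp[i,k] + g_rec Σ_l x_l w_rec[i,l] + g_bp Σ_m x_m w_bp[i,m],

and a binary *k*-winners threshold converts activations to rates: the
`round(sparseness·N)` most-activated neurons fire at rate 1 (ties to the
lowest index; an all-silent population stays silent when no activation is
positive).  The threshold stands in for feedback inhibition by
interneurons, which is not modelled explicitly.

Every synapse learns with the same associative rule, `dw = α·y_i·x_j`, with
a per-class learning rate.  After each presentation, every neuron that fired
has its **whole** concatenated weight vector (all three blocks, length
3·`n_syn`) rescaled to unit Euclidean norm.  This single whole-dendrite
normalisation is what couples the three learning systems: it keeps the
neurons competing on equal terms and implements heterosynaptic depression
of the inactive synapses on active neurons.  Weights are initialised
uniform on [0, 1] and normalised the same way, so all weights are
non-negative at all times.

## Parameters

| name | default | meaning |
|---|---|---|
| `n_neurons`, `n_syn` | 100, 100 | population size; synapses per class per neuron |
| `g_comp, g_rec, g_bp` | 1.0, 0.1, 0.1 | class gains; the weak recurrent/backprojection gains let the forward inputs dominate during learning while still sufficing for memory and recall alone |
| `alpha_comp, alpha_rec, alpha_bp` | 0.1, 0.03, 0.1 | per-class learning rates, chosen so the three classes reach comparable synaptic strengths |
| `sparseness` | 0.01 | output sparseness; a single winning neuron at N=100 |
| `epochs` | 5 | training epochs, patterns permuted afresh each epoch |
| `settle_iters` | 1 | settling passes per presentation; rates start at zero, so pass 1 has no recurrent contribution |
| `normalize_forward` | True | scale forward rate vectors to unit length (below) |
| `normalize_every` | "pattern" | renormalise after every presentation ("epoch" is exposed for comparison) |

All units are dimensionless rates and weights.

## Forward-input normalisation

Forward rate vectors are scaled to unit Euclidean length before synaptic
integration and learning (`normalize_forward`).  This is the classical
competitive-learning convention (Rumelhart–Zipser): with unit weight
vectors and unit input vectors the competition compares pattern *shapes*
(cosines), not intensities.  It is also quantitatively necessary here.  A
learned neuron's per-epoch weight increments per synapse are then roughly
0.16 (forward, 20 active lines at α/√20 times a within-category multiplicity
of ~7), 0.21 (recurrent, α·7 on the self-synapse) and 0.1 (backprojection) —
comparable, as the per-class learning rates intend.  With raw binary forward
vectors the forward block would receive an order of magnitude more increment
mass per epoch, and after whole-dendrite normalisation the learned
recurrent and backprojection weights would fall *below* the random weights
of the ~96 unallocated neurons; free recall and the attractor then fail
outright (this variant remains available by setting
`normalize_forward=False`).  Backprojection cues (3 active lines) and the
binary recurrent rate vector are sparse enough to be used as raw rates.

Within a presentation, learning uses the settled rates both as the
postsynaptic term and as the recurrent presynaptic vector, so recurrent
learning is autoassociative (pre = post), which is what makes the stored
attractor equal the output pattern itself.  With a single winner the
attractor is carried by the winner's self-synapse.

## Synthetic data

The pattern generators are the experiment's stimuli, not fixtures:

* **forward set** — 28 binary patterns of 20 active lines out of 100,
  consecutive patterns offset by 3 lines (positions taken modulo 100, so
  the last pattern wraps; every consecutive pair overlaps in exactly 17
  lines and every pattern keeps exactly 20 active lines).  Mean absolute
  off-diagonal Pearson correlation 13/42 ≈ 0.3095, printed 0.31.
* **backprojection set** — 28 pairwise-disjoint cues of 3 consecutive
  lines; off-diagonal correlations all −3/97.
* **random sets** — exact-count binary patterns at a given sparseness, for
  exploration.

These patterns emulate a graded family of correlated stimuli and clean
top-down cues.  They do not emulate graded firing rates, noise, or
spatially structured input, so passing tests demonstrate the circuit-level
mechanism, not robustness to biological variability.

## Experiments

`run_experiment` trains a fresh network, then measures: category labels
(distinct output vectors, numbered by first occurrence), contiguity of the
categories in pattern order (wrap-aware), correlation matrices of inputs
and outputs, recall fidelity (exact vector match between cue-evoked and
forward-evoked outputs), and attractor persistence (output unchanged over
10, optionally 100, free-running iterations).  `category_statistics`
repeats this over seeds; `robustness_sweep` grids parameters, and flags a
grid point "operational" only when *every* seeded run recalls perfectly,
holds its attractor, and forms 3–6 categories.  `attention_experiment`
builds ambiguous stimuli (element-wise max of one exemplar from each of two
categories) presented at half gain and asks whether a weak cue (half gain
on `g_bp`) pulls the winner toward the cued category.

Problem sizes follow the study design throughout: 28 patterns, 100
neurons, 5 epochs, 20 seeds for the multi-seed statistics — a default run
trains in well under a second.

## Numerical choices and degenerate inputs

* Seeds split into independent streams for weight initialisation and
  training permutations (`numpy` `SeedSequence.spawn`), so the whole
  pipeline is bit-reproducible and runs with different seed counts do not
  perturb each other.
* Ties in the k-winners threshold go to the lowest neuron index (with
  continuous random weights, exact ties have measure zero).
* All-zero activation produces all-zero rates rather than forcing winners.
* A zero norm in input or weight normalisation is left unscaled.
* Category identity is exact binary-vector equality, not a similarity
  threshold.
* Correlation of a constant (zero-variance) pattern is rejected with an
  error rather than returning NaN.

## Known limitations

* With the default parameters the modal number of categories over many
  seeds is 5 (4 and 6 also occur); category counts fall with faster
  forward learning, but faster forward learning starves the recurrent and
  backprojection blocks of their share of the normalised weight budget.
* Free recall is exact for all 28 cues in roughly six runs out of ten; the
  failing runs miss 1–2 cues.  The margins are structural: a neuron that
  wins a pattern once early in training and is then out-competed keeps its
  single backprojection association frozen (it never fires again, so
  normalisation never depresses it), and within the final epoch the
  earliest-refreshed cue weights decay slightly relative to the latest.
  Both effects are inherent to a pure Hebb rule whose only depression
  mechanism is renormalisation of active neurons.
* The attention probe is exploratory: it reports a directional bias
  (cued-category wins increase with cue gain), not a calibrated
  psychometric quantity.
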