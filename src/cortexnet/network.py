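"""The pyramidal-cell population model: three synaptic blocks, one Hebb rule.

A single population of ``N`` binary-rate neurons receives three classes of
synaptic input on each dendrite:

* ``w_comp`` — forward synapses from the previous cortical area, the
  competitive-learning pathway that categorises the inputs;
* ``w_rec``  — recurrent-collateral synapses from the population onto itself,
  the autoassociative pathway that maintains a short-term-memory attractor;
* ``w_bp``   — backprojection synapses from the next cortical area, the
  pattern-association pathway that supports top-down recall and attention.

The activation of neuron *i* is a weighted sum over all three blocks, each
scaled by a fixed class gain::

    h_i = g_comp * sum_k x_k w_comp[i,k]
        + g_rec  * sum_l x_l w_rec[i,l]
        + g_bp   * sum_m x_m w_bp[i,m]

A binary k-winners threshold then fixes the population sparseness (standing
in for feedback inhibition by interneurons).  Every synapse learns with the
same associative rule ``dw = alpha * y_i * x_j``, and after each pattern
presentation the *whole* concatenated weight vector of each updated neuron
(all three blocks, length ``3 * n_syn``) is rescaled to unit Euclidean norm —
the normalisation implements heterosynaptic depression of inactive synapses
on active neurons and makes the neurons compete on equal terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .patterns import PatternSet

__all__ = [
    "NetworkParams",
    "SynapticState",
    "NetworkState",
    "init_weights",
    "compute_activation",
    "apply_sparseness",
    "settle",
    "hebbian_update",
    "train",
    "test_forward",
    "run_attractor",
    "recall",
    "attention_bias",
]


@dataclass(frozen=True)
class NetworkParams:
    """All fixed scalars of the model.

    Attributes
    ----------
    n_neurons : int
        Population size N (output neurons).
    n_syn : int
        Synapses per input class per neuron; equals the input pattern length.
    g_comp, g_rec, g_bp : float
        Fixed scale factors for the forward, recurrent and backprojection
        blocks of the activation.  The recurrent and backprojection gains are
        low (0.1) so the forward inputs dominate during learning while the
        weak pathways still suffice for memory and recall on their own.
    alpha_comp, alpha_rec, alpha_bp : float
        Learning rates of the three synapse classes.
    sparseness : float
        Fraction of output neurons left firing by the binary threshold;
        0.01 with N=100 yields a single winning neuron.
    epochs : int
        Training epochs; each epoch visits every pattern pair once in a
        fresh random permutation.
    settle_iters : int
        Activation-settling passes per presentation.  Rates start at zero,
        so the first pass carries no recurrent contribution; additional
        passes feed the rates back through the recurrent collaterals.
    normalize_forward : bool
        Scale each forward rate vector to unit Euclidean length before
        synaptic integration and learning (the Rumelhart–Zipser competitive
        -learning convention, standing in for afferent gain control).  With
        the default learning rates this is what makes the per-epoch weight
        increments of the three synapse classes comparable, so that the
        weak recurrent and backprojection pathways can support memory and
        recall alongside the strong forward pathway.  Cue and recurrent
        rates are sparse binary vectors and are used as is.
    normalize_every : {'pattern', 'epoch'}
        When to renormalise the weight vectors during training.  The default
        renormalises after every presentation.
    """

    n_neurons: int = 100
    n_syn: int = 100
    g_comp: float = 1.0
    g_rec: float = 0.1
    g_bp: float = 0.1
    alpha_comp: float = 0.1
    alpha_rec: float = 0.03
    alpha_bp: float = 0.1
    sparseness: float = 0.01
    epochs: int = 5
    settle_iters: int = 1
    normalize_forward: bool = True
    normalize_every: str = "pattern"

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_syn < 1:
            raise ValueError("n_neurons and n_syn must be positive")
        for name in ("g_comp", "g_rec", "g_bp", "alpha_comp", "alpha_rec", "alpha_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.sparseness <= 1.0:
            raise ValueError("sparseness must lie in (0, 1]")
        if round(self.sparseness * self.n_neurons) < 1:
            raise ValueError("sparseness too low: no winners")
        if self.epochs < 0 or self.settle_iters < 1:
            raise ValueError("epochs must be >= 0 and settle_iters >= 1")
        if self.normalize_every not in ("pattern", "epoch"):
            raise ValueError("normalize_every must be 'pattern' or 'epoch'")

    @property
    def n_winners(self) -> int:
        """Number of neurons the threshold leaves firing."""
        return max(1, int(round(self.sparseness * self.n_neurons)))

    def replace(self, **changes) -> "NetworkParams":
        return replace(self, **changes)


@dataclass
class SynapticState:
    """The three weight blocks, rows = neurons.

    ``w_comp`` is (N, n_syn), ``w_rec`` is (N, N), ``w_bp`` is (N, n_syn).
    All weights are non-negative and every neuron's concatenated row
    (forward ‖ recurrent ‖ backprojection) has unit Euclidean norm.
    """

    w_comp: np.ndarray
    w_rec: np.ndarray
    w_bp: np.ndarray

    def concatenated(self) -> np.ndarray:
        """Each neuron's full dendritic weight vector, shape (N, 3*n_syn)."""
        return np.hstack([self.w_comp, self.w_rec, self.w_bp])

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.concatenated(), axis=1)

    def copy(self) -> "SynapticState":
        return SynapticState(self.w_comp.copy(), self.w_rec.copy(), self.w_bp.copy())

    def normalize_rows(self, rows: np.ndarray | None = None) -> None:
        """Rescale the selected neurons' concatenated weight vectors to unit norm."""
        if rows is None:
            rows = np.arange(self.w_comp.shape[0])
        rows = np.asarray(rows)
        if rows.size == 0:
            return
        norms = np.linalg.norm(
            np.hstack([self.w_comp[rows], self.w_rec[rows], self.w_bp[rows]]), axis=1
        )
        norms[norms == 0] = 1.0
        scale = (1.0 / norms)[:, None]
        self.w_comp[rows] *= scale
        self.w_rec[rows] *= scale
        self.w_bp[rows] *= scale


@dataclass
class NetworkState:
    """Current activations h and binary firing rates y of the population."""

    activations: np.ndarray
    rates: np.ndarray


def init_weights(
    params: NetworkParams, seed: int | np.random.Generator = 0
) -> SynapticState:
    """Uniform-random weights in [0, 1], then each neuron's concatenated
    weight vector rescaled to unit length."""
    rng = np.random.default_rng(seed)
    syn = SynapticState(
        w_comp=rng.uniform(0.0, 1.0, size=(params.n_neurons, params.n_syn)),
        w_rec=rng.uniform(0.0, 1.0, size=(params.n_neurons, params.n_neurons)),
        w_bp=rng.uniform(0.0, 1.0, size=(params.n_neurons, params.n_syn)),
    )
    syn.normalize_rows()
    return syn


def _as_rates(x: np.ndarray | PatternSet, n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {x.shape}")
    return x


def _unit(x: np.ndarray) -> np.ndarray:
    """Scale a rate vector to unit Euclidean length (zero stays zero)."""
    x = np.asarray(x, dtype=np.float64)
    n = np.linalg.norm(x)
    return x / n if n > 0 else x


def compute_activation(
    syn: SynapticState,
    params: NetworkParams,
    x_comp: np.ndarray,
    x_rec: np.ndarray,
    x_bp: np.ndarray,
) -> np.ndarray:
    """Activation h of every neuron: the three gain-scaled block dot products."""
    x_comp = _as_rates(x_comp, params.n_syn, "x_comp")
    x_rec = _as_rates(x_rec, params.n_neurons, "x_rec")
    x_bp = _as_rates(x_bp, params.n_syn, "x_bp")
    return (
        params.g_comp * (syn.w_comp @ x_comp)
        + params.g_rec * (syn.w_rec @ x_rec)
        + params.g_bp * (syn.w_bp @ x_bp)
    )


def apply_sparseness(h: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Binary threshold enforcing the fixed population sparseness.

    The ``n_winners`` neurons with the highest activation fire (rate 1), all
    others are silent; ties go to the lowest neuron index.  If no activation
    is positive, nothing fires.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (params.n_neurons,):
        raise ValueError(f"activation must have length {params.n_neurons}")
    rates = np.zeros(params.n_neurons, dtype=np.uint8)
    if np.max(h, initial=-np.inf) <= 0:
        return rates
    # sort by descending activation, then ascending index for the tie-break
    order = np.lexsort((np.arange(h.size), -h))
    rates[order[: params.n_winners]] = 1
    return rates


def settle(
    syn: SynapticState,
    params: NetworkParams,
    x_comp: np.ndarray,
    x_bp: np.ndarray,
    f_gain: float = 1.0,
    b_gain: float = 1.0,
) -> NetworkState:
    """Compute the population response to a forward + backprojection input.

    The forward vector is scaled to unit length first (see
    ``NetworkParams.normalize_forward``) and then multiplied by ``f_gain``;
    the cue is multiplied by ``b_gain``.  Rates start at zero, so the first
    pass has no recurrent contribution; each further pass (``settle_iters``
    total) feeds the current rates back through the recurrent collaterals.
    """
    x_comp = _as_rates(x_comp, params.n_syn, "x_comp")
    if params.normalize_forward:
        x_comp = _unit(x_comp)
    x_comp = x_comp * f_gain
    x_bp = _as_rates(x_bp, params.n_syn, "x_bp") * b_gain
    rates = np.zeros(params.n_neurons, dtype=np.float64)
    h = np.zeros(params.n_neurons, dtype=np.float64)
    for _ in range(params.settle_iters):
        h = compute_activation(syn, params, x_comp, rates, x_bp)
        rates = apply_sparseness(h, params).astype(np.float64)
    return NetworkState(activations=h, rates=rates.astype(np.uint8))


def hebbian_update(
    syn: SynapticState,
    params: NetworkParams,
    x_comp: np.ndarray,
    x_rec: np.ndarray,
    x_bp: np.ndarray,
    y: np.ndarray,
    normalize: bool = True,
) -> SynapticState:
    """Associative update of all three blocks, then renormalisation.

    ``dw[i, j] = alpha * y[i] * x[j]`` for each block; afterwards every
    neuron with ``y[i] > 0`` has its concatenated weight vector rescaled to
    unit norm (silent neurons are untouched, and their norm is already 1).
    Modifies ``syn`` in place and returns it.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (params.n_neurons,):
        raise ValueError(f"y must have length {params.n_neurons}")
    active = np.flatnonzero(y > 0)
    if active.size == 0:
        return syn
    x_comp = _as_rates(x_comp, params.n_syn, "x_comp")
    x_rec = _as_rates(x_rec, params.n_neurons, "x_rec")
    x_bp = _as_rates(x_bp, params.n_syn, "x_bp")
    ya = y[active][:, None]
    syn.w_comp[active] += params.alpha_comp * ya * x_comp[None, :]
    syn.w_rec[active] += params.alpha_rec * ya * x_rec[None, :]
    syn.w_bp[active] += params.alpha_bp * ya * x_bp[None, :]
    if normalize:
        syn.normalize_rows(active)
    return syn


def train(
    syn: SynapticState,
    params: NetworkParams,
    forward: PatternSet,
    backproj: PatternSet,
    rng: int | np.random.Generator = 0,
) -> SynapticState:
    """Train on paired forward/backprojection patterns.

    Each epoch presents every pattern pair once in a fresh random
    permutation.  For each pair the network settles on the joint input, and
    the final rates serve both as the postsynaptic term and as the recurrent
    presynaptic vector — so the recurrent block learns autoassociatively,
    which is what makes the attractor store the output pattern itself.
    Returns a trained copy; the input state is not modified.
    """
    if len(forward) != len(backproj):
        raise ValueError("forward and backprojection sets must pair up 1:1")
    if forward.n_lines != params.n_syn or backproj.n_lines != params.n_syn:
        raise ValueError(f"pattern length must equal n_syn={params.n_syn}")
    rng = np.random.default_rng(rng)
    syn = syn.copy()
    touched: set[int] = set()
    for _ in range(params.epochs):
        for idx in rng.permutation(len(forward)):
            x_comp = np.asarray(forward[idx], dtype=np.float64)
            if params.normalize_forward:
                x_comp = _unit(x_comp)
            state = settle(syn, params, forward[idx], backproj[idx])
            y = state.rates.astype(np.float64)
            hebbian_update(
                syn,
                params,
                x_comp,
                y,
                backproj[idx],
                y,
                normalize=params.normalize_every == "pattern",
            )
            touched.update(np.flatnonzero(y > 0).tolist())
        if params.normalize_every == "epoch" and touched:
            syn.normalize_rows(np.array(sorted(touched)))
            touched.clear()
    return syn


def test_forward(
    syn: SynapticState, params: NetworkParams, f: np.ndarray
) -> np.ndarray:
    """Response to a forward input alone (no backprojection, no learning)."""
    zeros = np.zeros(params.n_syn)
    return settle(syn, params, f, zeros).rates


def run_attractor(
    syn: SynapticState, params: NetworkParams, y0: np.ndarray, n_iter: int = 10
) -> list[np.ndarray]:
    """Free-run the recurrent collaterals from an initial firing pattern.

    All external input is off; each iteration recomputes the activations from
    the current rates through the recurrent block only and rethresholds.
    Returns the rate vector after each of the ``n_iter`` iterations.
    """
    zeros = np.zeros(params.n_syn)
    rates = np.asarray(y0, dtype=np.float64)
    trajectory: list[np.ndarray] = []
    for _ in range(n_iter):
        h = compute_activation(syn, params, zeros, rates, zeros)
        rates = apply_sparseness(h, params).astype(np.float64)
        trajectory.append(rates.astype(np.uint8))
    return trajectory


def recall(syn: SynapticState, params: NetworkParams, b: np.ndarray) -> np.ndarray:
    """Response to a backprojection cue alone (top-down recall)."""
    zeros = np.zeros(params.n_syn)
    return settle(syn, params, zeros, b).rates


def attention_bias(
    syn: SynapticState,
    params: NetworkParams,
    f: np.ndarray,
    b: np.ndarray,
    f_gain: float,
    b_gain: float,
) -> np.ndarray:
    """Response to a weak forward input plus a weak top-down cue.

    The gains scale the input rate vectors multiplicatively before the
    activation, modelling degraded / ambiguous bottom-up evidence and a weak
    attentional backprojection signal biasing the competition.
    """
    if not (0.0 <= f_gain <= 1.0 and 0.0 <= b_gain <= 1.0):
        raise ValueError("gains must lie in [0, 1]")
    return settle(syn, params, f, b, f_gain=f_gain, b_gain=b_gain).rates
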