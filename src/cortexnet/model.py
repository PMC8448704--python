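"""Model / Results interface over the pyramidal-cell population network.

:class:`CorticalModule` is built from a pair of pattern sets (forward stimuli
and their top-down cues) plus :class:`~cortexnet.network.NetworkParams`;
``fit(seed)`` trains the network and returns a
:class:`CorticalModuleResults` carrying the trained synapses, the category
structure of the outputs, correlation matrices, recall and attractor
diagnostics, and a ``summary()`` table.  Simulation (free-running the
attractor, attention probes) hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .network import NetworkParams, SynapticState
from .patterns import (
    PatternSet,
    correlation_matrix,
    make_orthogonal_patterns,
    make_shifted_patterns,
    mean_abs_offdiag,
)

__all__ = ["CorticalModule", "CorticalModuleResults", "split_seed"]


def split_seed(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Expand one seed into independent streams for weight initialisation and
    training-order permutations, so the two sources of randomness never
    interact."""
    weights_ss, perm_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(weights_ss), np.random.default_rng(perm_ss)


class CorticalModule:
    """A neocortical module: one pyramidal-cell population, three input classes.

    Parameters
    ----------
    forward : PatternSet
        Stimuli from the previous cortical area (competitive pathway).
    backproj : PatternSet
        One top-down cue per forward pattern (recall pathway).
    params : NetworkParams, optional
        Model constants; keyword overrides may be given instead, e.g.
        ``CorticalModule(f, b, epochs=10)``.

    Examples
    --------
    >>> model = CorticalModule.from_defaults()
    >>> res = model.fit(seed=0)
    >>> res.n_categories in (4, 5)
    True
    """

    def __init__(
        self,
        forward: PatternSet,
        backproj: PatternSet,
        params: NetworkParams | None = None,
        **overrides,
    ) -> None:
        if params is None:
            params = NetworkParams(**overrides)
        elif overrides:
            params = params.replace(**overrides)
        if len(forward) != len(backproj):
            raise ValueError("forward and backprojection sets must pair up 1:1")
        if forward.n_lines != params.n_syn or backproj.n_lines != params.n_syn:
            raise ValueError(f"pattern length must equal n_syn={params.n_syn}")
        self.forward = forward
        self.backproj = backproj
        self.params = params

    @classmethod
    def from_defaults(cls, params: NetworkParams | None = None, **overrides) -> "CorticalModule":
        """The standard configuration: 28 shifted forward patterns (20 of 100
        active, offset 3) paired with 28 disjoint 3-line backprojection cues."""
        forward = make_shifted_patterns(28, 100, 20, 3)
        backproj = make_orthogonal_patterns(28, 100, 3)
        return cls(forward, backproj, params, **overrides)

    def fit(self, seed: int = 0) -> "CorticalModuleResults":
        """Initialise random weights and train for ``params.epochs`` epochs.

        The seed is split into independent streams for the weight
        initialisation and the per-epoch pattern permutations, so the whole
        run is bit-reproducible.
        """
        weights_rng, perm_rng = split_seed(seed)
        syn0 = net.init_weights(self.params, weights_rng)
        syn = net.train(syn0, self.params, self.forward, self.backproj, perm_rng)
        return CorticalModuleResults(self, syn, seed)


@dataclass
class CorticalModuleResults:
    """A trained module and everything measured on it.

    Derived quantities (category labels, correlation matrices, recall and
    attractor diagnostics) are computed lazily and cached.
    """

    model: CorticalModule
    synapses: SynapticState
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> NetworkParams:
        return self.model.params

    # ---------------------------------------------------------------- outputs

    @property
    def forward_outputs(self) -> np.ndarray:
        """Output rate vectors for each forward pattern presented alone."""
        if "fwd" not in self._cache:
            self._cache["fwd"] = np.array(
                [net.test_forward(self.synapses, self.params, f) for f in self.model.forward]
            )
        return self._cache["fwd"]

    @property
    def recall_outputs(self) -> np.ndarray:
        """Output rate vectors for each backprojection cue presented alone."""
        if "rec" not in self._cache:
            self._cache["rec"] = np.array(
                [net.recall(self.synapses, self.params, b) for b in self.model.backproj]
            )
        return self._cache["rec"]

    # ------------------------------------------------------------- categories

    @property
    def category_labels(self) -> np.ndarray:
        """Integer category per forward pattern; categories are distinct output
        rate vectors, numbered by first occurrence."""
        if "labels" not in self._cache:
            labels, seen = [], {}
            for out in self.forward_outputs:
                key = out.tobytes()
                if key not in seen:
                    seen[key] = len(seen)
                labels.append(seen[key])
            self._cache["labels"] = np.array(labels, dtype=np.int64)
        return self._cache["labels"]

    @property
    def n_categories(self) -> int:
        return int(self.category_labels.max()) + 1

    @property
    def category_outputs(self) -> np.ndarray:
        """The distinct output rate vectors, one per category, in label order."""
        first = [int(np.argmax(self.category_labels == c)) for c in range(self.n_categories)]
        return self.forward_outputs[first]

    @property
    def categories_contiguous(self) -> bool:
        """Whether every category occupies one contiguous run of pattern
        indices (wrap-aware) — i.e. similar inputs share a category."""
        labels = self.category_labels
        n = len(labels)
        # count circular boundaries where the label changes; a partition into
        # k contiguous circular runs has exactly k boundaries
        boundaries = sum(labels[i] != labels[(i + 1) % n] for i in range(n))
        return boundaries == self.n_categories or self.n_categories == 1

    # ------------------------------------------------------------ diagnostics

    @property
    def input_corr(self) -> np.ndarray:
        """Pearson correlation matrix of the forward input patterns."""
        return correlation_matrix(self.model.forward)

    @property
    def output_corr_forward(self) -> np.ndarray:
        """Correlation matrix of the outputs under forward testing."""
        return correlation_matrix(self.forward_outputs)

    @property
    def output_corr_recall(self) -> np.ndarray:
        """Correlation matrix of the outputs under backprojection recall."""
        return correlation_matrix(self.recall_outputs)

    @property
    def mean_abs_input_corr(self) -> float:
        return mean_abs_offdiag(self.input_corr)

    @property
    def mean_abs_category_corr(self) -> float:
        """Mean absolute pairwise correlation between the distinct category
        output vectors (forward testing)."""
        return mean_abs_offdiag(correlation_matrix(self.category_outputs))

    @property
    def mean_abs_recall_corr(self) -> float:
        """Mean absolute pairwise correlation between the distinct output
        vectors under backprojection recall."""
        distinct = np.unique(self.recall_outputs, axis=0)
        return mean_abs_offdiag(correlation_matrix(distinct))

    @property
    def recall_correct(self) -> int:
        """Number of cues whose recalled output equals the matched forward
        output exactly."""
        return int(
            sum(
                np.array_equal(r, f)
                for r, f in zip(self.recall_outputs, self.forward_outputs)
            )
        )

    @property
    def recall_perfect(self) -> bool:
        return self.recall_correct == len(self.model.forward)

    def attractor_stable(self, n_iter: int = 10) -> bool:
        """Whether every forward-evoked firing pattern persists unchanged when
        the input is removed and the network free-runs for ``n_iter`` steps."""
        for y0 in self.forward_outputs:
            for y in self.simulate_attractor(y0, n_iter):
                if not np.array_equal(y, y0):
                    return False
        return True

    # ------------------------------------------------------------- simulation

    def simulate_attractor(self, y0: np.ndarray, n_iter: int = 10) -> list[np.ndarray]:
        """Free-run the recurrent collaterals from ``y0`` with no external
        input, returning the rate vector after each iteration."""
        return net.run_attractor(self.synapses, self.params, y0, n_iter)

    def respond(self, f=None, b=None, f_gain: float = 1.0, b_gain: float = 1.0) -> np.ndarray:
        """Response to an arbitrary (possibly scaled) input combination."""
        zeros = np.zeros(self.params.n_syn)
        f = zeros if f is None else np.asarray(f, dtype=np.float64)
        b = zeros if b is None else np.asarray(b, dtype=np.float64)
        return net.attention_bias(self.synapses, self.params, f, b, f_gain, b_gain)

    # --------------------------------------------------------------- plotting

    def plot_correlations(self, axes=None):
        """Render the input / forward-output / recall-output correlation
        matrices side by side (returns the matplotlib figure)."""
        import matplotlib.pyplot as plt

        if axes is None:
            fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        else:
            fig = axes[0].figure
        titles = ("input patterns", "outputs (forward)", "outputs (recall)")
        mats = (self.input_corr, self.output_corr_forward, self.output_corr_recall)
        for ax, mat, title in zip(axes, mats, titles):
            im = ax.imshow(mat, vmin=-1, vmax=1, cmap="gray")
            ax.set_title(title)
            fig.colorbar(im, ax=ax, fraction=0.046)
        return fig

    def plot_weights(self, ax=None):
        """Render the synaptic matrix: 3*n_syn rows (backprojection block on
        top, then recurrent, then forward) by N neuron columns."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 10))
        stacked = np.vstack(
            [self.synapses.w_bp.T, self.synapses.w_rec.T, self.synapses.w_comp.T]
        )
        ax.imshow(stacked, cmap="gray", aspect="auto")
        ax.set_xlabel("neuron (dendrite)")
        ax.set_ylabel("synapse (bp | rec | fwd)")
        return ax.figure

    # ----------------------------------------------------------------- report

    def summary(self) -> str:
        """Human-readable run summary."""
        p = self.params
        lines = [
            "Cortical module fit",
            "===================",
            f"neurons N            : {p.n_neurons}",
            f"patterns             : {len(self.model.forward)}",
            f"epochs               : {p.epochs}   seed: {self.seed}",
            f"gains (fwd/rec/bp)   : {p.g_comp}/{p.g_rec}/{p.g_bp}",
            f"rates (fwd/rec/bp)   : {p.alpha_comp}/{p.alpha_rec}/{p.alpha_bp}",
            f"output sparseness    : {p.sparseness} ({p.n_winners} winner(s))",
            "-------------------",
            f"categories formed    : {self.n_categories}"
            f" ({'contiguous' if self.categories_contiguous else 'non-contiguous'})",
            f"mean |corr| inputs   : {self.mean_abs_input_corr:.4f}",
            f"mean |corr| outputs  : {self.mean_abs_category_corr:.4f}",
            f"mean |corr| recall   : {self.mean_abs_recall_corr:.4f}",
            f"recall correct       : {self.recall_correct}/{len(self.model.forward)}",
            f"attractor stable(10) : {self.attractor_stable(10)}",
        ]
        return "\n".join(lines)
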