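"""The study's experiments as runnable procedures.

Everything here drives :class:`~cortexnet.model.CorticalModule` fits and
aggregates their diagnostics: single-run reports, multi-seed category
statistics, parameter-robustness sweeps, and the top-down attention probe.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CorticalModule, CorticalModuleResults
from .network import NetworkParams
from .patterns import PatternSet

__all__ = [
    "RunReport",
    "CategoryStatistics",
    "run_experiment",
    "category_statistics",
    "robustness_sweep",
    "attention_experiment",
]


@dataclass
class RunReport:
    """Structured record of one trained run."""

    seed: int
    n_patterns: int
    n_categories: int
    category_labels: np.ndarray
    contiguous: bool
    recall_correct: int
    attractor_stable: bool
    mean_abs_input_corr: float
    mean_abs_distinct_output_corr: float
    mean_abs_recall_corr: float
    input_corr: np.ndarray = field(repr=False)
    output_corr_forward: np.ndarray = field(repr=False)
    output_corr_recall: np.ndarray = field(repr=False)

    @property
    def recall_perfect(self) -> bool:
        return self.recall_correct == self.n_patterns

    def operates_well(self, min_categories: int = 3, max_categories: int = 6) -> bool:
        """The qualitative 'operates well' judgement made quantitative:
        perfect recall, a stable attractor, and a plausible category count."""
        return (
            self.recall_perfect
            and self.attractor_stable
            and min_categories <= self.n_categories <= max_categories
        )


def report_from_results(res: CorticalModuleResults, attractor_iters: int = 10) -> RunReport:
    """Measure every report field on a fitted module."""
    return RunReport(
        seed=res.seed,
        n_patterns=len(res.model.forward),
        n_categories=res.n_categories,
        category_labels=res.category_labels.copy(),
        contiguous=res.categories_contiguous,
        recall_correct=res.recall_correct,
        attractor_stable=res.attractor_stable(attractor_iters),
        mean_abs_input_corr=res.mean_abs_input_corr,
        mean_abs_distinct_output_corr=res.mean_abs_category_corr,
        mean_abs_recall_corr=res.mean_abs_recall_corr,
        input_corr=res.input_corr,
        output_corr_forward=res.output_corr_forward,
        output_corr_recall=res.output_corr_recall,
    )


def run_experiment(
    params: NetworkParams,
    forward: PatternSet,
    backproj: PatternSet,
    seed: int = 0,
    attractor_iters: int = 10,
) -> RunReport:
    """Train a fresh network and measure categorisation, recall fidelity and
    attractor persistence."""
    res = CorticalModule(forward, backproj, params).fit(seed=seed)
    return report_from_results(res, attractor_iters)


@dataclass
class CategoryStatistics:
    """Distribution of outcomes over independently seeded runs."""

    n_categories_counts: dict[int, int]
    modal_n_categories: int
    contiguous_rate: float
    recall_perfect_rate: float
    attractor_stable_rate: float
    reports: list[RunReport] = field(repr=False)


def category_statistics(
    params: NetworkParams,
    forward: PatternSet,
    backproj: PatternSet,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> CategoryStatistics:
    """Run the experiment with seeds ``base_seed .. base_seed + n_seeds - 1``
    and summarise the category-count distribution and success rates."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    reports = [
        run_experiment(params, forward, backproj, seed=base_seed + s)
        for s in range(n_seeds)
    ]
    counts = Counter(r.n_categories for r in reports)
    # modal value; ties broken toward the smaller category count
    modal = min(counts, key=lambda k: (-counts[k], k))
    return CategoryStatistics(
        n_categories_counts=dict(sorted(counts.items())),
        modal_n_categories=modal,
        contiguous_rate=float(np.mean([r.contiguous for r in reports])),
        recall_perfect_rate=float(np.mean([r.recall_perfect for r in reports])),
        attractor_stable_rate=float(np.mean([r.attractor_stable for r in reports])),
        reports=reports,
    )


def robustness_sweep(
    base: NetworkParams,
    grid: dict[str, list],
    forward: PatternSet,
    backproj: PatternSet,
    n_seeds: int = 5,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Evaluate every point of a parameter grid over ``n_seeds`` runs.

    ``grid`` maps parameter names (fields of :class:`NetworkParams`) to value
    lists; the cartesian product is explored.  Each row of the returned frame
    carries the grid point, the modal category count, the recall / attractor
    success rates, and an ``operational`` flag set when every run at that
    point recalls perfectly, holds its attractor, and forms 3–6 categories.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    names = list(grid)
    rows = []
    points = list(itertools.product(*(grid[n] for n in names)))
    if progress:
        from tqdm import tqdm  # soft dependency, used only for display

        points = tqdm(points, desc="sweep")
    for values in points:
        params = base.replace(**dict(zip(names, values)))
        stats = category_statistics(
            params, forward, backproj, n_seeds=n_seeds, base_seed=base_seed
        )
        row = dict(zip(names, values))
        row.update(
            modal_n_categories=stats.modal_n_categories,
            recall_perfect_rate=stats.recall_perfect_rate,
            attractor_stable_rate=stats.attractor_stable_rate,
            contiguous_rate=stats.contiguous_rate,
            operational=all(r.operates_well() for r in stats.reports),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def attention_experiment(
    res: CorticalModuleResults,
    f_gain: float = 0.5,
    b_gain: float = 0.5,
) -> pd.DataFrame:
    """Probe top-down biased competition on a trained module.

    For every ordered pair of categories (A, B) an ambiguous stimulus is
    built as the element-wise max of one exemplar of each, presented at
    ``f_gain``.  The winning category is recorded without a cue and with the
    cue of category B applied at ``b_gain``.  The frame has one row per pair
    with columns ``cued_category``, ``winner_unbiased``, ``winner_biased``
    and ``cue_wins`` (whether the cued category won under bias).
    """
    labels = res.category_labels
    cat_outputs = {c: res.category_outputs[c] for c in range(res.n_categories)}
    exemplar = {c: int(np.argmax(labels == c)) for c in cat_outputs}

    def winner(rates: np.ndarray) -> int:
        for c, out in cat_outputs.items():
            if np.array_equal(rates, out):
                return c
        return -1  # not a learned category pattern

    rows = []
    fwd = res.model.forward
    bp = res.model.backproj
    for a, b in itertools.permutations(cat_outputs, 2):
        mixture = np.maximum(fwd[exemplar[a]], fwd[exemplar[b]])
        cue = bp[exemplar[b]]
        unbiased = res.respond(f=mixture, f_gain=f_gain, b_gain=0.0)
        biased = res.respond(f=mixture, b=cue, f_gain=f_gain, b_gain=b_gain)
        rows.append(
            {
                "category_a": a,
                "category_b": b,
                "cued_category": b,
                "winner_unbiased": winner(unbiased),
                "winner_biased": winner(biased),
                "cue_wins": winner(biased) == b,
            }
        )
    return pd.DataFrame(rows)
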