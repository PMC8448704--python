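"""Binary input patterns and their correlation structure.

The simulations are driven entirely by synthetic binary rate patterns:

* *forward* patterns — correlated stimuli from the previous cortical area,
  constructed as shifted blocks of active lines so that consecutive patterns
  overlap heavily (the standard probe for competitive categorisation);
* *backprojection* patterns — short, mutually orthogonal top-down cues from
  the next cortical area, one per forward pattern;
* *random* patterns — uniform binary patterns at a given sparseness, for
  exploring the competitive network beyond the structured set.

Patterns are stored as a :class:`PatternSet`, a thin validated wrapper around
a 2-D ``uint8`` array (rows = patterns, columns = input lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternSet",
    "make_shifted_patterns",
    "make_orthogonal_patterns",
    "make_random_patterns",
    "correlation_matrix",
    "mean_abs_offdiag",
    "mean_signed_offdiag",
    "overlap",
    "consecutive_overlaps",
]

_KINDS = ("forward", "backprojection", "output")


@dataclass(frozen=True)
class PatternSet:
    """An ordered set of equal-length binary rate patterns.

    Parameters
    ----------
    values : ndarray of shape (n_patterns, n_lines)
        Binary (0/1) firing rates, one pattern per row.
    kind : {'forward', 'backprojection', 'output'}
        Which input class the patterns are destined for.
    """

    values: np.ndarray
    kind: str = "forward"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"pattern array must be 2-D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("patterns must be binary (entries 0 or 1)")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "values", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n_patterns

    def __getitem__(self, i: int) -> np.ndarray:
        return self.values[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternSet):
            return NotImplemented
        return self.kind == other.kind and np.array_equal(self.values, other.values)


def _check_sizes(n_patterns: int, n_lines: int, n_active: int) -> None:
    if n_patterns < 1 or n_lines < 1 or n_active < 1:
        raise ValueError("pattern counts and sizes must be positive")
    if n_active > n_lines:
        raise ValueError(f"n_active={n_active} exceeds n_lines={n_lines}")


def make_shifted_patterns(
    n_patterns: int = 28, n_lines: int = 100, n_active: int = 20, step: int = 3
) -> PatternSet:
    """Build the correlated forward training set of circularly shifted blocks.

    Pattern ``i`` is active on lines ``{(i*step + p) mod n_lines : p < n_active}``,
    so consecutive patterns share ``n_active - step`` active lines (17 with the
    defaults).  Positions wrap circularly, which keeps the active count and the
    consecutive overlap exact for every pattern in the set.
    """
    _check_sizes(n_patterns, n_lines, n_active)
    if step < 1:
        raise ValueError("step must be >= 1")
    values = np.zeros((n_patterns, n_lines), dtype=np.uint8)
    offsets = np.arange(n_active)
    for i in range(n_patterns):
        values[i, (i * step + offsets) % n_lines] = 1
    return PatternSet(values, kind="forward")


def make_orthogonal_patterns(
    n_patterns: int = 28, n_lines: int = 100, n_active: int = 3
) -> PatternSet:
    """Build pairwise-disjoint backprojection cues of consecutive blocks.

    Pattern ``i`` is active on lines ``{i*n_active .. i*n_active + n_active - 1}``;
    no two patterns share an active line.
    """
    _check_sizes(n_patterns, n_lines, n_active)
    if n_patterns * n_active > n_lines:
        raise ValueError(
            f"{n_patterns} disjoint patterns of {n_active} active lines "
            f"do not fit in {n_lines} lines"
        )
    values = np.zeros((n_patterns, n_lines), dtype=np.uint8)
    for i in range(n_patterns):
        values[i, i * n_active : (i + 1) * n_active] = 1
    return PatternSet(values, kind="backprojection")


def make_random_patterns(
    n_patterns: int,
    n_lines: int,
    sparseness: float,
    seed: int | np.random.Generator = 0,
    kind: str = "forward",
) -> PatternSet:
    """Draw binary patterns with exactly ``round(sparseness * n_lines)`` active
    lines each, positions chosen uniformly without replacement."""
    if not 0.0 < sparseness <= 1.0:
        raise ValueError(f"sparseness must lie in (0, 1], got {sparseness}")
    n_active = int(round(sparseness * n_lines))
    _check_sizes(n_patterns, n_lines, max(n_active, 1))
    if n_active < 1:
        raise ValueError("sparseness too low: no active lines per pattern")
    rng = np.random.default_rng(seed)
    values = np.zeros((n_patterns, n_lines), dtype=np.uint8)
    for i in range(n_patterns):
        values[i, rng.choice(n_lines, size=n_active, replace=False)] = 1
    return PatternSet(values, kind=kind)


def correlation_matrix(ps: PatternSet | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between the patterns (rows) of a set.

    Raises
    ------
    ValueError
        If fewer than two patterns are given or any pattern is constant
        (zero variance, for which Pearson correlation is undefined).
    """
    values = ps.values if isinstance(ps, PatternSet) else np.asarray(ps)
    if values.shape[0] < 2:
        raise ValueError("need at least two patterns for a correlation matrix")
    if (values.std(axis=1) == 0).any():
        bad = int(np.flatnonzero(values.std(axis=1) == 0)[0])
        raise ValueError(f"pattern {bad} is constant; correlation undefined")
    return np.corrcoef(values.astype(np.float64))


def mean_abs_offdiag(cm: np.ndarray) -> float:
    """Mean of the absolute off-diagonal entries of a square matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.shape[0]
    if cm.ndim != 2 or cm.shape[1] != n or n < 2:
        raise ValueError("need a square matrix of size >= 2")
    mask = ~np.eye(n, dtype=bool)
    return float(np.abs(cm[mask]).mean())


def mean_signed_offdiag(cm: np.ndarray) -> float:
    """Mean of the signed off-diagonal entries of a square matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.shape[0]
    if cm.ndim != 2 or cm.shape[1] != n or n < 2:
        raise ValueError("need a square matrix of size >= 2")
    mask = ~np.eye(n, dtype=bool)
    return float(cm[mask].mean())


def overlap(p1: np.ndarray, p2: np.ndarray) -> int:
    """Number of lines active in both binary patterns."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError(f"length mismatch: {p1.shape} vs {p2.shape}")
    return int(np.sum((p1 == 1) & (p2 == 1)))


def consecutive_overlaps(ps: PatternSet) -> np.ndarray:
    """Overlap of each pattern with its successor (length ``n_patterns - 1``)."""
    v = ps.values
    return np.array([overlap(v[i], v[i + 1]) for i in range(len(v) - 1)])
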