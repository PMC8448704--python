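"""Plain-text persistence: patterns, matrices, weights, reports, configs.

Everything round-trips losslessly through delimited text so that runs are
inspectable and reproducible without any binary formats.  Reals are written
with ``repr`` precision (17 significant digits), which is exact for float64.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .network import NetworkParams, SynapticState
from .patterns import PatternSet

__all__ = [
    "write_patterns",
    "read_patterns",
    "write_matrix",
    "read_matrix",
    "write_weights",
    "read_weights",
    "write_report",
    "read_report",
    "read_config",
]


class ParseError(ValueError):
    """A malformed input file; carries the offending line (1-based)."""

    def __init__(self, path, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


def _split(text: str) -> list[str]:
    # accept comma- or whitespace-separated fields, and CRLF endings
    return text.replace(",", " ").split()


def write_patterns(ps: PatternSet, path: str | Path) -> None:
    """One pattern per row of space-separated 0/1 integers, with the kind
    recorded on a leading comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {ps.kind}\n")
        for row in ps.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_patterns(path: str | Path, kind: str | None = None) -> PatternSet:
    """Read a delimited 0/1 pattern file, validating binarity and equal
    lengths; a ``# kind:`` comment line sets the default kind."""
    path = Path(path)
    rows: list[list[int]] = []
    file_kind = "forward"
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "kind:" in line:
                    file_kind = line.split("kind:", 1)[1].strip()
                continue
            fields = _split(line)
            row = []
            for col, tok in enumerate(fields, start=1):
                try:
                    v = int(tok)
                except ValueError:
                    raise ParseError(path, ln, f"column {col}: not an integer: {tok!r}") from None
                if v not in (0, 1):
                    raise ParseError(path, ln, f"column {col}: entry {v} is not binary")
                row.append(v)
            if rows and len(row) != len(rows[0]):
                raise ParseError(
                    path, ln, f"row has {len(row)} entries, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise ParseError(path, 1, "no patterns in file")
    return PatternSet(np.array(rows, dtype=np.uint8), kind=kind or file_kind)


def write_matrix(mat: np.ndarray, path: str | Path, header: bool = True) -> None:
    """Delimited-text real matrix with an optional index header row."""
    mat = np.asarray(mat, dtype=np.float64)
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("# " + " ".join(str(j) for j in range(mat.shape[1])) + "\n")
        for row in mat:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    rows = []
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in _split(line)])
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ParseError(path, ln, "ragged row")
    if not rows:
        raise ParseError(path, 1, "empty matrix file")
    return np.array(rows, dtype=np.float64)


def write_weights(syn: SynapticState, params: NetworkParams, path: str | Path, seed=None) -> None:
    """Persist the synaptic matrix in the dendrite layout: one neuron per
    column, 3*n_syn rows ordered backprojection block, recurrent block,
    forward block (top of the apical dendrite first).  A structured header
    records the parameters and seed needed to reinterpret the file."""
    path = Path(path)
    stacked = np.vstack([syn.w_bp.T, syn.w_rec.T, syn.w_comp.T])
    with path.open("w") as fh:
        fh.write("# cortexnet weights v1\n")
        for key, val in vars(params).items():
            fh.write(f"# {key} = {val}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        fh.write("# rows: bp block, rec block, comp block; columns: neurons\n")
        for row in stacked:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_weights(path: str | Path) -> tuple[SynapticState, NetworkParams, int | None]:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                rows.append([float(tok) for tok in _split(line)])
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
    params = _params_from_meta(meta)
    stacked = np.array(rows, dtype=np.float64)
    expected = 2 * params.n_syn + params.n_neurons
    if stacked.shape != (expected, params.n_neurons):
        raise ParseError(
            path, 1, f"expected {expected}x{params.n_neurons} weight rows, got {stacked.shape}"
        )
    n_syn, n = params.n_syn, params.n_neurons
    syn = SynapticState(
        w_bp=stacked[:n_syn].T.copy(),
        w_rec=stacked[n_syn : n_syn + n].T.copy(),
        w_comp=stacked[n_syn + n :].T.copy(),
    )
    seed = int(meta["seed"]) if "seed" in meta else None
    return syn, params, seed


_PARAM_TYPES = {
    "n_neurons": int,
    "n_syn": int,
    "epochs": int,
    "settle_iters": int,
    "normalize_every": str,
    "normalize_forward": lambda s: s in ("True", "true", "1"),
}


def _params_from_meta(meta: dict[str, str]) -> NetworkParams:
    kwargs = {
        key: _PARAM_TYPES.get(key, float)(meta[key])
        for key in NetworkParams.__dataclass_fields__
        if key in meta
    }
    return NetworkParams(**kwargs)


def write_report(report, path: str | Path) -> None:
    """Serialise a RunReport as key-value lines plus embedded matrices."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# cortexnet run report v1\n")
        fh.write(f"seed = {report.seed}\n")
        fh.write(f"n_patterns = {report.n_patterns}\n")
        fh.write(f"n_categories = {report.n_categories}\n")
        fh.write(f"contiguous = {report.contiguous}\n")
        fh.write(f"recall_correct = {report.recall_correct}\n")
        fh.write(f"attractor_stable = {report.attractor_stable}\n")
        fh.write(f"mean_abs_input_corr = {report.mean_abs_input_corr!r}\n")
        fh.write(f"mean_abs_distinct_output_corr = {report.mean_abs_distinct_output_corr!r}\n")
        fh.write(f"mean_abs_recall_corr = {report.mean_abs_recall_corr!r}\n")
        fh.write("category_labels = " + " ".join(map(str, report.category_labels)) + "\n")
        for name in ("input_corr", "output_corr_forward", "output_corr_recall"):
            fh.write(f"[{name}]\n")
            for row in np.asarray(getattr(report, name), dtype=np.float64):
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_report(path: str | Path) -> dict:
    """Read a run-report file back into a plain dict (matrices as arrays)."""
    path = Path(path)
    out: dict = {}
    current: str | None = None
    matrix_rows: list[list[float]] = []

    def flush() -> None:
        nonlocal current, matrix_rows
        if current is not None:
            out[current] = np.array(matrix_rows, dtype=np.float64)
        current, matrix_rows = None, []

    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                flush()
                current = line[1:-1]
                continue
            if current is not None:
                matrix_rows.append([float(tok) for tok in _split(line)])
                continue
            if "=" not in line:
                raise ParseError(path, ln, f"expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "category_labels":
                out[key] = np.array([int(t) for t in val.split()], dtype=np.int64)
            elif val in ("True", "False"):
                out[key] = val == "True"
            else:
                try:
                    out[key] = int(val)
                except ValueError:
                    out[key] = float(val)
    flush()
    return out


def read_config(path: str | Path) -> dict:
    """Flat ``key = value`` config file; values are coerced to int, float or
    str.  Lines starting with ``#`` are comments."""
    path = Path(path)
    out: dict = {}
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(path, ln, f"expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            try:
                out[key] = int(val)
            except ValueError:
                try:
                    out[key] = float(val)
                except ValueError:
                    out[key] = val
    return out
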