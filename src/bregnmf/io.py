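"""File I/O and light postprocessing.

Dense matrices travel as CSV/TSV with a header of column indices; empty
cells, "NA" and NaN encode missing entries.  MatrixMarket (MTX) is
supported for sparse interchange.  Generation and solver parameters are
written to plain key-value sidecar files.  Floats are serialized with 12
significant digits, so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import MaskedMatrix
from .robust import RobustDecomposition
from .synth import SyntheticInstance

logger = logging.getLogger("bregnmf")

_FLOAT_FMT = "%.12g"
_NA_VALUES = ["", "NA", "NaN", "nan"]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    orientation: str = "samples-rows",
    label_column: bool = False,
) -> tuple[MaskedMatrix, pd.Series | None]:
    """Read a data matrix, returning (MaskedMatrix, optional label column).

    ``orientation`` must be explicit: "samples-rows" keeps the file layout,
    "samples-cols" transposes so rows are samples internally.  With
    ``label_column`` the first column (e.g. a tumor-state annotation) is
    split off and returned separately, untouched.  Empty cells, "NA" and
    NaN become unobserved entries; a negative observed value is a hard
    error naming its position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if orientation not in ("samples-rows", "samples-cols"):
        raise ValueError(f"unknown orientation {orientation!r}")

    labels: pd.Series | None = None
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
        if label_column:
            labels = df.iloc[:, 0]
            df = df.iloc[:, 1:]
        values = df.to_numpy(dtype=float)
    elif fmt == "mtx":
        if label_column:
            raise ValueError("label_column is not supported for MTX input")
        mat = scipy.io.mmread(str(path))
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "samples-cols":
        values = values.T
    neg = np.argwhere(~np.isnan(values) & (values < 0))
    if len(neg):
        i, j = (int(k) for k in neg[0])
        raise ValueError(
            f"negative value {values[i, j]} at row {i}, column {j}; "
            "the factorization domain is non-negative"
        )
    return MaskedMatrix.from_dense(values), labels


def write_matrix(A: np.ndarray, path: str | Path, mask: np.ndarray | None = None) -> None:
    """Write a dense matrix as CSV with a header of column indices.

    If ``mask`` is given, entries where it is False are written as empty
    cells (missing).
    """
    A = np.asarray(A, dtype=float)
    if mask is not None:
        A = np.where(mask, A, np.nan)
    df = pd.DataFrame(A, columns=[str(j) for j in range(A.shape[1])])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def write_metadata(meta: dict, path: str | Path) -> None:
    """Plain key-value sidecar; nested dicts are flattened with dots."""

    def _flatten(d: dict, prefix: str = ""):
        for k, v in d.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                yield from _flatten(v, key + ".")
            else:
                yield key, v

    lines = [f"{k} = {v}" for k, v in _flatten(meta)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_decomposition(
    decomp: RobustDecomposition,
    outdir: str | Path,
    config=None,
) -> list[Path]:
    """Write a completed run: Y, S, U, V, Lambda, history and metadata.

    Fixed filenames: Y.csv, S.csv, U.csv, V.csv, Lambda.csv, history.csv,
    metadata.txt.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, A in [
        ("Y", decomp.Y),
        ("S", decomp.S),
        ("U", decomp.factors.U),
        ("V", decomp.factors.V),
        ("Lambda", decomp.Lam),
    ]:
        p = outdir / f"{name}.csv"
        write_matrix(A, p)
        written.append(p)
    hist = outdir / "history.csv"
    pd.DataFrame(decomp.history).to_csv(hist, index=False, float_format=_FLOAT_FMT)
    written.append(hist)
    meta = {
        "converged": decomp.converged,
        "n_iter": decomp.n_iter,
        "rank": decomp.factors.rank,
        "S_nonzeros": int(np.count_nonzero(decomp.S)),
    }
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    mp = outdir / "metadata.txt"
    write_metadata(meta, mp)
    written.append(mp)
    logger.info("decomposition written to %s", outdir)
    return written


def write_instance(inst: SyntheticInstance, outdir: str | Path) -> list[Path]:
    """Serialize a synthetic instance: observed matrix, truth, metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "M_observed.csv"
    write_matrix(inst.M_observed.values, p, mask=inst.M_observed.observed)
    written.append(p)
    for name, A in [("M_clean", inst.M_clean), ("S_true", inst.S_true)]:
        q = outdir / f"{name}.csv"
        write_matrix(A, q)
        written.append(q)
    mp = outdir / "metadata.txt"
    write_metadata(inst.metadata, mp)
    written.append(mp)
    return written


def cluster_index(V: np.ndarray) -> np.ndarray:
    """Assign each sample (row of V) the 1-based index of its largest loading.

    The dominant factor acts as a cluster label; ties resolve to the
    smallest index.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < 1:
        raise ValueError("V must be a 2-d matrix with at least one column")
    return np.argmax(V, axis=1) + 1
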