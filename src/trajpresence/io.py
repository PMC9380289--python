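"""Data matrices, file I/O, and PCA reduction.

The test consumes an observations-by-features numeric matrix — typically a
2-D PCA projection of a single-cell RNA-seq expression matrix, where rows
are cells and columns are principal-component scores.  This module provides
the :class:`DataMatrix` container, readers for dense CSV/TSV and sparse
MatrixMarket input, the PCA reduction step, and the :class:`RunConfig`
holding the sweep parameters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "RunConfig",
    "ConfigError",
    "ParseError",
    "load_matrix",
    "write_matrix",
    "reduce_pca",
    "STATISTIC_NAMES",
]

#: Canonical order of the three tree statistics.
STATISTIC_NAMES = ("D1", "D2", "Lmax")


class ParseError(ValueError):
    """A data file could not be parsed."""


class ConfigError(ValueError):
    """A run configuration is invalid or inconsistent with the data."""


@dataclass(frozen=True)
class DataMatrix:
    """An n x p observation-by-feature matrix with row and column labels.

    Invariants enforced on construction: n >= 3 observations, p >= 1
    features, all entries finite, and unique row/column labels.
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={values.ndim}")
        n, p = values.shape
        if n < 3:
            raise ValueError(f"need at least 3 observations, got n={n}")
        if p < 1:
            raise ValueError(f"need at least 1 feature, got p={p}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0]!r}, column {bad[1]!r}"
            )
        row_ids = tuple(str(r) for r in self.row_ids)
        col_ids = tuple(str(c) for c in self.col_ids)
        if len(row_ids) != n:
            raise ValueError(f"{len(row_ids)} row_ids for {n} rows")
        if len(col_ids) != p:
            raise ValueError(f"{len(col_ids)} col_ids for {p} columns")
        if len(set(row_ids)) != n:
            raise ValueError("row_ids are not unique")
        if len(set(col_ids)) != p:
            raise ValueError("col_ids are not unique")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", row_ids)
        object.__setattr__(self, "col_ids", col_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, row_ids=None, col_ids=None) -> "DataMatrix":
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        if row_ids is None:
            row_ids = [f"obs{i}" for i in range(n)]
        if col_ids is None:
            col_ids = [f"f{j}" for j in range(p)]
        return cls(values, tuple(row_ids), tuple(col_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)),
                   tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.row_ids),
                            columns=list(self.col_ids))

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Same labels, new values (shape must match)."""
        if np.shape(values) != self.values.shape:
            raise ValueError("shape mismatch")
        return replace(self, values=np.array(values, dtype=float))


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("csv", "tsv", "mtx"):
        return ext
    raise ValueError(f"cannot infer format from extension {ext!r}; "
                     "pass format explicitly")


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = os.path.splitext(path)[0]
    return stem + ".rows.txt", stem + ".cols.txt"


def load_matrix(path: str, format: str | None = None,
                transpose: bool = False) -> DataMatrix:
    """Read a data matrix from CSV, TSV, or MatrixMarket MTX.

    CSV/TSV files carry a header row of feature names and a first column of
    observation labels.  MTX files (coordinate format, 1-based indices) are
    densified and need sidecar ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    files with one label per line.  ``transpose=True`` flips a genes-by-cells
    MTX into the cells-by-genes orientation the test expects.

    Raises
    ------
    FileNotFoundError
        If the file (or an MTX sidecar) is missing.
    ParseError
        On malformed content; the message names the offending location.
    ValueError
        On non-numeric or non-finite entries, naming row and column.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unknown format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if fmt == "mtx":
        from scipy.io import mmread

        rows_path, cols_path = _sidecar_paths(path)
        for side in (rows_path, cols_path):
            if not os.path.exists(side):
                raise FileNotFoundError(
                    f"missing MTX sidecar name file: {side}")
        try:
            mat = mmread(path)
        except Exception as exc:  # scipy raises bare ValueError
            raise ParseError(f"malformed MTX file {path}: {exc}") from exc
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                            dtype=float)
        with open(rows_path) as fh:
            row_ids = [line.strip() for line in fh if line.strip()]
        with open(cols_path) as fh:
            col_ids = [line.strip() for line in fh if line.strip()]
        if transpose:
            values = values.T
            row_ids, col_ids = col_ids, row_ids
        if values.shape != (len(row_ids), len(col_ids)):
            raise ParseError(
                f"MTX shape {values.shape} does not match sidecars "
                f"({len(row_ids)} rows, {len(col_ids)} cols)")
    else:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                             na_values=[], keep_default_na=False,
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ParseError(f"malformed {fmt} file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no feature columns found")
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            try:
                values[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = df.index[
                    pd.to_numeric(df[col], errors="coerce").isna()][0]
                raise ValueError(
                    f"non-numeric value at row {bad!r}, column {col!r}"
                ) from exc
        row_ids = list(map(str, df.index))
        col_ids = list(map(str, df.columns))

    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at row {row_ids[i]!r}, column {col_ids[j]!r}")
    return DataMatrix(values, tuple(row_ids), tuple(col_ids))


def write_matrix(X: DataMatrix, path: str, format: str | None = None) -> None:
    """Write a matrix as CSV/TSV (with labels) or MTX (with sidecars).

    CSV output round-trips bit-identically through :func:`load_matrix`.
    """
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        from scipy.io import mmwrite

        mmwrite(path, np.asarray(X.values))
        rows_path, cols_path = _sidecar_paths(path)
        with open(rows_path, "w") as fh:
            fh.write("\n".join(X.row_ids) + "\n")
        with open(cols_path, "w") as fh:
            fh.write("\n".join(X.col_ids) + "\n")
        return
    sep = "," if fmt == "csv" else "\t"
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(X.col_ids) + "\n")
        for rid, row in zip(X.row_ids, X.values):
            fh.write(rid + sep + sep.join(repr(float(v)) for v in row)
                     + "\n")


def reduce_pca(X: DataMatrix, d: int) -> DataMatrix:
    """Project onto the top-d principal components of the centered matrix.

    Columns are centered but NOT scaled to unit variance: the test operates
    on Euclidean geometry, and variance scaling would distort it.  The sign
    of each component is fixed so that its largest-magnitude loading is
    positive, making the output reproducible across SVD implementations.
    Output columns are labelled ``PC1..PCd`` and their variances are
    non-increasing.
    """
    if not 1 <= d <= min(X.n, X.p):
        raise ValueError(
            f"d={d} outside [1, min(n, p)] = [1, {min(X.n, X.p)}]")
    centered = X.values - X.values.mean(axis=0)
    # full_matrices=False keeps U at n x min(n, p)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(d):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :d] * s[:d]
    return DataMatrix(scores, X.row_ids,
                      tuple(f"PC{j + 1}" for j in range(d)))


@dataclass(frozen=True)
class RunConfig:
    """Sweep parameters for the trajectory-presence test.

    ``k_min``/``k_max`` bound the cluster-number sweep (defaults 5..35, the
    range over which the tree shape is informative: too few clusters always
    look linear, too many always look branched).  ``n_permutations`` is the
    permutation count B per (statistic, k) cell; ``pca_dims`` selects the
    reduction applied before testing (``None`` = use data as-is, ``"auto"``
    = 2 components when p > 10).  ``statistics`` selects which of the three
    tree statistics to compute.
    """

    k_min: int = 5
    k_max: int = 35
    n_permutations: int = 1000
    seed: int = 0
    pca_dims: int | str | None = "auto"
    statistics: tuple[str, ...] = STATISTIC_NAMES
    n_restarts: int = 10
    permute_before_pca: bool = False

    def __post_init__(self):
        if not 3 <= self.k_min <= self.k_max:
            raise ConfigError(
                f"need 3 <= k_min <= k_max, got [{self.k_min}, {self.k_max}]")
        if self.n_permutations < 19:
            raise ConfigError(
                "n_permutations must be >= 19 (the smallest add-one "
                f"p-value must resolve 0.05), got {self.n_permutations}")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        stats = tuple(self.statistics)
        if not stats or any(s not in STATISTIC_NAMES for s in stats):
            raise ConfigError(
                f"statistics must be a non-empty subset of {STATISTIC_NAMES},"
                f" got {stats}")
        if len(set(stats)) != len(stats):
            raise ConfigError("duplicate statistic names")
        pca = self.pca_dims
        if isinstance(pca, str):
            if pca.lower() in ("none", ""):
                pca = None
            elif pca.lower() == "auto":
                pca = "auto"
            else:
                try:
                    pca = int(pca)
                except ValueError:
                    raise ConfigError(f"bad pca_dims {self.pca_dims!r}")
        if pca is not None and pca != "auto" and int(pca) < 1:
            raise ConfigError(f"pca_dims must be >= 1, got {pca}")
        object.__setattr__(self, "statistics", stats)
        object.__setattr__(self, "pca_dims", pca)

    def validate_against(self, X: DataMatrix) -> None:
        """Check data-dependent invariants before any computation."""
        if self.k_max > X.n - 1:
            raise ConfigError(
                f"k_max={self.k_max} must be <= n-1 = {X.n - 1}")
        if isinstance(self.pca_dims, int) and self.pca_dims > min(X.n, X.p):
            raise ConfigError(
                f"pca_dims={self.pca_dims} exceeds min(n, p)={min(X.n, X.p)}")

    def resolve_pca_dims(self, X: DataMatrix) -> int | None:
        """Resolve the 'auto' policy: 2 components when p > 10, else none."""
        if self.pca_dims == "auto":
            return 2 if X.p > 10 else None
        return self.pca_dims

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Read a flat ``key=value`` config file (# comments allowed)."""
        kwargs: dict = {}
        int_keys = {"k_min", "k_max", "n_permutations", "seed", "n_restarts"}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key in int_keys:
                    kwargs[key] = int(value)
                elif key == "pca_dims":
                    kwargs[key] = value
                elif key == "statistics":
                    kwargs[key] = tuple(
                        s.strip() for s in value.split(",") if s.strip())
                elif key == "permute_before_pca":
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)
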