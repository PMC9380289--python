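"""The trajectory-presence permutation test.

For each cluster number k in a sweep range, the observed data are
partitioned by k-means, an MST is built on the cluster centers, and three
tree-shape statistics are read off.  A permutation null — each feature
column independently reshuffled across observations, destroying any
inter-feature dependence and hence any trajectory while preserving every
marginal — yields an empirical distribution for each statistic, and a
one-tailed add-one p-value is computed: lower tail for the leaf count D1
(few leaves = linear), upper tail for the degree-two count D2 and the
longest-path length Lmax (many degree-two nodes / long diameter = linear).
The median p-value across the sweep summarizes the evidence that the point
cloud contains a trajectory.

Usage follows the model/results pattern::

    model = TrajectoryPresenceTest(X, k_min=5, k_max=35, n_permutations=1000)
    res = model.fit(seed=0)
    print(res.summary())
    res.to_tsv("report.tsv")
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import (STATISTIC_NAMES, ConfigError, DataMatrix, RunConfig,
                 reduce_pca)
from .mst import build_mst, stat_triple
from .partition import kmeans_centers

__all__ = [
    "TAILS",
    "NullDistribution",
    "TrajectoryPresenceTest",
    "TrajectoryPresenceResults",
    "permute_matrix",
    "null_distribution",
    "p_value",
    "test_trajectory_presence",
    "plot_report",
]

#: Tail of the one-sided test for each statistic.  A trajectory pushes the
#: leaf count DOWN and the degree-two count and diameter UP.
TAILS = {"D1": "lower", "D2": "upper", "Lmax": "upper"}


def permute_matrix(X: DataMatrix, seed) -> DataMatrix:
    """Independently reshuffle each column of ``X`` across rows.

    This is the null-generating operation: every marginal feature
    distribution is preserved exactly while all dependence between
    features — and with it any trajectory — is destroyed.
    """
    rng = np.random.default_rng(seed)
    values = np.column_stack(
        [rng.permutation(X.values[:, j]) for j in range(X.p)])
    return X.with_values(values)


@dataclass(frozen=True)
class NullDistribution:
    """B samples of one statistic at one k, computed on permuted data."""

    statistic: str
    k: int
    samples: np.ndarray

    def __post_init__(self):
        if self.statistic not in STATISTIC_NAMES:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        samples = np.asarray(self.samples, dtype=np.int64)
        if samples.size == 0:
            raise ValueError("empty null distribution")
        lo, hi = _stat_bounds(self.statistic, self.k)
        if samples.min() < lo or samples.max() > hi:
            raise ValueError(
                f"{self.statistic} sample outside [{lo}, {hi}] for k={self.k}")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def B(self) -> int:
        return int(self.samples.size)


def _stat_bounds(statistic: str, k: int) -> tuple[int, int]:
    if statistic == "D1":
        return 2, k - 1
    if statistic == "D2":
        return 0, k - 2
    return 2, k - 1  # Lmax


def p_value(observed: int, null: NullDistribution, tail: str) -> float:
    """Add-one empirical p-value; ties count as extreme (conservative).

    lower: (1 + #{samples <= observed}) / (1 + B)
    upper: (1 + #{samples >= observed}) / (1 + B)
    """
    samples = null.samples
    if tail == "lower":
        extreme = int(np.count_nonzero(samples <= observed))
    elif tail == "upper":
        extreme = int(np.count_nonzero(samples >= observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1 + extreme) / (1 + samples.size)


def _seed_for(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(master), spawn_key=tuple(key))


def _observed_triple(values: np.ndarray, k: int, master: int,
                     n_restarts: int):
    centers = kmeans_centers(values, k, _seed_for(master, k), n_restarts)
    return stat_triple(build_mst(centers))


def _null_triples(values: np.ndarray, k: int, B: int, master: int,
                  n_restarts: int,
                  permute_fn=None) -> np.ndarray:
    """B x 3 array of (D1, D2, Lmax) on permuted data.

    One clustering and one MST per permutation serve all three statistics;
    replicate ``r`` draws from the seed stream ``(master, k, r)``, so any
    cell of the sweep can be recomputed independently.
    """
    n, p = values.shape
    out = np.empty((B, 3), dtype=np.int64)
    for r in range(B):
        perm_rng = np.random.default_rng(_seed_for(master, k, r, 0))
        if permute_fn is None:
            permuted = np.column_stack(
                [perm_rng.permutation(values[:, j]) for j in range(p)])
        else:
            permuted = permute_fn(perm_rng)
        centers = kmeans_centers(permuted, k, _seed_for(master, k, r, 1),
                                 n_restarts)
        triple = stat_triple(build_mst(centers))
        out[r] = (triple.d1, triple.d2, triple.lmax)
    return out


def null_distribution(X: DataMatrix, k: int, statistic: str, B: int,
                      seed: int, n_restarts: int = 10) -> NullDistribution:
    """Permutation null of one statistic at one k.

    Each of the B replicates permutes the matrix, re-clusters, rebuilds the
    MST, and reads off the statistic.  Reproducible given (seed, k, B).
    """
    if statistic not in STATISTIC_NAMES:
        raise ValueError(f"unknown statistic {statistic!r}")
    triples = _null_triples(np.asarray(X.values), k, B, seed, n_restarts)
    col = STATISTIC_NAMES.index(statistic)
    return NullDistribution(statistic=statistic, k=k, samples=triples[:, col])


class TrajectoryPresenceTest:
    """Permutation test for the presence of a trajectory in a point cloud.

    Parameters
    ----------
    data : DataMatrix, pandas.DataFrame, or array-like
        Observations in rows, features in columns.  Typically the 2-D PCA
        projection of a single-cell expression matrix.
    config : RunConfig, optional
        Sweep parameters; keyword arguments build one if omitted
        (``k_min``, ``k_max``, ``n_permutations``, ``seed``, ``pca_dims``,
        ``statistics``, ``n_restarts``, ``permute_before_pca``).
    """

    def __init__(self, data, config: RunConfig | None = None, **kwargs):
        if isinstance(data, DataMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = DataMatrix.from_dataframe(data)
        else:
            self.data = DataMatrix.from_array(np.asarray(data, dtype=float))
        if config is None:
            config = RunConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        self.config = config
        config.validate_against(self.data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(DataMatrix.from_dataframe(df), **kwargs)

    @property
    def exog(self) -> np.ndarray:
        """The matrix actually tested (post-PCA when reduction applies)."""
        d = self.config.resolve_pca_dims(self.data)
        if d is None:
            return np.asarray(self.data.values)
        return np.asarray(reduce_pca(self.data, d).values)

    def fit(self, seed: int | None = None,
            keep_nulls: bool = False) -> "TrajectoryPresenceResults":
        """Run the full sweep and return the results.

        ``seed`` overrides the config seed.  With ``keep_nulls`` the
        per-(statistic, k) null samples are retained on the results object
        (memory grows with B and the sweep width).
        """
        cfg = self.config
        master = int(cfg.seed if seed is None else seed)
        cfg.validate_against(self.data)
        d = cfg.resolve_pca_dims(self.data)
        raw = np.asarray(self.data.values)
        values = raw if d is None else np.asarray(
            reduce_pca(self.data, d).values)

        permute_raw = cfg.permute_before_pca and d is not None
        stats = cfg.statistics
        rows = []
        nulls: dict = {}
        for k in range(cfg.k_min, cfg.k_max + 1):
            obs = _observed_triple(values, k, master, cfg.n_restarts)
            permute_fn = None
            if permute_raw:
                dm = self.data

                def permute_fn(rng, _dm=dm, _d=d):
                    shuffled = np.column_stack(
                        [rng.permutation(_dm.values[:, j])
                         for j in range(_dm.p)])
                    return np.asarray(
                        reduce_pca(_dm.with_values(shuffled), _d).values)

            triples = _null_triples(values, k, cfg.n_permutations, master,
                                    cfg.n_restarts, permute_fn)
            obs_map = obs.as_dict()
            for stat in stats:
                col = STATISTIC_NAMES.index(stat)
                null = NullDistribution(statistic=stat, k=k,
                                        samples=triples[:, col])
                p = p_value(obs_map[stat], null, TAILS[stat])
                rows.append((stat, k, obs_map[stat], p))
                if keep_nulls:
                    nulls[(stat, k)] = null
        table = pd.DataFrame(rows,
                             columns=["statistic", "k", "observed", "p_value"])
        return TrajectoryPresenceResults(model=self, table=table,
                                         config=cfg, seed=master,
                                         nulls=nulls if keep_nulls else None)


class TrajectoryPresenceResults:
    """Per-k p-values, observed statistics, and median-p summaries.

    ``table`` is the long-form report (statistic, k, observed, p_value);
    ``median_pvalues`` holds the sweep summary per statistic.  The median
    p-value is a summary of dependent per-k tests, not a calibrated
    p-value; no multiplicity correction is applied across k or statistics.
    """

    def __init__(self, model, table: pd.DataFrame, config: RunConfig,
                 seed: int, nulls=None):
        self.model = model
        self.table = table
        self.config = config
        self.seed = seed
        self.nulls = nulls
        # even-length sweeps take the midpoint of the two central values
        med = table.groupby("statistic")["p_value"].median()
        self.median_pvalues = med.reindex(
            [s for s in STATISTIC_NAMES if s in set(table["statistic"])])

    @property
    def pvalues(self) -> pd.DataFrame:
        """Wide form: statistics in rows, k in columns."""
        return self.table.pivot(index="statistic", columns="k",
                                values="p_value").reindex(
            self.median_pvalues.index)

    @property
    def observed(self) -> pd.DataFrame:
        """Observed statistic values, statistics in rows, k in columns."""
        return self.table.pivot(index="statistic", columns="k",
                                values="observed").reindex(
            self.median_pvalues.index)

    def summary(self) -> str:
        cfg = self.config
        data = self.model.data
        lines = [
            "Trajectory presence test (MST statistics, permutation null)",
            "=" * 62,
            f"Observations: {data.n}    Input features: {data.p}",
            f"Cluster sweep: k = {cfg.k_min}..{cfg.k_max} "
            f"({cfg.k_max - cfg.k_min + 1} values)",
            f"Permutations per k: {cfg.n_permutations}    Seed: {self.seed}",
            "-" * 62,
            f"{'statistic':<10}{'tail':<8}{'median p':>10}{'min p':>10}"
            f"{'max p':>10}",
        ]
        for stat, med in self.median_pvalues.items():
            sub = self.table[self.table["statistic"] == stat]["p_value"]
            lines.append(f"{stat:<10}{TAILS[stat]:<8}{med:>10.4g}"
                         f"{sub.min():>10.4g}{sub.max():>10.4g}")
        lines.append("-" * 62)
        lines.append("median p is the sweep summary; small values indicate "
                     "a trajectory")
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        """Write the long-form report; footer lines carry the medians.

        Output is bit-stable given identical inputs (floats via repr).
        """
        with open(path, "w") as fh:
            fh.write("statistic\tk\tobserved\tp_value\n")
            for stat, k, obs, p in self.table.itertuples(index=False):
                fh.write(f"{stat}\t{int(k)}\t{int(obs)}\t{float(p)!r}\n")
            for stat, med in self.median_pvalues.items():
                fh.write(f"# median {stat} {float(med)!r}\n")

    def plot(self, path: str | None = None, ax=None):
        """Box plot of per-k p-values per statistic, medians marked."""
        import matplotlib.pyplot as plt

        if self.table.empty:
            raise ValueError("empty report: nothing to plot")
        stats = list(self.median_pvalues.index)
        data = [self.table.loc[self.table["statistic"] == s, "p_value"]
                for s in stats]
        if ax is None:
            fig, ax = plt.subplots(figsize=(1.8 + 1.2 * len(stats), 4))
        else:
            fig = ax.figure
        ax.boxplot(data, tick_labels=stats, showmeans=False)
        for i, med in enumerate(self.median_pvalues, start=1):
            ax.annotate(f"{med:.3f}", (i, med), textcoords="offset points",
                        xytext=(6, 2), fontsize=8)
        ax.set_ylabel("p-value")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title("Trajectory presence: per-k p-values")
        if path is not None:
            fig.savefig(path, bbox_inches="tight")
            plt.close(fig)
        return ax


def test_trajectory_presence(X: DataMatrix,
                             config: RunConfig) -> TrajectoryPresenceResults:
    """Run the full pipeline on a data matrix with the given configuration."""
    return TrajectoryPresenceTest(X, config=config).fit()


def plot_report(report: TrajectoryPresenceResults, path: str) -> None:
    """Write the box-plot figure for a results object."""
    report.plot(path=path)
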