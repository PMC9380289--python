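"""Synthetic low-dimensional point clouds with known trajectory topology.

The test consumes 2-D (typically PCA) coordinates, so the generators are
geometric rather than transcriptomic: each topology is a union of smooth
branch curves in the unit square, sampled uniformly by arc length with
isotropic Gaussian noise added in all dimensions.  Ground truth (branch
label, pseudotime, and the noiseless coordinates) rides along as a sidecar
table, so every stage of the pipeline can be validated without any
download.  An optional linear "lift" maps the 2-D coordinates to a wider
noisy gene-expression-like matrix for end-to-end I/O tests.

Topologies: ``none`` (i.i.d. uniform, no structure), ``linear`` (a single
smooth arc), ``multifurcating`` (a root splitting into three children),
``converging_diverging`` (two branches merging then re-splitting), and
``disconnected_looping`` (an open circular arc plus a disjoint segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataMatrix

__all__ = ["TopologySpec", "NOISE_PRESETS", "TOPOLOGY_KINDS", "generate",
           "topology_info", "lift_to_genes"]

TOPOLOGY_KINDS = ("none", "linear", "multifurcating",
                  "converging_diverging", "disconnected_looping")

#: Default noise standard deviation per topology (coordinate units; the
#: geometry lives in the unit square).  Small enough that each topology's
#: backbone stays visible, large enough that clusters overlap along it —
#: the regime the test is meant for.
NOISE_PRESETS = {
    "none": 0.0,
    "linear": 0.05,
    "multifurcating": 0.05,
    "converging_diverging": 0.05,
    "disconnected_looping": 0.04,
}


@dataclass(frozen=True)
class TopologySpec:
    """What to generate: topology kind, size, noise, dimension, seed.

    ``noise_sd`` is the standard deviation of isotropic Gaussian noise in
    every coordinate; ``None`` selects the per-kind preset.  ``dims`` >= 2:
    the geometry lives in the first two coordinates, the rest are pure
    noise (mimicking uninformative trailing PCs).
    """

    kind: str
    n_cells: int = 500
    noise_sd: float | None = None
    seed: int = 0
    dims: int = 2

    def __post_init__(self):
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(
                f"unknown topology kind {self.kind!r}; "
                f"expected one of {TOPOLOGY_KINDS}")
        if self.n_cells < 50:
            raise ValueError(f"n_cells must be >= 50, got {self.n_cells}")
        if self.dims < 2:
            raise ValueError(f"dims must be >= 2, got {self.dims}")
        sd = self.noise_sd
        if sd is None:
            sd = NOISE_PRESETS[self.kind]
        if sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {sd}")
        object.__setattr__(self, "noise_sd", float(sd))


class _Branch:
    """A parametric curve segment with a label and a pseudotime offset."""

    def __init__(self, label: str, fn, length: float, t_offset: float):
        self.label = label
        self.fn = fn  # maps u in [0,1] -> (x, y)
        self.length = length
        self.t_offset = t_offset


def _segment(label, p0, p1, t_offset):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    return _Branch(label, lambda u: p0 + np.outer(u, p1 - p0), length,
                   t_offset)


def _arc(label, center, radius, theta0, theta1, t_offset):
    center = np.asarray(center, float)

    def fn(u):
        theta = theta0 + u * (theta1 - theta0)
        return center + radius * np.column_stack(
            [np.cos(theta), np.sin(theta)])

    return _Branch(label, fn, abs(theta1 - theta0) * radius, t_offset)


def _sine_curve(label, amplitude=0.3):
    # arc length of (t, A sin(pi t)) via fine polyline
    t = np.linspace(0.0, 1.0, 2001)
    pts = np.column_stack([t, amplitude * np.sin(np.pi * t)])
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def fn(u):
        return np.column_stack([u, amplitude * np.sin(np.pi * u)])

    return _Branch(label, fn, length, 0.0)


def _branches(kind: str) -> list[_Branch]:
    if kind == "linear":
        return [_sine_curve("main")]
    if kind == "multifurcating":
        root_end = (0.5, 0.5)
        return [
            _segment("root", (0.0, 0.5), root_end, 0.0),
            _segment("child0", root_end, (1.0, 0.15), 0.5),
            _segment("child1", root_end, (1.0, 0.5), 0.5),
            _segment("child2", root_end, (1.0, 0.85), 0.5),
        ]
    if kind == "converging_diverging":
        merge, split = (0.35, 0.5), (0.65, 0.5)
        return [
            _segment("in0", (0.0, 0.15), merge, 0.0),
            _segment("in1", (0.0, 0.85), merge, 0.0),
            _segment("mid", merge, split, 0.35),
            _segment("out0", split, (1.0, 0.15), 0.65),
            _segment("out1", split, (1.0, 0.85), 0.65),
        ]
    if kind == "disconnected_looping":
        # open arc spanning 280 degrees: the 80-degree gap is > 20% of a
        # full turn, so the loop reads as a (long) curve, not a cycle
        theta0, theta1 = np.deg2rad(40.0), np.deg2rad(320.0)
        return [
            _arc("loop", (0.4, 0.5), 0.35, theta0, theta1, 0.0),
            _segment("spur", (1.0, 0.5), (1.25, 0.5), 0.0),
        ]
    raise ValueError(kind)


def topology_info(kind: str) -> dict:
    """Ground-truth branch structure of a topology kind."""
    if kind == "none":
        return {"n_branches": 0, "n_branch_points": 0}
    branch_points = {"linear": 0, "multifurcating": 1,
                     "converging_diverging": 2, "disconnected_looping": 0}
    return {"n_branches": len(_branches(kind)),
            "n_branch_points": branch_points[kind]}


def generate(spec: TopologySpec) -> tuple[DataMatrix, pd.DataFrame]:
    """Sample a point cloud with the requested topology.

    Returns the noisy data matrix and a sidecar frame with per-point
    ground truth: ``branch`` label, ``pseudotime`` (arc length from the
    branch system's origin), and the noiseless coordinates ``true_0``,
    ``true_1``, ...  Deterministic: identical spec gives identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, dims, sd = spec.n_cells, spec.dims, spec.noise_sd

    if spec.kind == "none":
        clean = rng.uniform(0.0, 1.0, size=(n, dims))
        branch = np.array(["none"] * n)
        pseudotime = np.full(n, np.nan)
        noisy = clean + rng.normal(0.0, sd, size=(n, dims)) if sd > 0 \
            else clean
    else:
        branches = _branches(spec.kind)
        lengths = np.array([b.length for b in branches])
        # points per branch proportional to arc length, remainders to the
        # longest branches (deterministic allocation)
        quota = lengths / lengths.sum() * n
        counts = np.floor(quota).astype(int)
        short = n - counts.sum()
        for i in np.argsort(-(quota - counts))[:short]:
            counts[i] += 1
        coords, labels, times = [], [], []
        for b, c in zip(branches, counts):
            u = rng.uniform(0.0, 1.0, size=c)
            coords.append(b.fn(u))
            labels.append(np.repeat(b.label, c))
            times.append(b.t_offset + u * b.length)
        clean2d = np.concatenate(coords)
        branch = np.concatenate(labels)
        pseudotime = np.concatenate(times)
        clean = np.zeros((n, dims))
        clean[:, :2] = clean2d
        noisy = clean + rng.normal(0.0, sd, size=(n, dims)) if sd > 0 \
            else clean

    row_ids = tuple(f"cell{i}" for i in range(n))
    X = DataMatrix(noisy, row_ids,
                   tuple(f"dim{j}" for j in range(dims)))
    sidecar = pd.DataFrame({"branch": branch, "pseudotime": pseudotime},
                           index=list(row_ids))
    for j in range(dims):
        sidecar[f"true_{j}"] = clean[:, j]
    return X, sidecar


def lift_to_genes(X: DataMatrix, n_genes: int = 50, noise_sd: float = 0.1,
                  seed: int = 0) -> DataMatrix:
    """Embed low-dimensional coordinates in a wide noisy linear expression.

    Each output column is a random linear combination of the input
    coordinates plus Gaussian noise — enough structure that PCA recovers
    the original geometry, which makes the lift useful for exercising the
    full read / reduce / test path.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    W = rng.normal(0.0, 1.0, size=(X.p, n_genes))
    values = X.values @ W + rng.normal(0.0, noise_sd, size=(X.n, n_genes))
    return DataMatrix(values, X.row_ids,
                      tuple(f"g{j}" for j in range(n_genes)))
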