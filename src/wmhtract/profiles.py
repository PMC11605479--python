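"""Along-tract profiles: arc-length resampling to 100 equidistant nodes
and pointwise three-group statistics.

Each streamline is parameterized by cumulative arc length, its scalar
(FA) linearly interpolated at equidistant arc-length fractions, and the
tract profile is the unweighted cross-streamline mean at each node.
Pointwise comparison runs a one-way ANOVA per node, controls the false
discovery rate across nodes (BH), and reports Bonferroni-corrected
pairwise post hoc tests with contiguous significant node ranges per
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, DegenerateError
from .stats import fdr_adjust

N_NODES = 100


def resample_streamline(
    points: np.ndarray, values: np.ndarray, n_nodes: int = N_NODES
) -> np.ndarray:
    """Scalar values at ``n_nodes`` equidistant arc-length positions.

    ``points`` is an ordered (m, 3) array of world coordinates in mm and
    ``values`` the per-point scalar. Node j (0-based) sits at arc-length
    fraction j / (n_nodes - 1); values are linearly interpolated between
    the bracketing input points.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise DataError("streamline needs at least 2 points of shape (m, 3)")
    if len(values) != len(points):
        raise DataError("per-point values must match the point count")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise DegenerateError("zero-length streamline")
    targets = np.linspace(0.0, s[-1], n_nodes)
    return np.interp(targets, s, values)


def orient_streamline(
    points: np.ndarray, values: np.ndarray, start: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Flip a streamline so its first point is nearest the declared start
    waypoint; with no waypoint, ties break by lexicographic endpoint order."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    a, b = points[0], points[-1]
    if start is not None:
        start = np.asarray(start, dtype=float)
        flip = np.linalg.norm(b - start) < np.linalg.norm(a - start)
    else:
        flip = tuple(b) < tuple(a)
    if flip:
        return points[::-1].copy(), values[::-1].copy()
    return points, values


def resample_profile(
    streamlines: list[tuple[np.ndarray, np.ndarray]],
    n_nodes: int = N_NODES,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Mean tract profile over a set of (points, values) streamlines."""
    if not streamlines:
        raise DataError("no streamlines given")
    nodes = []
    for points, values in streamlines:
        points, values = orient_streamline(points, values, start)
        nodes.append(resample_streamline(points, values, n_nodes))
    return np.mean(nodes, axis=0)


@dataclass
class PointwiseResult:
    """Node-wise omnibus and post hoc results for one tract."""

    F: np.ndarray  # (n_nodes,)
    p: np.ndarray
    p_adj: np.ndarray
    posthoc: dict[tuple[str, str], np.ndarray]  # contrast -> per-node p (NaN off omnibus)
    ranges: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)
    alpha: float = 0.05


def _contiguous_ranges(sig: np.ndarray) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) ranges of True runs."""
    ranges = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            ranges.append((start + 1, i))
            start = None
    if start is not None:
        ranges.append((start + 1, len(sig)))
    return ranges


def pointwise_anova(
    profiles: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> PointwiseResult:
    """Pointwise three-group comparison of tract profiles.

    ``profiles`` has one row per subject: a ``group`` column plus node
    columns ``node_1 .. node_N``. Per node: one-way ANOVA across groups,
    BH-FDR across nodes; at nodes surviving the omnibus, pairwise pooled
    t-tests Bonferroni-corrected by the number of group pairs; contiguous
    significant node ranges reported per contrast.
    """
    node_cols = [c for c in profiles.columns if c.startswith("node_")]
    if not node_cols:
        raise DataError("profiles table has no node_* columns")
    node_cols = sorted(node_cols, key=lambda c: int(c.split("_")[1]))
    groups = sorted(profiles[group_col].dropna().unique())
    if len(groups) < 2:
        raise DataError("need at least two groups")
    arrays = {
        g: profiles.loc[profiles[group_col] == g, node_cols].to_numpy(float)
        for g in groups
    }
    for g, arr in arrays.items():
        if arr.shape[0] < 2:
            raise DataError(f"group {g!r} has fewer than 2 subjects")

    F, p = sps.f_oneway(*arrays.values(), axis=0)
    p_adj = fdr_adjust(p)
    omnibus = p_adj < alpha

    import itertools

    npairs = len(groups) * (len(groups) - 1) // 2
    posthoc: dict[tuple[str, str], np.ndarray] = {}
    ranges: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a, b in itertools.combinations(groups, 2):
        _, praw = sps.ttest_ind(arrays[a], arrays[b], axis=0, equal_var=True)
        pc = np.minimum(1.0, praw * npairs)
        pc = np.where(omnibus, pc, np.nan)
        posthoc[(a, b)] = pc
        ranges[(a, b)] = _contiguous_ranges(omnibus & (np.nan_to_num(pc, nan=1.0) < alpha))
    return PointwiseResult(
        F=np.asarray(F, float),
        p=np.asarray(p, float),
        p_adj=p_adj,
        posthoc=posthoc,
        ranges=ranges,
        alpha=alpha,
    )


def profiles_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy (subject, node, value) table into the wide node_* form."""
    for col in ("subject", "node", "value"):
        if col not in table.columns:
            raise DataError(f"profile table lacks column {col!r}")
    wide = table.pivot(index="subject", columns="node", values="value")
    wide.columns = [f"node_{int(c)}" for c in wide.columns]
    return wide.reset_index()
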