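"""Sliding-window dynamic functional connectivity and brain states.

Per-subject ROI time series are motion-scrubbed (framewise displacement
above 1 mm flags a frame invalid), cut into 50-TR windows shifted by one
TR, and each window's Pearson correlation matrix is Fisher-z transformed
and vectorized (upper triangle). Recurring connectivity states are found
by k-means over the pooled window vectors, with the number of states
chosen by cluster-validity indices (silhouette by default; Calinski–
Harabasz and Davies–Bouldin recorded alongside). Per-subject temporal
metrics — mean dwell time, fractional occupancy, and transition count —
are computed by run-length encoding of the window-label stream, with
scrubbed (invalid) windows treated as gaps that break runs without
counting as transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .exceptions import ConfigError, DataError, DegenerateError
from .stats import fdr_adjust, group_compare

GAP = -1  # label marking an invalid (scrubbed) window
R_CLAMP = 1.0 - 1e-7


@dataclass
class SubjectSeries:
    """One subject's ROI time series (rows = volumes, columns = ROIs)."""

    subject: str
    data: np.ndarray  # (n_volumes, n_rois)
    tr: float
    fd: np.ndarray | None = None  # framewise displacement, mm
    valid: np.ndarray | None = None  # per-frame validity flags

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("series data must be 2D (volumes x ROIs)")
        if np.isnan(self.data).any():
            raise DataError(f"series {self.subject!r} contains missing values")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if len(self.fd) != self.n_volumes:
                raise DataError("FD trace length must match volume count")
            if (self.fd < 0).any():
                raise DataError("FD must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def scrub(
    series: SubjectSeries, fd_limit: float = 1.0, max_invalid_frac: float = 0.5
) -> tuple[SubjectSeries, dict]:
    """Flag frames with FD strictly above ``fd_limit`` as invalid.

    Returns the flagged series and a report with the invalid count and an
    ``exclude`` flag raised when the invalid fraction exceeds
    ``max_invalid_frac``.
    """
    if series.fd is None:
        raise DataError(f"series {series.subject!r} has no FD trace")
    valid = series.fd <= fd_limit
    frac = 1.0 - valid.mean()
    report = {
        "subject": series.subject,
        "n_invalid": int((~valid).sum()),
        "invalid_frac": float(frac),
        "exclude": bool(frac > max_invalid_frac),
    }
    return replace(series, valid=valid), report


@dataclass
class WindowStack:
    """Vectorized window connectivity for one subject."""

    subject: str
    vectors: np.ndarray  # (n_windows, n_pairs), NaN rows where invalid
    valid: np.ndarray  # (n_windows,) bool
    window_starts: np.ndarray
    n_rois: int
    tr: float
    step: int

    @property
    def n_windows(self) -> int:
        return len(self.valid)


def _window_corr_vector(frames: np.ndarray) -> np.ndarray | None:
    """Fisher-z upper-triangle correlation vector of one window's frames."""
    if frames.shape[0] < 2:
        return None
    sd = frames.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(frames, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)  # zero-variance ROI pairs -> r = 0
    iu = np.triu_indices_from(r, k=1)
    return np.arctanh(np.clip(r[iu], -R_CLAMP, R_CLAMP))


def sliding_windows(
    series: SubjectSeries,
    window_length: int = 50,
    step: int = 1,
    min_valid_frac: float = 0.8,
    fisher: bool = True,
) -> WindowStack:
    """Sliding-window connectivity vectors.

    Window t covers frames [t*step, t*step + W - 1]; correlations use the
    window's valid frames only; windows with fewer than ``min_valid_frac``
    valid frames are flagged invalid. Window count is
    floor((T - W) / step) + 1 (131 for 180 volumes, W = 50, step 1).
    """
    W = int(window_length)
    T = series.n_volumes
    if W > T:
        raise ConfigError(f"window length {W} exceeds {T} volumes")
    if W < 2 or step < 1:
        raise ConfigError("window length must be >= 2 and step >= 1")
    valid_frames = (
        series.valid if series.valid is not None else np.ones(T, dtype=bool)
    )
    n_windows = (T - W) // step + 1
    n_pairs = series.n_rois * (series.n_rois - 1) // 2
    vectors = np.full((n_windows, n_pairs), np.nan)
    ok = np.zeros(n_windows, dtype=bool)
    starts = np.arange(n_windows) * step
    for i, t0 in enumerate(starts):
        sel = valid_frames[t0 : t0 + W]
        frames = series.data[t0 : t0 + W][sel]
        vec = _window_corr_vector(frames)
        if vec is None:
            continue
        if not fisher:
            vec = np.tanh(vec)
        vectors[i] = vec
        ok[i] = sel.mean() >= min_valid_frac
    return WindowStack(
        subject=series.subject,
        vectors=vectors,
        valid=ok,
        window_starts=starts,
        n_rois=series.n_rois,
        tr=series.tr,
        step=step,
    )


@dataclass
class StateModel:
    """k-means state model over pooled window-connectivity vectors."""

    k: int
    centroids: np.ndarray  # (k, n_pairs)
    validity: pd.DataFrame  # per candidate k: silhouette, CH, DB
    chosen_k: int
    chosen_by: str = "silhouette"

    def selected_k(self, index: str) -> int:
        """The k preferred by a given validity index."""
        v = self.validity.set_index("k")[index]
        if index == "davies_bouldin":
            return int(v.idxmin())
        return int(v.idxmax())


@dataclass
class StateSequence:
    """Per-window state labels (1..k) for one subject; GAP marks scrubbed
    windows."""

    subject: str
    labels: np.ndarray
    tr: float
    step: int


def _relabel_by_occurrence(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel states in descending pooled occurrence (ties: centroid norm)."""
    k = centroids.shape[0]
    counts = np.bincount(labels, minlength=k)
    norms = np.linalg.norm(centroids, axis=1)
    order = sorted(range(k), key=lambda j: (-counts[j], -norms[j]))
    mapping = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new
    return mapping[labels], centroids[order]


def fit_states(
    stacks: list[WindowStack],
    k_range=range(2, 7),
    n_init: int = 5,
    seed: int = 0,
    choose_by: str = "silhouette",
    silhouette_cap: int = 6000,
) -> tuple[StateModel, list[StateSequence]]:
    """Discover recurring connectivity states by k-means over all subjects.

    For each candidate k, k-means (squared-Euclidean, ``n_init`` restarts,
    seeded) is fit on the pooled valid window vectors; silhouette
    (maximize), Calinski–Harabasz (maximize) and Davies–Bouldin (minimize)
    are recorded. ``chosen_k`` follows ``choose_by`` (ties to the smaller
    k). States are relabeled in descending pooled occurrence so labels are
    deterministic, and per-subject label sequences are emitted (labels
    1..k, scrubbed windows as gaps). Silhouette uses a seeded subsample
    when the pool exceeds ``silhouette_cap`` windows.
    """
    k_range = sorted(k_range)
    if not stacks:
        raise DataError("no window stacks given")
    pool = np.concatenate([s.vectors[s.valid] for s in stacks], axis=0)
    if len(pool) < max(k_range):
        raise DataError(
            f"only {len(pool)} valid windows pooled; need >= {max(k_range)}"
        )
    if np.allclose(pool.std(axis=0), 0):
        raise DegenerateError("all window vectors identical; no state structure")

    rng = np.random.default_rng(seed)
    if len(pool) > silhouette_cap:
        sil_idx = rng.choice(len(pool), silhouette_cap, replace=False)
    else:
        sil_idx = np.arange(len(pool))
    # pairwise distances computed once and reused across candidate k
    sub = pool[sil_idx]
    sq = (sub**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * sub @ sub.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    dist = np.sqrt(d2)

    rows = []
    fits = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(pool)
        fits[k] = (km, labels)
        rows.append(
            {
                "k": k,
                "silhouette": float(
                    silhouette_score(dist, labels[sil_idx], metric="precomputed")
                ),
                "calinski_harabasz": float(calinski_harabasz_score(pool, labels)),
                "davies_bouldin": float(davies_bouldin_score(pool, labels)),
                "inertia": float(km.inertia_),
            }
        )
    validity = pd.DataFrame(rows)

    if choose_by == "davies_bouldin":
        chosen_k = int(validity.loc[validity[choose_by].idxmin(), "k"])
    else:
        chosen_k = int(validity.loc[validity[choose_by].idxmax(), "k"])
    km, labels = fits[chosen_k]
    labels, centroids = _relabel_by_occurrence(labels, km.cluster_centers_.copy())

    sequences = []
    offset = 0
    for s in stacks:
        seq = np.full(s.n_windows, GAP, dtype=int)
        nv = int(s.valid.sum())
        seq[s.valid] = labels[offset : offset + nv] + 1  # 1-based state labels
        offset += nv
        sequences.append(
            StateSequence(subject=s.subject, labels=seq, tr=s.tr, step=s.step)
        )
    model = StateModel(
        k=chosen_k,
        centroids=centroids,
        validity=validity,
        chosen_k=chosen_k,
        chosen_by=choose_by,
    )
    return model, sequences


# ---------------------------------------------------------------------------
# temporal metrics


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a label stream into (state, length) pairs,
    splitting at gaps (gaps contribute no runs and no transitions)."""
    runs = []
    cur, length = None, 0
    for lab in labels:
        if lab == GAP:
            if cur is not None:
                runs.append((cur, length))
            cur, length = None, 0
        elif lab == cur:
            length += 1
        else:
            if cur is not None:
                runs.append((cur, length))
            cur, length = lab, 1
    if cur is not None:
        runs.append((cur, length))
    return runs


def temporal_metrics(seq: StateSequence, k: int) -> dict:
    """Mean dwell time, fractional occupancy, and transitions for one
    subject.

    Dwell is reported both in windows (mean run length) and seconds (run
    length x step x TR). Occupancies are percentages of valid windows and
    sum to 100. Transitions count adjacent label changes within gap-free
    segments; the empirical k x k transition-probability matrix
    (row-normalized counts) is included. Never-visited states get
    occupancy 0 and dwell NaN.
    """
    labels = np.asarray(seq.labels)
    valid = labels != GAP
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DataError(f"subject {seq.subject!r}: all windows invalid")
    runs = _runs(labels)

    out: dict = {"subject": seq.subject, "n_valid_windows": n_valid}
    # transitions and transition counts must not bridge gaps: walk the raw
    # label stream segment-wise
    transitions = 0
    trans_counts = np.zeros((k, k))
    segments: list[list[int]] = []
    cur: list[int] = []
    for lab in labels:
        if lab == GAP:
            if cur:
                segments.append(cur)
            cur = []
        else:
            cur.append(int(lab))
    if cur:
        segments.append(cur)
    for seg in segments:
        for a, b in zip(seg[:-1], seg[1:]):
            trans_counts[a - 1, b - 1] += 1
            if a != b:
                transitions += 1

    window_seconds = seq.step * seq.tr
    for state in range(1, k + 1):
        state_runs = [length for s, length in runs if s == state]
        occ = 100.0 * sum(state_runs) / n_valid
        dwell_w = float(np.mean(state_runs)) if state_runs else float("nan")
        out[f"occupancy_{state}"] = occ
        out[f"dwell_windows_{state}"] = dwell_w
        out[f"dwell_seconds_{state}"] = dwell_w * window_seconds
    out["transitions"] = int(transitions)
    row_sums = trans_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["transition_matrix"] = np.where(
            row_sums > 0, trans_counts / row_sums, np.nan
        )
    out["transition_counts"] = trans_counts
    return out


def cohort_temporal_metrics(sequences: list[StateSequence], k: int) -> pd.DataFrame:
    """Tidy per-subject temporal-metrics table (matrices dropped)."""
    rows = []
    for seq in sequences:
        m = temporal_metrics(seq, k)
        m.pop("transition_matrix")
        m.pop("transition_counts")
        rows.append(m)
    return pd.DataFrame(rows)


def compare_temporal(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """Group comparison of every temporal metric, BH-FDR across metrics.

    Two group levels give Welch t-tests; three give one-way ANOVA with
    Bonferroni post hoc pairs (columns posthoc_<a>_vs_<b>).
    """
    df = metrics.merge(cohort[["subject", group_col]], on="subject", how="inner")
    if df.empty:
        raise DataError("no overlap between metrics and cohort subjects")
    sizes = df.groupby(group_col)["subject"].count()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise DegenerateError(f"groups with fewer than 2 subjects: {small}")
    metric_cols = [
        c
        for c in metrics.columns
        if c.startswith(("occupancy_", "dwell_")) or c == "transitions"
    ]
    rows = []
    for col in metric_cols:
        try:
            res = group_compare(df.dropna(subset=[col]), col, group_col=group_col)
        except DegenerateError:
            continue
        row = {"metric": col, "stat": res.stat, "stat_name": res.stat_name, "p": res.p}
        for g in res.levels:
            row[f"mean_{g}"] = res.means[g]
        for (a, b), p in res.posthoc.items():
            row[f"posthoc_{a}_vs_{b}"] = p
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out
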