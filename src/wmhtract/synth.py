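"""Seeded synthetic cohorts with recorded ground truth.

The generator emulates the data the analysis consumes: a 20-tract
probabilistic atlas of tubular supports, per-subject lesion probability
fields concentrated in the six burden-prone tracts (bilateral thalamic
radiation, bilateral cingulum cingulate, anterior/posterior corpus
callosum), ROI time series switching between a sparse "segregated"
covariance state and a hub-coupled "integrated" state via a first-order
Markov chain whose state-2 persistence grows with left-thalamic-
radiation lesion load, along-tract FA profiles with a planted severe-
group effect window, and a cohort table whose processing-speed score is
linearly coupled to left-thalamic-radiation load (default slope 65.6 s
per mL). Every quantity a downstream module estimates is recorded as
ground truth at generation time.

All randomness flows from ``SimulationConfig.seed`` through named
child generators, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .dfc import SubjectSeries
from .exceptions import ConfigError, DataError, SizingError
from .registry import AFFECTED_TRACTS, TRACTS
from .volumes import LesionVolume, TractAtlas

CYTOKINES = ("il1b", "il4", "il6", "il8", "il10", "il12", "ccl2", "ifng", "tnfa")

#: Planted covariate effects on each cognitive outcome (per year of age /
#: per year of education), scaled by ``covariate_effect_scale``.
COVARIATE_EFFECTS = {
    "tmta": (0.4, -1.2),
    "dsc": (-0.15, 0.8),
    "fds": (-0.01, 0.05),
    "bds": (-0.01, 0.05),
    "vf": (-0.03, 0.2),
}

#: Planted lesion-load slopes for the non-TMT-A outcomes (per mL of LTR
#: load, patients worse: speed up in seconds, scores down).
SECONDARY_SLOPES = {"dsc": -18.0, "fds": -1.0, "bds": -1.0, "vf": -3.5}

#: Outcome baselines at zero load / reference covariates.
BASELINES = {"tmta": 38.0, "dsc": 46.0, "fds": 8.3, "bds": 4.3, "vf": 18.8}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named child generator derived from the single top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def subject_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    controls = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    return patients, controls


def group_labels(config: SimulationConfig) -> pd.Series:
    patients, controls = subject_ids(config)
    return pd.Series(
        ["mTBI"] * len(patients) + ["HC"] * len(controls),
        index=patients + controls,
        name="group",
    )


# ---------------------------------------------------------------------------
# atlas


def _affine(config: SimulationConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = config.voxel_size
    return aff


def _world_coords(config: SimulationConfig) -> np.ndarray:
    """(nx*ny*nz, 3) voxel-center world coordinates."""
    grids = np.meshgrid(
        *[np.arange(s) * config.voxel_size for s in config.grid_shape], indexing="ij"
    )
    return np.stack([g.ravel() for g in grids], axis=1)


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def make_atlas(config: SimulationConfig) -> TractAtlas:
    """20 tubular tract probability maps on the config grid.

    Nine bilateral pairs are mirror images across the x mid-plane; the two
    callosal parts sit centrally. Each map is a Gaussian radial falloff
    around a line segment (peak 1 on the axis), so values lie in [0, 1]
    and every tract has positive mass.
    """
    if min(config.grid_shape) < 12:
        raise SizingError(
            f"grid {config.grid_shape} too small to place 20 tract supports "
            "(each dimension must be >= 12 voxels)"
        )
    rng = _rng(config, "atlas")
    extent = np.array(config.grid_shape) * config.voxel_size
    pts = _world_coords(config)
    sigma = config.tube_radius_mm

    maps: dict[str, np.ndarray] = {}
    bilateral = [t[1:] for t in TRACTS if t.startswith("L")]
    for stem in bilateral:
        # left-hemisphere segment in x in [0.55, 0.9] of extent
        a = np.array(
            [
                rng.uniform(0.55, 0.90) * extent[0],
                rng.uniform(0.15, 0.85) * extent[1],
                rng.uniform(0.15, 0.85) * extent[2],
            ]
        )
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # keep tubes roughly parasagittal
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.45, 0.7) * extent.min()
        b = np.clip(a + direction * length, 0.1 * extent, 0.9 * extent)
        for side in ("L", "R"):
            if side == "L":
                aa, bb = a, b
            else:  # mirror across the x mid-plane
                aa = np.array([extent[0] - a[0], a[1], a[2]])
                bb = np.array([extent[0] - b[0], b[1], b[2]])
            d = _segment_distance(pts, aa, bb)
            maps[f"{side}{stem}"] = np.exp(-(d**2) / (2 * sigma**2)).reshape(
                config.grid_shape
            )
    for name, yfrac in (("ACC", 0.25), ("PCC", 0.75)):
        a = np.array([0.30 * extent[0], yfrac * extent[1], 0.5 * extent[2]])
        b = np.array([0.70 * extent[0], yfrac * extent[1], 0.5 * extent[2]])
        d = _segment_distance(pts, a, b)
        maps[name] = np.exp(-(d**2) / (2 * sigma**2)).reshape(config.grid_shape)
    ordered = {name: maps[name] for name in TRACTS}
    return TractAtlas(maps=ordered, affine=_affine(config))


# ---------------------------------------------------------------------------
# lesions


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages estimate."""

    loads: pd.DataFrame  # tidy subject x tract wmh_ml / load_ratio_pct
    severities: pd.Series = None
    latent_sequences: dict[str, np.ndarray] = field(default_factory=dict)
    stay_probs: pd.DataFrame | None = None
    slopes: dict[str, float] = field(default_factory=dict)
    profile_effect_nodes: tuple[int, int] | None = None
    profile_effect_tracts: tuple[str, ...] = ()


def _blob(pts: np.ndarray, center: np.ndarray, radius: float, amp: float) -> np.ndarray:
    d2 = ((pts - center) ** 2).sum(axis=1)
    return amp * np.exp(-d2 / (2 * radius**2))


def _atlas_axis_point(config, rng, tract_map: np.ndarray) -> np.ndarray:
    """A high-probability location inside a tract (probability-weighted draw
    among voxels near the tube axis)."""
    flat = tract_map.ravel()
    core = np.flatnonzero(flat >= 0.95 * flat.max())
    idx = rng.choice(core)
    return _world_coords(config)[idx]


def true_tract_loads(
    lesion: LesionVolume, atlas: TractAtlas, threshold: float = 0.8
) -> dict[str, tuple[float, float]]:
    """Direct voxel-summation loads: (wmh_ml, load_ratio_pct) per tract."""
    mask = lesion.values >= threshold
    vox_ml = atlas.voxel_volume / 1000.0
    out = {}
    for name in atlas.names:
        s = float(atlas.maps[name][mask].sum())
        out[name] = (s * vox_ml, 100.0 * s / atlas.mass(name))
    return out


def make_lesions(
    config: SimulationConfig,
    atlas: TractAtlas,
    groups: pd.Series | None = None,
) -> tuple[dict[str, LesionVolume], GroundTruth]:
    """Per-subject lesion probability fields plus recorded true loads.

    Every subject receives one Gaussian blob per affected tract, centered
    on a cohort-fixed point of the tract axis, with radius scaled by a
    per-subject severity draw (patients from the higher range; the first
    patient is planted at the severity maximum when ``plant_severe``).
    Group-specific ``lesion_intensity`` scales the blob amplitude; an
    intensity of 0 yields an empty lesion field.
    """
    if groups is None:
        groups = group_labels(config)
    if atlas.shape != tuple(config.grid_shape):
        raise DataError("atlas grid does not match the config grid")
    rng = _rng(config, "lesions")
    pts = _world_coords(config)

    centers = {
        t: _atlas_axis_point(config, rng, atlas.maps[t]) for t in AFFECTED_TRACTS
    }
    volumes: dict[str, LesionVolume] = {}
    severities = {}
    load_rows = []
    for subject in groups.index:
        grp = groups[subject]
        lo, hi = (
            config.patient_severity if grp == "mTBI" else config.control_severity
        )
        sev = rng.uniform(lo, hi)
        jitter = rng.uniform(0.8, 1.2, size=len(AFFECTED_TRACTS))
        if config.plant_severe and subject == "P001" and grp == "mTBI":
            # top of the severity range at maximal jitter: guarantees this
            # patient's blobs strictly contain any control's
            sev, jitter = config.patient_severity[1], np.full_like(jitter, 1.2)
        severities[subject] = sev
        amp = float(config.lesion_intensity.get(grp, 0.0))
        field_flat = np.zeros(pts.shape[0])
        if amp > 0:
            for t, j in zip(AFFECTED_TRACTS, jitter):
                radius = config.lesion_radius_mm * sev * j
                field_flat = np.maximum(
                    field_flat, _blob(pts, centers[t], radius, amp)
                )
        vol = LesionVolume(
            values=np.clip(field_flat, 0, 1).reshape(config.grid_shape),
            affine=_affine(config),
        )
        volumes[subject] = vol
        for tract, (ml, ratio) in true_tract_loads(vol, atlas).items():
            load_rows.append(
                {
                    "subject": subject,
                    "tract": tract,
                    "wmh_ml": ml,
                    "load_ratio_pct": ratio,
                }
            )
    truth = GroundTruth(
        loads=pd.DataFrame(load_rows),
        severities=pd.Series(severities, name="severity"),
    )
    return volumes, truth


# ---------------------------------------------------------------------------
# time series


def _nearest_pd_correlation(C: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Eigenvalue-clip repair to the nearest feasible correlation matrix."""
    w, V = np.linalg.eigh(C)
    if w.min() >= floor:
        return C
    w = np.clip(w, floor, None)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def state_correlations(config: SimulationConfig, strict: bool = False) -> list[np.ndarray]:
    """Per-state ROI correlation matrices.

    State 1 is the segregated state (uniform weak off-diagonal r). State 2
    is the integrated regime: strong within-block correlation everywhere
    plus one hub ("DMN") block correlated with all other blocks. Any
    further states are alternative integrated regimes with a globally
    synchronized rotating hub block (hub rows at the within-block level
    over weak background), keeping the regimes mutually well-separated. Requested structures that are not positive definite
    are repaired by eigenvalue clipping unless ``strict``, in which case
    they raise.
    """
    n, nb = config.n_rois, config.n_blocks
    sizes = [n // nb + (1 if i < n % nb else 0) for i in range(nb)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mats = []
    C1 = np.full((n, n), config.sparse_r)
    np.fill_diagonal(C1, 1.0)
    mats.append(C1)
    for j in range(1, config.planted_k):
        hub = (j - 1) % nb
        C = np.full((n, n), config.background_r)
        if j == 1:  # the canonical integrated state: all blocks coherent
            for i in range(nb):
                s, e = edges[i], edges[i + 1]
                C[s:e, s:e] = config.within_block_r
        hs, he = edges[hub], edges[hub + 1]
        hub_to_other = config.hub_block_r if j == 1 else config.within_block_r
        C[hs:he, :] = np.where(C[hs:he, :] == config.background_r,
                               hub_to_other, C[hs:he, :])
        C[:, hs:he] = C[hs:he, :].T
        C[hs:he, hs:he] = config.within_block_r
        np.fill_diagonal(C, 1.0)
        mats.append(C)
    out = []
    for C in mats:
        if np.linalg.eigvalsh(C).min() <= 0:
            if strict:
                raise ConfigError("requested state covariance is not positive definite")
            C = _nearest_pd_correlation(C)
        out.append(C)
    return out


def stay2_probability(config: SimulationConfig, load_ml: float) -> float:
    """State-2 persistence as a function of LTR lesion load: linear in
    stay-log-odds, clipped to (0.5, 0.99)."""
    val = expit(logit(config.stay_prob) + config.occupancy_slope * load_ml)
    return float(np.clip(val, 0.5 + 1e-9, 0.99))


def _transition_matrix(config: SimulationConfig, stay2: float) -> np.ndarray:
    k = config.planted_k
    P = np.empty((k, k))
    for i in range(k):
        stay = stay2 if i == 1 else config.stay_prob
        P[i] = (1 - stay) / (k - 1)
        P[i, i] = stay
    return P


def make_timeseries(
    config: SimulationConfig,
    true_loads: pd.DataFrame,
    groups: pd.Series | None = None,
) -> tuple[list[SubjectSeries], GroundTruth]:
    """State-switching ROI time series plus recorded latent sequences.

    Per subject a first-order Markov chain over ``planted_k`` states is
    sampled per TR (state-2 persistence increasing with the subject's
    true LTR load); frames are zero-mean multivariate normal draws from
    the state's correlation matrix; an FD trace plants
    ``fd_spike_frac`` of frames above the 1 mm scrubbing limit.
    """
    if config.planted_k < 2:
        raise ConfigError("planted_k must be >= 2")
    if groups is None:
        groups = group_labels(config)
    corrs = state_correlations(config)
    chols = [np.linalg.cholesky(C) for C in corrs]
    ltr = (
        true_loads[true_loads["tract"] == "LTR"]
        .set_index("subject")["wmh_ml"]
        .reindex(groups.index)
    )
    if ltr.isna().any():
        raise DataError("true_loads lacks LTR rows for some subjects")

    rng = _rng(config, "timeseries")
    T, k = config.n_volumes, config.planted_k
    series: list[SubjectSeries] = []
    truth = GroundTruth(loads=true_loads)
    stay_rows = []
    for subject in groups.index:
        stay2 = stay2_probability(config, float(ltr[subject]))
        P = _transition_matrix(config, stay2)
        stay_rows.append({"subject": subject, "stay2": stay2})
        # stationary initial state of the planted chain
        evals, evecs = np.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        stat = np.abs(stat) / np.abs(stat).sum()
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(k, p=stat)
        u = rng.random(T)
        cumP = np.cumsum(P, axis=1)
        for t in range(1, T):
            states[t] = min(np.searchsorted(cumP[states[t - 1]], u[t]), k - 1)
        z = rng.standard_normal((T, config.n_rois))
        data = np.empty_like(z)
        for s in range(k):
            idx = states == s
            if idx.any():
                data[idx] = z[idx] @ chols[s].T
        fd = np.clip(np.abs(rng.normal(0.15, 0.08, T)), 0, 0.9)
        n_spikes = int(round(config.fd_spike_frac * T))
        if n_spikes:
            spikes = rng.choice(T, n_spikes, replace=False)
            fd[spikes] = rng.uniform(1.05, 1.8, n_spikes)
        series.append(
            SubjectSeries(subject=subject, data=data, tr=config.tr, fd=fd)
        )
        truth.latent_sequences[subject] = states + 1  # 1-based like state labels
    truth.stay_probs = pd.DataFrame(stay_rows)
    return series, truth


def planted_window_labels(
    latent: np.ndarray, window_length: int, step: int = 1, min_frac: float = 0.8
) -> np.ndarray:
    """Planted per-window state labels from a latent per-TR sequence.

    A window's planted state is the latent state occupying at least
    ``min_frac`` of its frames; windows straddling a transition without a
    dominant state have no ground-truth label and are marked 0. The 0.8
    default mirrors the 80%-valid-frames window convention. ``min_frac``
    at 0.5 degrades to a plain majority label (ties to the lower state).
    """
    latent = np.asarray(latent)
    T = len(latent)
    n_windows = (T - window_length) // step + 1
    out = np.zeros(n_windows, dtype=int)
    for i in range(n_windows):
        w = latent[i * step : i * step + window_length]
        states, counts = np.unique(w, return_counts=True)
        j = int(np.argmax(counts))
        if counts[j] >= min_frac * window_length:
            out[i] = states[j]
    return out


# ---------------------------------------------------------------------------
# cohort table


def make_cohort_table(
    config: SimulationConfig,
    true_loads: pd.DataFrame,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Demographics, cognition, and optional cytokines with planted links.

    TMT-A = baseline + slope x LTR load + covariate effects + noise; the
    other scores carry signed load slopes in the patients-worse
    direction. Age/sex/education margins approximate the cohort the
    generator emulates. Cytokine levels scale log-normally with total
    affected-tract burden when ``include_cytokines``.
    """
    if groups is None:
        groups = group_labels(config)
    rng = _rng(config, "cohort")
    ltr = (
        true_loads[true_loads["tract"] == "LTR"]
        .set_index("subject")["wmh_ml"]
        .reindex(groups.index)
    )
    if ltr.isna().any():
        raise DataError("true_loads lacks LTR rows for some subjects")
    total_load = (
        true_loads[true_loads["tract"].isin(AFFECTED_TRACTS)]
        .groupby("subject")["wmh_ml"]
        .sum()
        .reindex(groups.index)
    )

    is_pat = (groups == "mTBI").to_numpy()
    n = len(groups)
    age = np.where(
        is_pat, rng.normal(40.1, 12.6, n), rng.normal(37.3, 12.5, n)
    ).clip(18, 80)
    sex = np.where(
        rng.random(n) < np.where(is_pat, 40 / 85, 30 / 52), "F", "M"
    )
    education = np.where(
        is_pat, rng.normal(8.0, 4.16, n), rng.normal(10.8, 5.95, n)
    ).clip(0, 22)

    cs = config.covariate_effect_scale
    table = pd.DataFrame(
        {
            "subject": groups.index,
            "group": groups.to_numpy(),
            "age": age,
            "sex": sex,
            "education": education,
        }
    )
    slopes = {"tmta": config.slope_tmta_per_ml, **SECONDARY_SLOPES}
    loads_arr = ltr.to_numpy(float)
    for score, slope in slopes.items():
        a_eff, e_eff = COVARIATE_EFFECTS[score]
        sd = float(config.noise_sd.get(score, 0.0))
        vals = (
            BASELINES[score]
            + slope * loads_arr
            + cs * (a_eff * (age - 38.0) + e_eff * (education - 9.0))
            + (rng.normal(0, sd, n) if sd > 0 else 0.0)
        )
        if score != "tmta":
            vals = np.clip(vals, 0, None)
        table[score] = vals
    if config.include_cytokines:
        burden = total_load.to_numpy(float)
        for cyt in CYTOKINES:
            base = rng.lognormal(mean=1.0, sigma=0.4, size=n)
            bump = {"il1b": 0.5, "il6": 0.7, "tnfa": 0.5}.get(cyt, 0.1)
            table[cyt] = base * np.exp(bump * burden)
    truth = GroundTruth(loads=true_loads, slopes=slopes)
    return table, truth


# ---------------------------------------------------------------------------
# along-tract profiles


def make_profiles(
    config: SimulationConfig,
    subgroups: pd.Series,
    tracts=AFFECTED_TRACTS,
    n_nodes: int = 100,
) -> tuple[pd.DataFrame, GroundTruth]:
    """100-node FA profiles per subject and tract with a planted effect.

    Baseline is a smooth bump profile plus node noise; subjects labeled
    sWMH receive ``profile_effect`` added over ``profile_effect_nodes``
    (1-based inclusive) of every affected tract.
    """
    rng = _rng(config, "profiles")
    x = np.linspace(0, 1, n_nodes)
    lo, hi = config.profile_effect_nodes
    window = np.zeros(n_nodes)
    window[lo - 1 : hi] = 1.0
    rows = []
    for tract in tracts:
        base = 0.42 + 0.08 * np.sin(np.pi * x + rng.uniform(0, np.pi))
        for subject, label in subgroups.items():
            prof = base + rng.normal(0, config.profile_noise_sd, n_nodes)
            if label == "sWMH":
                prof = prof + config.profile_effect * window
            prof = np.clip(prof, 0, 1)
            row = {"subject": subject, "tract": tract, "subgroup": label}
            row.update({f"node_{j + 1}": prof[j] for j in range(n_nodes)})
            rows.append(row)
    truth = GroundTruth(
        loads=pd.DataFrame(),
        profile_effect_nodes=config.profile_effect_nodes,
        profile_effect_tracts=tuple(tracts),
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SyntheticCohort:
    """A full synthetic dataset plus its ground truth."""

    config: SimulationConfig
    atlas: TractAtlas
    lesions: dict[str, LesionVolume]
    series: list[SubjectSeries]
    cohort: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate atlas, lesions, time series, and cohort table in one call."""
    config = config or SimulationConfig()
    groups = group_labels(config)
    atlas = make_atlas(config)
    lesions, truth = make_lesions(config, atlas, groups)
    series, ts_truth = make_timeseries(config, truth.loads, groups)
    table, ct_truth = make_cohort_table(config, truth.loads, groups)
    truth.latent_sequences = ts_truth.latent_sequences
    truth.stay_probs = ts_truth.stay_probs
    truth.slopes = ct_truth.slopes
    return SyntheticCohort(
        config=config,
        atlas=atlas,
        lesions=lesions,
        series=series,
        cohort=table,
        truth=truth,
    )
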