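"""End-to-end pipeline orchestration and the run manifest.

Stages run in analysis order — lesion projection, severity subgrouping,
along-tract statistics, dynamic-state discovery, association battery —
with every stage's outputs written to disk before the next stage starts,
so any stage can be re-run from files. A manifest records the config
snapshot, input checksums, per-stage row counts, and the package
version; with identical inputs and seed the TSV/JSON outputs are
bit-identical.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io
from .config import GroupingConfig
from .dfc import (
    SubjectSeries,
    cohort_temporal_metrics,
    compare_temporal,
    fit_states,
    scrub,
    sliding_windows,
)
from .exceptions import ConfigError, DataError
from .grouping import assign_subgroups, residual_zscores
from .lesion import (
    binarize_lesion,
    cohort_probability_map,
    cohort_tract_loads,
    compare_tract_loads,
)
from .profiles import pointwise_anova
from .stats import association_suite

#: Constants every run logs (threshold, window, step, FD limit, z rule,
#: candidate state counts).
PIPELINE_CONSTANTS = {
    "lesion_threshold": 0.8,
    "window_length": 50,
    "window_step": 1,
    "fd_limit_mm": 1.0,
    "z_threshold": 1.5,
    "min_tracts": 2,
    "k_range": [2, 3, 4, 5, 6],
}


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    out_dir: str
    lesions_dir: str | None = None
    atlas_path: str | None = None
    series_dir: str | None = None
    profiles_path: str | None = None
    cohort_path: str | None = None
    lesion_threshold: float = 0.8
    window_length: int = 50
    window_step: int = 1
    fd_limit: float = 1.0
    k_range: tuple[int, int] = (2, 6)
    z_threshold: float = 1.5
    min_tracts: int = 2
    covariates: tuple[str, ...] = ("age", "sex", "education")
    seed: int = 0

    def require(self, *fields: str) -> None:
        for f in fields:
            value = getattr(self, f)
            if value is None:
                raise ConfigError(f"run config is missing required field {f!r}")
            if f.endswith(("_dir", "_path")) and not Path(value).exists():
                raise ConfigError(f"run config field {f!r}: path {value} does not exist")


def load_series_dir(series_dir: str | Path, tr: float | None = None) -> list[SubjectSeries]:
    """Read per-subject ``<id>.series.tsv`` (+ ``<id>.fd.tsv``) files.

    Series TSVs have rows = volumes and columns = ROIs; the repetition
    time is taken from a ``tr.json`` in the directory unless given.
    """
    series_dir = Path(series_dir)
    if tr is None:
        meta = series_dir / "tr.json"
        if not meta.exists():
            raise DataError(f"no tr.json in {series_dir} and no tr given")
        tr = float(io.read_json(meta)["tr"])
    out = []
    for f in sorted(series_dir.glob("*.series.tsv")):
        sid = f.name.replace(".series.tsv", "")
        data = io.read_table(f).to_numpy(float)
        fd_file = series_dir / f"{sid}.fd.tsv"
        fd = io.read_table(fd_file)["fd"].to_numpy(float) if fd_file.exists() else None
        out.append(SubjectSeries(subject=sid, data=data, tr=tr, fd=fd))
    if not out:
        raise DataError(f"no *.series.tsv files in {series_dir}")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "constants": dict(PIPELINE_CONSTANTS),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        # stage 1: lesion projection -------------------------------------
        config.require("lesions_dir", "atlas_path", "cohort_path")
        atlas = io.read_atlas(config.atlas_path)
        cohort = io.read_table(config.cohort_path, required=("subject", "group"))
        manifest["inputs"]["cohort"] = io.checksum(config.cohort_path)
        masks = {}
        for f in sorted(Path(config.lesions_dir).glob("*.nii*")):
            sid = f.name.split(".")[0]
            lesion = io.read_volume(f, lesion=True)
            masks[sid] = binarize_lesion(lesion, config.lesion_threshold)
        if not masks:
            raise DataError(f"no lesion volumes in {config.lesions_dir}")
        loads = cohort_tract_loads(masks, atlas)
        io.write_table(loads, out / "tract_loads.tsv")
        patient_masks = {
            s: m for s, m in masks.items()
            if cohort.set_index("subject")["group"].get(s) == "mTBI"
        }
        prob_map = cohort_probability_map(patient_masks or masks)
        io.write_volume(prob_map, out / "wmh_probability_map.nii.gz")
        load_tests = compare_tract_loads(loads, cohort)
        io.write_table(load_tests, out / "tract_load_tests.tsv")
        manifest["stages"]["lesion_mapping"] = {"rows": len(loads)}

        # stage 2: severity subgrouping ----------------------------------
        gconf = GroupingConfig(
            z_threshold=config.z_threshold,
            min_tracts=config.min_tracts,
            covariates=config.covariates,
        )
        z = residual_zscores(loads, cohort, gconf)
        assign = assign_subgroups(z, cohort, gconf)
        io.write_table(assign, out / "subgroups.tsv")
        cohort = cohort.merge(assign, on="subject", how="left")
        io.write_table(cohort, out / "cohort_with_subgroups.tsv")
        manifest["stages"]["severity_grouping"] = {
            "rows": len(assign),
            "n_sWMH": int((assign["subgroup"] == "sWMH").sum()),
        }

        # stage 3: along-tract pointwise statistics (optional input) -----
        if config.profiles_path is not None:
            profs = io.read_table(config.profiles_path, required=("subject", "tract"))
            profs = profs.merge(assign, on="subject", how="inner", suffixes=("", "_y"))
            rows = []
            for tract, sub in profs.groupby("tract"):
                res = pointwise_anova(sub, group_col="subgroup")
                for (a, b), ranges in res.ranges.items():
                    for lo, hi in ranges:
                        rows.append(
                            {"tract": tract, "contrast": f"{a}_vs_{b}",
                             "node_start": lo, "node_end": hi}
                        )
            io.write_table(
                pd.DataFrame(rows, columns=["tract", "contrast", "node_start", "node_end"]),
                out / "pointwise_ranges.tsv",
            )
            manifest["stages"]["tract_profile"] = {"rows": len(rows)}

        # stage 4: dynamic states ----------------------------------------
        config.require("series_dir")
        series = load_series_dir(config.series_dir)
        stacks = []
        for s in series:
            if s.fd is not None:
                s, _ = scrub(s, fd_limit=config.fd_limit)
            stacks.append(
                sliding_windows(s, config.window_length, config.window_step)
            )
        model, seqs = fit_states(
            stacks,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.seed,
        )
        metrics = cohort_temporal_metrics(seqs, model.k)
        io.write_table(metrics, out / "temporal_metrics.tsv")
        io.write_json(
            {
                "k": model.k,
                "chosen_by": model.chosen_by,
                "validity": model.validity.to_dict(orient="records"),
                "centroids": model.centroids,
            },
            out / "state_model.json",
        )
        seq_rows = [
            {"subject": q.subject, "window": i, "state": int(lab)}
            for q in seqs
            for i, lab in enumerate(q.labels)
        ]
        io.write_table(pd.DataFrame(seq_rows), out / "state_sequences.tsv")
        temporal_tests = compare_temporal(metrics, cohort)
        io.write_table(temporal_tests, out / "temporal_tests.tsv")
        manifest["stages"]["dfc"] = {"k": model.k, "rows": len(metrics)}

        # stage 5: association battery -----------------------------------
        assoc = association_suite(loads, metrics, cohort, covariates=config.covariates)
        io.write_table(assoc, out / "associations.tsv")
        manifest["stages"]["stats_assoc"] = {"rows": len(assoc)}
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    io.write_json(manifest, out / "manifest.json")
    return manifest
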