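"""Lesion-to-tract projection.

A lesion probability map is binarized at a probability threshold
(default 0.8) and overlaid on each probabilistic tract map. The
tract-specific hyperintensity volume is the probability-weighted sum of
tract-atlas values over the lesion mask, scaled to millilitres; the load
ratio normalizes that sum by the tract's total probability mass over the
whole grid, so a ratio of 100% means the lesion mask covers the entire
tract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, DegenerateError
from .stats import fdr_adjust, group_compare
from .volumes import LesionVolume, TractAtlas, Volume

LOAD_COLUMNS = ("subject", "tract", "wmh_ml", "load_ratio_pct")


def binarize_lesion(
    lesion: LesionVolume, threshold: float = 0.8, inclusive: bool = True
) -> Volume:
    """Binary lesion mask: voxel is lesioned iff probability >= threshold.

    ``inclusive=False`` switches the boundary to a strict ``>``.
    """
    if not 0 <= threshold <= 1:
        raise ConfigError(f"threshold must lie in [0, 1], got {threshold}")
    op = np.greater_equal if inclusive else np.greater
    mask = op(lesion.values, threshold).astype(np.uint8)
    return Volume(values=mask, affine=lesion.affine.copy())


def tract_load(
    mask: Volume,
    atlas: TractAtlas,
    subject: str = "subject",
    weight: str = "tract",
    lesion: LesionVolume | None = None,
) -> pd.DataFrame:
    """Per-tract hyperintensity volume (mL) and load ratio (%) for one mask.

    ``weight="tract"`` (default) sums the tract's voxel-wise probabilities
    within the lesion mask — consistent with normalizing by the tract's
    total probability mass. ``weight="lesion"`` instead sums the lesion
    probabilities within the mask (requires ``lesion``); this alternative
    reading is provided for comparison and is off by default.
    """
    Volume(mask.values, mask.affine).require_same_grid(atlas, "mask and atlas")
    m = mask.values.astype(bool)
    vox_ml = atlas.voxel_volume / 1000.0  # mm^3 -> mL
    if weight == "lesion":
        if lesion is None:
            raise ConfigError("weight='lesion' requires the lesion probability map")
        weights = lesion.values
    elif weight == "tract":
        weights = None
    else:
        raise ConfigError("weight must be 'tract' or 'lesion'")

    rows = []
    for name in atlas.names:
        tract_map = atlas.maps[name]
        total_mass = float(tract_map.sum())
        if total_mass <= 0:
            raise DegenerateError(f"tract {name!r} has zero probability mass")
        if weights is None:
            s = float(tract_map[m].sum())
        else:
            s = float((weights * (tract_map > 0))[m].sum())
        rows.append(
            {
                "subject": subject,
                "tract": name,
                "wmh_ml": s * vox_ml,
                "load_ratio_pct": 100.0 * s / total_mass,
            }
        )
    return pd.DataFrame(rows, columns=list(LOAD_COLUMNS))


def cohort_tract_loads(
    masks: dict[str, Volume], atlas: TractAtlas, **kwargs
) -> pd.DataFrame:
    """Stack :func:`tract_load` over a cohort of per-subject masks."""
    if not masks:
        raise DataError("no masks given")
    return pd.concat(
        [tract_load(m, atlas, subject=s, **kwargs) for s, m in masks.items()],
        ignore_index=True,
    )


def cohort_probability_map(masks: list[Volume] | dict[str, Volume]) -> Volume:
    """Per-voxel lesion frequency across subjects (values in [0, 1])."""
    if isinstance(masks, dict):
        masks = list(masks.values())
    if not masks:
        raise DataError("cohort probability map needs at least one mask")
    first = masks[0]
    acc = np.zeros(first.shape, dtype=float)
    for m in masks:
        first.require_same_grid(m, "cohort masks")
        acc += m.values.astype(bool)
    return Volume(values=acc / len(masks), affine=first.affine.copy())


def compare_tract_loads(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    value: str = "wmh_ml",
    group_col: str = "group",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-tract two-group comparison of lesion loads, BH-FDR corrected
    across tracts."""
    for col in ("subject", "tract", value):
        if col not in table.columns:
            raise DataError(f"load table lacks column {col!r}")
    merged = table.merge(cohort[["subject", group_col]], on="subject", how="left")
    if merged[group_col].isna().any():
        missing = merged.loc[merged[group_col].isna(), "subject"].unique()
        raise DataError(f"subjects missing from cohort table: {list(missing)[:5]}")

    rows = []
    for tract, sub in merged.groupby("tract", sort=False):
        res = group_compare(sub, value, group_col=group_col, equal_var=equal_var)
        g1, g2 = res.levels
        rows.append(
            {
                "tract": tract,
                f"mean_{g1}": res.means[g1],
                f"mean_{g2}": res.means[g2],
                f"sd_{g1}": res.sds[g1],
                f"sd_{g2}": res.sds[g2],
                "t": res.stat,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out
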