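"""Severity subgrouping by covariate-residualized lesion-load z-scores.

For each tract in the affected set, lesion load is regressed on age, sex
and education within healthy controls. Every subject's z-score is the
observed load minus the control-model prediction, divided by the control
residual standard deviation (n - p - 1 denominator). Patients exceeding
z > 1.5 on at least two tracts form the severe (sWMH) subgroup; the rest
are mild (mWMH); controls keep the HC label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GroupingConfig
from .exceptions import DataError, DegenerateError
from .stats import _encode_numeric


def residual_zscores(
    loads: pd.DataFrame,
    cohort: pd.DataFrame,
    config: GroupingConfig | None = None,
) -> pd.DataFrame:
    """Per-subject, per-tract residualized z-scores (wide: subject x tract)."""
    config = config or GroupingConfig()
    for col in ("subject", "tract", config.value):
        if col not in loads.columns:
            raise DataError(f"load table lacks column {col!r}")
    wide = loads.pivot(index="subject", columns="tract", values=config.value)
    missing = [t for t in config.tract_set if t not in wide.columns]
    if missing:
        raise DataError(f"load table lacks tracts: {missing}")

    cov_cols = list(config.covariates)
    cdf = cohort.set_index("subject")
    df = wide.join(cdf[["group", *cov_cols]], how="inner")
    if df["group"].isna().any():
        raise DataError("subjects without a group label")
    controls = df[df["group"] == "HC"]
    p = len(cov_cols)
    if len(controls) < p + 2:
        raise DataError(
            f"need at least {p + 2} controls to residualize {p} covariates"
        )

    X_all = np.column_stack(
        [np.ones(len(df))] + [_encode_numeric(df[c]).to_numpy(float) for c in cov_cols]
    )
    hc = (df["group"] == "HC").to_numpy()
    X_hc = X_all[hc]
    if np.linalg.matrix_rank(X_hc) < X_hc.shape[1]:
        raise DegenerateError("singular covariate design in controls")

    out = {}
    for tract in config.tract_set:
        y_hc = controls[tract].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X_hc, y_hc, rcond=None)
        resid = y_hc - X_hc @ beta
        dof = len(y_hc) - X_hc.shape[1]
        sd = float(np.sqrt((resid**2).sum() / dof))
        scale = max(float(np.abs(y_hc).max()), 1.0)
        if sd <= scale * 1e-10:
            raise DegenerateError(
                f"zero control residual variance for tract {tract!r}"
            )
        out[tract] = (df[tract].to_numpy(float) - X_all @ beta) / sd
    z = pd.DataFrame(out, index=df.index)
    z.index.name = "subject"
    return z


def assign_subgroups(
    z: pd.DataFrame,
    cohort: pd.DataFrame,
    config: GroupingConfig | None = None,
) -> pd.DataFrame:
    """Label every subject sWMH / mWMH / HC from the z-score table."""
    config = config or GroupingConfig()
    missing = [t for t in config.tract_set if t not in z.columns]
    if missing:
        raise DataError(f"z table lacks tracts: {missing}")
    zz = z[list(config.tract_set)]
    if zz.isna().any().any():
        raise DataError("missing z-scores")
    op = np.greater if config.strict else np.greater_equal
    exceed = op(zz.to_numpy(float), config.z_threshold).sum(axis=1)

    groups = cohort.set_index("subject")["group"]
    labels = []
    for subject, count in zip(zz.index, exceed):
        if groups.get(subject) == "HC":
            labels.append("HC")
        else:
            labels.append("sWMH" if count >= config.min_tracts else "mWMH")
    out = pd.DataFrame({"subject": zz.index, "subgroup": labels})
    return out.reset_index(drop=True)


def subgroup_cohort(
    loads: pd.DataFrame,
    cohort: pd.DataFrame,
    config: GroupingConfig | None = None,
) -> pd.DataFrame:
    """Cohort table with an added ``subgroup`` column (convenience)."""
    z = residual_zscores(loads, cohort, config)
    assign = assign_subgroups(z, cohort, config)
    return cohort.merge(assign, on="subject", how="left")
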