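"""Statistical layer: group comparisons, covariate-adjusted linear
associations, and Benjamini–Hochberg multiplicity control.

Group contrasts use two-sample t-tests (Welch by default) or chi-square
for categorical variables, and one-way ANOVA with Bonferroni-corrected
pairwise post hoc tests for three-level factors. Associations are
Gaussian identity-link linear models (outcome ~ predictor + covariates),
reported as per-unit slopes with t-based 95% CIs and standardized
coefficients. Families of tests are corrected with BH-FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, DegenerateError
from .registry import AFFECTED_TRACTS

COGNITIVE_SCORES = ("tmta", "dsc", "fds", "bds", "vf")


# ---------------------------------------------------------------------------
# multiplicity


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Monotone, capped at 1, invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupTestResult:
    variable: str
    levels: tuple[str, ...]
    n: dict[str, int]
    means: dict[str, float]
    sds: dict[str, float]
    stat_name: str
    stat: float
    p: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)


def group_compare(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    categorical: bool = False,
    equal_var: bool = False,
    yates: bool = False,
) -> GroupTestResult:
    """Compare a variable across 2 or 3 group levels.

    Two levels: Welch t-test (``equal_var=True`` for pooled) or Pearson
    chi-square for categorical variables (``yates=True`` adds the 2x2
    continuity correction). Three levels: one-way ANOVA with
    Bonferroni-corrected pairwise pooled t post hoc tests.
    """
    if variable not in cohort.columns:
        raise DataError(f"column {variable!r} not in cohort table")
    df = cohort[[group_col, variable]].dropna()
    levels = tuple(sorted(df[group_col].unique()))
    if len(levels) not in (2, 3):
        raise DataError(f"need 2 or 3 group levels, found {len(levels)}")

    if categorical:
        tab = pd.crosstab(df[group_col], df[variable])
        chi2, p, _, expected = sps.chi2_contingency(tab.values, correction=yates)
        if (expected < 1).any():
            raise DataError("chi-square expected counts below 1")
        counts = df.groupby(group_col)[variable].count().to_dict()
        return GroupTestResult(
            variable, levels, counts, {}, {}, "chi2", float(chi2), float(p)
        )

    samples = {g: df.loc[df[group_col] == g, variable].to_numpy(float) for g in levels}
    for g, x in samples.items():
        if len(x) < 2:
            raise DegenerateError(f"group {g!r} has fewer than 2 observations")
    if all(np.std(x) == 0 for x in samples.values()) and len(
        {x[0] for x in samples.values()}
    ) == 1:
        raise DegenerateError(f"variable {variable!r} is constant")

    n = {g: len(x) for g, x in samples.items()}
    means = {g: float(np.mean(x)) for g, x in samples.items()}
    sds = {g: float(np.std(x, ddof=1)) for g, x in samples.items()}

    if len(levels) == 2:
        a, b = (samples[g] for g in levels)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupTestResult(variable, levels, n, means, sds, "t", float(t), float(p))

    f, p = sps.f_oneway(*(samples[g] for g in levels))
    posthoc: dict[tuple[str, str], float] = {}
    npairs = len(levels) * (len(levels) - 1) // 2
    for a, b in itertools.combinations(levels, 2):
        _, praw = sps.ttest_ind(samples[a], samples[b], equal_var=True)
        posthoc[(a, b)] = float(min(1.0, praw * npairs))
    return GroupTestResult(
        variable, levels, n, means, sds, "F", float(f), float(p), posthoc
    )


# ---------------------------------------------------------------------------
# covariate-adjusted association


@dataclass
class AssocResult:
    outcome: str
    predictor: str
    n: int
    slope: float
    ci_low: float
    ci_high: float
    beta_std: float
    p: float
    covariates: tuple[str, ...]
    p_adj: float | None = None
    n_dropped: int = 0

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "n": self.n,
            "slope": self.slope,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "beta_std": self.beta_std,
            "p": self.p,
            "p_adj": self.p_adj,
            "covariates": ",".join(self.covariates),
        }


def _encode_numeric(s: pd.Series) -> pd.Series:
    """Encode a two-level categorical column (e.g. sex) as a 0/1 indicator."""
    if s.dtype.kind in "ifub":
        return s.astype(float)
    cats = sorted(s.dropna().unique())
    if len(cats) > 2:
        raise DataError(f"cannot encode {s.name!r}: more than two levels")
    return s.map({c: float(i) for i, c in enumerate(cats)})


def adjusted_association(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=("age", "sex", "education"),
    alpha: float = 0.05,
) -> AssocResult:
    """Linear model ``outcome ~ predictor + covariates``.

    Returns the per-unit slope of the predictor, its t-based 95% CI, the
    standardized coefficient (slope scaled by sd(predictor)/sd(outcome)),
    and the raw p-value. Rows with missing values are dropped listwise.
    """
    covariates = tuple(covariates)
    cols = [outcome, predictor, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    data = df[cols].copy()
    for c in cols:
        data[c] = _encode_numeric(data[c])
    n_before = len(data)
    data = data.dropna()
    n = len(data)
    if n <= len(covariates) + 2:
        raise DegenerateError(f"n={n} too small for {len(covariates)} covariates")

    X = sm.add_constant(data[[predictor, *covariates]].to_numpy(float))
    y = data[outcome].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=alpha)
    sx = float(np.std(data[predictor], ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise DegenerateError("zero variance in predictor or outcome")
    return AssocResult(
        outcome=outcome,
        predictor=predictor,
        n=n,
        slope=slope,
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        beta_std=slope * sx / sy,
        p=float(fit.pvalues[1]),
        covariates=covariates,
        n_dropped=n_before - n,
    )


# ---------------------------------------------------------------------------
# the association battery


def association_suite(
    loads: pd.DataFrame,
    metrics: pd.DataFrame | None,
    cohort: pd.DataFrame,
    tracts=AFFECTED_TRACTS,
    scores=COGNITIVE_SCORES,
    covariates=("age", "sex", "education"),
    subset: str | None = "mTBI",
    load_value: str = "wmh_ml",
) -> pd.DataFrame:
    """Run the three association families and BH-correct within each.

    Family 1: tract lesion loads -> cognitive scores.
    Family 2: tract lesion loads -> temporal dynamics metrics.
    Family 3: temporal dynamics (occupancy, dwell) -> cognitive scores.

    ``loads`` is the tidy per-subject-per-tract table; ``metrics`` the wide
    per-subject temporal-metrics table (or None to skip families 2 and 3).
    Models run within ``subset`` of the cohort (default: patients only).
    """
    if loads is None or len(loads) == 0:
        raise DataError("empty tract-load table")
    wide = loads.pivot(index="subject", columns="tract", values=load_value)
    missing_tracts = [t for t in tracts if t not in wide.columns]
    if missing_tracts:
        raise DataError(f"loads table lacks tracts: {missing_tracts}")
    wide = wide[list(tracts)].add_prefix("load_")

    df = cohort.set_index("subject").join(wide, how="inner")
    lost = set(cohort["subject"]) - set(df.index)
    if metrics is not None:
        if len(metrics) == 0:
            raise DataError("empty temporal-metrics table")
        df = df.join(metrics.set_index("subject"), how="left")
    if subset is not None:
        df = df[df["group"] == subset]
    df = df.reset_index()
    if len(lost) == len(cohort):
        raise DataError("no subject ids in common between loads and cohort")

    rows: list[dict] = []

    def run_family(name: str, pairs: list[tuple[str, str]]) -> None:
        results = []
        for outcome, predictor in pairs:
            if outcome not in df.columns or predictor not in df.columns:
                continue
            try:
                results.append(adjusted_association(df, outcome, predictor, covariates))
            except DegenerateError:
                continue
        if not results:
            return
        adj = fdr_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
            rows.append({"family": name, **r.to_row()})

    run_family(
        "load_cognition",
        [(s, f"load_{t}") for t in tracts for s in scores],
    )
    if metrics is not None:
        metric_cols = [
            c for c in df.columns
            if c.startswith(("occupancy_", "dwell_windows_")) or c == "transitions"
        ]
        run_family(
            "load_dynamics",
            [(m, f"load_{t}") for t in tracts for m in metric_cols],
        )
        dyn_pred = [c for c in metric_cols if c != "transitions"]
        run_family(
            "dynamics_cognition",
            [(s, m) for m in dyn_pred for s in scores],
        )
    return pd.DataFrame(rows)
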