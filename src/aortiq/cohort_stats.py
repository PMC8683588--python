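"""Growth rates and the covariate-screened linear-model analysis.

The statistical strategy mirrors a longitudinal aneurysm follow-up analysis:

* growth rate = (follow-up measure - baseline measure) / interval, per
  patient and aortic segment, in mm/year;
* unpaired t-tests for group differences (Welch by default), optionally
  age-adjusted via a linear model;
* univariable screening of candidate predictors against each growth outcome,
  with candidates entering the multivariable model iff p < 0.20, while age
  and sex are forced into every model regardless of the screen;
* multivariable ordinary least squares on complete cases, with t-distribution
  p-values (appropriate at the small n of such cohorts) and no
  multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CohortError

logger = logging.getLogger(__name__)

SEGMENTS = ("S1", "S2", "S3", "S4")


@dataclass
class ModelFit:
    outcome: str
    predictors: list[str]
    beta: pd.Series
    se: pd.Series
    p_value: pd.Series
    n_used: int
    r2: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se, "p_value": self.p_value})


@dataclass
class ScreenResult:
    outcome: str
    table: pd.DataFrame  # index: candidate; columns: p_value, included, forced

    @property
    def included(self) -> list[str]:
        return list(self.table.index[self.table["included"]])


@dataclass
class GroupComparison:
    variable: str
    group_means: dict[str, float]
    t_statistic: float
    p_value: float
    age_adjusted_beta: float | None = None
    age_adjusted_p: float | None = None
    n_per_group: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------


def compute_growth_rates(
    table: pd.DataFrame, segments: tuple[str, ...] = SEGMENTS
) -> pd.DataFrame:
    """Per-patient, per-segment diameter and length growth rates (mm/year).

    rate = (follow-up - baseline) / interval_years, computed independently for
    diameter and length.  A missing timepoint yields a missing rate (never
    zero).  A non-positive interval is an error.
    """
    if "interval_years" not in table:
        raise CohortError("table lacks an interval_years column")
    interval = table["interval_years"]
    if (interval.dropna() <= 0).any():
        bad = table.index[interval <= 0].tolist()
        raise CohortError(f"non-positive follow-up interval for rows {bad}")
    out = pd.DataFrame(index=table.index)
    for seg in segments:
        for meas in ("diameter", "length"):
            base = f"baseline_{meas}_{seg}_mm"
            fu = f"followup_{meas}_{seg}_mm"
            if base in table and fu in table:
                out[f"{meas}_growth_{seg}_mm_per_year"] = (
                    (table[fu] - table[base]) / interval
                )
    if out.empty:
        raise CohortError("no baseline/follow-up measurement pairs found in the table")
    return out


def growth_summary_by_group(
    table: pd.DataFrame, rates: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Mean +/- SD growth per segment and group (the cohort-summary table shape)."""
    rows = []
    for col in rates.columns:
        meas, _, rest = col.partition("_growth_")
        seg = rest.split("_")[0]
        for grp, idx in table.groupby(group_col).groups.items():
            vals = rates.loc[idx, col].dropna()
            rows.append(
                {
                    "segment": seg,
                    "measure": meas,
                    "group": grp,
                    "mean_mm_per_year": vals.mean(),
                    "sd_mm_per_year": vals.std(ddof=1),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


def _design(table: pd.DataFrame, outcome: str, predictors: list[str]):
    cols = [outcome, *predictors]
    missing = [c for c in cols if c not in table]
    if missing:
        raise CohortError(f"columns absent from the table: {missing}")
    sub = table[cols].apply(pd.to_numeric, errors="coerce").dropna()  # complete case
    y = sub[outcome]
    x = sm.add_constant(sub[predictors], has_constant="add")
    return y, x, len(sub)


def fit_linear_model(
    table: pd.DataFrame, outcome: str, predictors: list[str]
) -> ModelFit:
    """Ordinary least squares of ``outcome`` on ``predictors``, complete cases only.

    Betas, standard errors and two-sided p-values come from the t distribution
    with residual degrees of freedom.  Rank deficiency is an error naming the
    collinear predictors rather than a silently dropped column.
    """
    y, x, n = _design(table, outcome, predictors)
    if n < len(predictors) + 2:
        raise CohortError(
            f"{n} complete cases for {len(predictors)} predictors; "
            "need at least predictors + 2"
        )
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        collinear = _find_collinear(x)
        raise CohortError(f"design matrix is rank deficient; collinear predictors: {collinear}")
    res = sm.OLS(y, x).fit()
    return ModelFit(
        outcome=outcome,
        predictors=list(predictors),
        beta=res.params,
        se=res.bse,
        p_value=res.pvalues,
        n_used=n,
        r2=float(res.rsquared),
    )


def _find_collinear(x: pd.DataFrame) -> list[str]:
    arr = x.to_numpy()
    full = np.linalg.matrix_rank(arr)
    names = []
    for j, col in enumerate(x.columns):
        rest = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(rest) == full:
            names.append(str(col))
    return names or list(map(str, x.columns))


def screen_covariates(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    forced: tuple[str, ...] = ("age_years", "sex_male"),
    threshold: float = 0.20,
    min_n: int = 10,
) -> ScreenResult:
    """Univariable screen: include a candidate iff p < threshold, or when forced.

    Each candidate is tested in a simple linear model ``outcome ~ candidate``
    on complete cases.  Age and sex are included in every multivariable model
    regardless of their univariable association.  Constant candidates are
    excluded with a warning.
    """
    n_outcome = pd.to_numeric(table.get(outcome), errors="coerce").notna().sum()
    if n_outcome < min_n:
        raise CohortError(
            f"outcome {outcome!r} present for only {n_outcome} patients (need >= {min_n})"
        )
    rows = {}
    for cand in dict.fromkeys(list(candidates) + list(forced)):
        is_forced = cand in forced
        vals = pd.to_numeric(table.get(cand), errors="coerce")
        if vals is None or vals.dropna().nunique() < 2:
            if is_forced:
                raise CohortError(f"forced covariate {cand!r} is constant or absent")
            logger.warning("candidate %r is constant; excluded from screening", cand)
            rows[cand] = {"p_value": np.nan, "included": False, "forced": False}
            continue
        fit = fit_linear_model(table, outcome, [cand])
        p = float(fit.p_value[cand])
        rows[cand] = {
            "p_value": p,
            "included": bool(p < threshold) or is_forced,
            "forced": is_forced,
        }
    return ScreenResult(outcome=outcome, table=pd.DataFrame.from_dict(rows, orient="index"))


def screened_multivariable_fit(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    forced: tuple[str, ...] = ("age_years", "sex_male"),
    threshold: float = 0.20,
) -> tuple[ScreenResult, ModelFit]:
    """The full strategy: screen at p < threshold, then fit the multivariable model."""
    screen = screen_covariates(table, outcome, candidates, forced=forced, threshold=threshold)
    fit = fit_linear_model(table, outcome, screen.included)
    return screen, fit


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    equal_var: bool = False,
    age_adjust: bool = False,
    age_col: str = "age_years",
) -> GroupComparison:
    """Unpaired two-sided t-test between the two groups (Welch unless equal_var).

    With ``age_adjust=True`` the group effect is additionally estimated from a
    linear model ``variable ~ group + age`` and its coefficient/p reported.
    """
    groups = list(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise CohortError(f"expected exactly 2 groups, found {groups}")
    if "Marfan" in groups:  # convention: Marfan coded 1 in the adjusted model
        groups = [g for g in groups if g != "Marfan"] + ["Marfan"]
    sub = table[[group_col, variable]].dropna()
    a = sub.loc[sub[group_col] == groups[0], variable].to_numpy(dtype=float)
    b = sub.loc[sub[group_col] == groups[1], variable].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs at least 2 members for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    out = GroupComparison(
        variable=variable,
        group_means={str(groups[0]): float(a.mean()), str(groups[1]): float(b.mean())},
        t_statistic=float(t),
        p_value=float(p),
        n_per_group={str(groups[0]): len(a), str(groups[1]): len(b)},
    )
    if age_adjust:
        tmp = table[[group_col, variable, age_col]].dropna().copy()
        tmp["_group"] = (tmp[group_col] == groups[1]).astype(float)
        fit = fit_linear_model(tmp, variable, ["_group", age_col])
        out.age_adjusted_beta = float(fit.beta["_group"])
        out.age_adjusted_p = float(fit.p_value["_group"])
    return out
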