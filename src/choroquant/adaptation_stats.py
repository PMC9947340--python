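"""Paired dark/light-adaptation statistics for the glucose-vs-control design.

Every subject is measured under two conditions (control, hyperglycemia) at
five timepoints (baseline in ambient light, after 45 min dark adaptation, and
30 s / 2 min / 5 min after return to ambient light).  The estimand of the
condition contrast at a post-baseline timepoint is the between-condition
difference of within-condition changes from baseline,

    d_i = [x_i(glc, t) − x_i(glc, base)] − [x_i(ctl, t) − x_i(ctl, base)],

reported as mean ± SE with a two-sided p-value.  Covariate adjustment for
axial length and age is done by ordinary least squares of d_i on mean-centered
covariates; the intercept is then the adjusted mean difference.  Because the
analysis is run on per-subject paired differences, the subject-level random
intercept of an equivalent mixed model cancels exactly, and with no
covariates the estimator reduces to the textbook paired t-test.

Within-condition changes between two timepoints are tested with the
paired-samples t-test.  No multiple-testing correction is applied by default
(a Holm option is available); significance is flagged at α = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import EstimationError, ValidationError
from .scan_model import Condition, Timepoint

__all__ = [
    "PARAMETERS",
    "MeasurementTable",
    "DifferenceReport",
    "paired_differences",
    "adjusted_mean_difference",
    "within_condition_change",
    "build_report",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("LV", "SV", "TCV", "CVI")
DEFAULT_COVARIATES = ("axial_length_mm", "age_years")
_REQUIRED_COLUMNS = {
    "subject_id",
    "condition",
    "timepoint",
    "ring_inner_mm",
    "ring_outer_mm",
    "parameter",
    "value",
}


@dataclass
class MeasurementTable:
    """Long-format measurements joined with subject covariates.

    At most one record per (subject, condition, timepoint, ring, parameter).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = _REQUIRED_COLUMNS - set(self.data.columns)
        if missing:
            raise ValidationError(f"measurement table lacks columns {sorted(missing)}")
        keys = ["subject_id", "condition", "timepoint", "ring_inner_mm",
                "ring_outer_mm", "parameter"]
        if len(self.data) and self.data.duplicated(subset=keys).any():
            raise ValidationError("duplicate (subject, condition, timepoint, ring, parameter) records")

    @property
    def rings(self) -> list[tuple[float, float]]:
        if self.data.empty:
            return []
        pairs = self.data[["ring_inner_mm", "ring_outer_mm"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))


@dataclass(frozen=True)
class AdjustedDifference:
    mean_diff: float
    se: float
    p_value: float
    n_pairs: int


@dataclass
class DifferenceReport:
    """Grid of condition contrasts: one row per (timepoint, ring, parameter)."""

    records: pd.DataFrame
    alpha: float = 0.05

    def to_text(self) -> str:
        """Pretty grid per ring: parameters × post-baseline timepoints,
        cells formatted ``mean ± SE`` with a star below the α level."""
        if self.records.empty:
            return "(empty report)\n"
        lines = []
        tps = [t.value for t in Timepoint if t is not Timepoint.BASELINE]
        for (inner, outer), sub in self.records.groupby(["ring_inner_mm", "ring_outer_mm"]):
            lines.append(f"Ring {inner:g}-{outer:g} mm  (mean difference glucose - control ± SE)")
            header = f"{'parameter':<10}" + "".join(f"{tp:>16}" for tp in tps)
            lines.append(header)
            for p in PARAMETERS:
                row = f"{p:<10}"
                for tp in tps:
                    cell = sub[(sub.parameter == p) & (sub.timepoint == tp)]
                    if cell.empty or not np.isfinite(cell.iloc[0].mean_diff):
                        row += f"{'--':>16}"
                    else:
                        c = cell.iloc[0]
                        star = "*" if c.p_value < self.alpha else ""
                        row += f"{f'{c.mean_diff:+.2f} ± {c.se_diff:.2f}{star}':>16}"
                lines.append(row)
            lines.append("")
        return "\n".join(lines)


def _pivot(table: MeasurementTable, ring: tuple[float, float], parameter: str) -> pd.DataFrame:
    df = table.data
    sub = df[
        (df.parameter == parameter)
        & (df.ring_inner_mm == ring[0])
        & (df.ring_outer_mm == ring[1])
    ]
    return sub.pivot_table(
        index="subject_id", columns=["condition", "timepoint"], values="value",
        aggfunc="first",
    )


def paired_differences(
    table: MeasurementTable,
    timepoint: str | Timepoint,
    ring: tuple[float, float],
    parameter: str,
) -> pd.DataFrame:
    """Per-subject glucose − control differences at one timepoint.

    At baseline the raw values are differenced; at post-baseline timepoints
    each condition's value is first expressed as change from its own baseline
    (the design's readout is parameter *change*).  Subjects missing any needed
    session are dropped with a logged warning.  Returns columns
    ``subject_id, diff`` plus any covariates present in the table.
    """
    tp = Timepoint(timepoint).value
    wide = _pivot(table, ring, parameter)
    glc, ctl = Condition.HYPERGLYCEMIA.value, Condition.CONTROL.value
    base = Timepoint.BASELINE.value
    if tp == base:
        needed = [(glc, base), (ctl, base)]
    else:
        needed = [(glc, tp), (glc, base), (ctl, tp), (ctl, base)]
    for col in needed:
        if col not in wide.columns:
            raise EstimationError(f"no data for {col} at ring {ring}, {parameter}")
    complete = wide[needed].dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning(
            "%d subject(s) dropped at %s/%s/%s for missing sessions",
            n_dropped, tp, ring, parameter,
        )
    if len(complete) < 2:
        raise EstimationError("fewer than 2 complete pairs")
    if tp == base:
        d = complete[(glc, base)] - complete[(ctl, base)]
    else:
        d = (complete[(glc, tp)] - complete[(glc, base)]) - (
            complete[(ctl, tp)] - complete[(ctl, base)]
        )
    out = pd.DataFrame({"subject_id": complete.index, "diff": d.to_numpy()})
    for cov in DEFAULT_COVARIATES:
        if cov in table.data.columns:
            cov_map = table.data.groupby("subject_id")[cov].first()
            out[cov] = cov_map.reindex(complete.index).to_numpy()
    return out


def adjusted_mean_difference(
    differences: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AdjustedDifference:
    """Covariate-adjusted mean of per-subject differences.

    OLS of d_i on an intercept plus mean-centered covariates; the intercept is
    the adjusted mean difference, with its standard error and a two-sided p
    from the t distribution on n − 1 − k df.  With no covariates this is
    exactly the paired t-test.  Constant or collinear covariates fall back to
    the unadjusted test with a logged warning.
    """
    d = np.asarray(differences["diff"], dtype=np.float64)
    n = d.size
    covs = [c for c in covariates if c in differences.columns]
    if n < 2 + len(covs) + (1 if covs else 0):
        raise EstimationError(f"{n} pairs insufficient for {len(covs)} covariates")

    X = np.ones((n, 1))
    if covs:
        C = np.asarray(differences[covs], dtype=np.float64)
        C = C - C.mean(axis=0)
        if np.linalg.matrix_rank(np.hstack([X, C])) < 1 + C.shape[1]:
            logger.warning("collinear/constant covariates; falling back to unadjusted test")
        else:
            X = np.hstack([X, C])

    if np.allclose(d - d[0], 0.0) and X.shape[1] > 1:
        # zero-variance differences: adjusted model is degenerate
        return AdjustedDifference(float(d[0]), 0.0, 0.0 if d[0] != 0 else 1.0, n)
    res = sm.OLS(d, X).fit()
    se = float(res.bse[0])
    if se == 0.0:
        p = 0.0 if res.params[0] != 0 else 1.0
    else:
        p = float(res.pvalues[0])
    return AdjustedDifference(float(res.params[0]), se, p, n)


def within_condition_change(
    table: MeasurementTable,
    condition: str | Condition,
    from_timepoint: str | Timepoint,
    to_timepoint: str | Timepoint,
    ring: tuple[float, float],
    parameter: str,
) -> AdjustedDifference:
    """Paired t-test on per-subject changes between two timepoints within one
    condition; identical pairs give (0, 0, p=1) by convention."""
    cond = Condition(condition).value
    tp0, tp1 = Timepoint(from_timepoint).value, Timepoint(to_timepoint).value
    wide = _pivot(table, ring, parameter)
    for col in [(cond, tp0), (cond, tp1)]:
        if col not in wide.columns:
            raise EstimationError(f"no data for {col}")
    complete = wide[[(cond, tp0), (cond, tp1)]].dropna()
    if len(complete) < 2:
        raise EstimationError("fewer than 2 complete pairs")
    change = (complete[(cond, tp1)] - complete[(cond, tp0)]).to_numpy(dtype=np.float64)
    n = change.size
    mean = float(change.mean())
    sd = float(change.std(ddof=1))
    se = sd / math.sqrt(n)
    if sd == 0.0:
        return AdjustedDifference(mean, 0.0, 1.0 if mean == 0 else 0.0, n)
    t = mean / se
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return AdjustedDifference(mean, se, p, n)


def build_report(
    table: MeasurementTable,
    *,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    holm: bool = False,
) -> DifferenceReport:
    """Condition-contrast grid over all parameters, post-baseline timepoints
    and rings, with mean ± SE and significance flags at ``alpha``.

    ``holm=True`` applies a Holm step-down correction across the grid's
    p-values before flagging (off by default)."""
    rows = []
    if not table.data.empty:
        tps = [t.value for t in Timepoint if t is not Timepoint.BASELINE]
        for ring in table.rings:
            for parameter in PARAMETERS:
                for tp in tps:
                    try:
                        diffs = paired_differences(table, tp, ring, parameter)
                        est = adjusted_mean_difference(diffs, covariates)
                    except EstimationError as exc:
                        logger.warning("cell %s/%s/%s not estimable: %s", tp, ring, parameter, exc)
                        est = AdjustedDifference(math.nan, math.nan, math.nan, 0)
                    rows.append(
                        {
                            "timepoint": tp,
                            "ring_inner_mm": ring[0],
                            "ring_outer_mm": ring[1],
                            "parameter": parameter,
                            "n_pairs": est.n_pairs,
                            "mean_diff": est.mean_diff,
                            "se_diff": est.se,
                            "p_value": est.p_value,
                        }
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "timepoint", "ring_inner_mm", "ring_outer_mm", "parameter",
            "n_pairs", "mean_diff", "se_diff", "p_value",
        ],
    )
    if len(records):
        pvals = records["p_value"].to_numpy()
        if holm:
            finite = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            if finite.any():
                p = pvals[finite]
                order = np.argsort(p)
                m = p.size
                stepped = np.maximum.accumulate((m - np.arange(m)) * p[order])
                out = np.empty(m)
                out[order] = np.minimum(stepped, 1.0)
                adj[finite] = out
            records["p_adjusted"] = adj
            records["significant"] = adj < alpha
        else:
            records["significant"] = pvals < alpha
    else:
        records["significant"] = pd.Series(dtype=bool)
    return DifferenceReport(records=records, alpha=alpha)
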