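"""Within-subject drug-challenge statistics for 5-CSRTT cohorts.

Each subject is tested under vehicle and under drug; every behavioural
parameter is summarised as the log10 of the within-subject drug/vehicle
ratio, which puts multiplicative drug effects on an additive scale suitable
for parametric tests (one-sample t against 0 per group, paired t between two
drug conditions).  The two parameters that can hit exactly 0% (%premature
and %perseverative) are first integerised with a strict round-up rule —
values in [0, 1) become 1, [1, 2) become 2, and so on — applied symmetrically
to both conditions, so the ratio is always finite and sub-1% noise cannot
blow up the log scale.

Sidak adjustment and Pearson correlation screening (does the impulsivity
effect merely track omissions or latencies?) round out the toolbox.  The
omnibus mixed-design ANOVA machinery that the normalised values feed in a
full study is deliberately left to general statistics packages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateSampleError

__all__ = [
    "DEFAULT_FLOOR_PARAMS",
    "floor_rule",
    "log_ratio",
    "one_sample_t",
    "paired_t",
    "sidak_adjust",
    "pearson_r",
    "ChallengeTable",
    "challenge_table",
]

logger = logging.getLogger(__name__)

#: Parameters that can assume 0% and therefore go through the flooring rule.
DEFAULT_FLOOR_PARAMS = ("pct_premature", "pct_perseverative")


def floor_rule(x: float) -> int:
    """Round a percentage up to the next full integer: [0,1) -> 1, [1,2) -> 2, ...

    Equivalent to ``floor(x) + 1`` for all x >= 0; note that exact integers
    move up a band (1.0 -> 2).  Applied before the log-ratio transform to the
    parameters that can be exactly 0%.
    """
    if x < 0:
        raise ValueError(f"percentage must be >= 0, got {x}")
    return int(math.floor(x)) + 1


def log_ratio(drug: float, vehicle: float, apply_floor: bool = False) -> float:
    """log10 of the within-subject drug/vehicle ratio, optionally floored.

    With ``apply_floor`` both values are integerised by :func:`floor_rule`
    (symmetrically, so identical inputs always map to a ratio of 0) before
    the ratio is formed.
    """
    if apply_floor:
        drug, vehicle = floor_rule(drug), floor_rule(vehicle)
    if vehicle == 0:
        raise DegenerateSampleError(
            "vehicle value is 0; the ratio is undefined (enable flooring for "
            "parameters that can reach 0%)"
        )
    if drug == 0:
        raise DegenerateSampleError(
            "drug value is 0; the log-ratio is undefined (enable flooring for "
            "parameters that can reach 0%)"
        )
    return math.log10(drug / vehicle)


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> tuple[float, int, float]:
    """Classical one-sample t-test, two-sided.  Returns ``(t, df, p)``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateSampleError("one-sample t requires n >= 2")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("sample has zero variance")
    res = scipy.stats.ttest_1samp(arr, popmean=mu)
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Paired-sample t-test: a one-sample t on the pairwise differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return one_sample_t(a - b, mu=0.0)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment: ``1 - (1 - p)^m``, capped at 1.

    Exact under independence and never more conservative than Bonferroni.
    Family composition (which comparisons share an ``m``) is the caller's
    responsibility.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if p == 1.0 or m == 1:
        return p
    # -expm1(m*log1p(-p)) is the same quantity without cancellation for tiny p
    return min(1.0, -math.expm1(m * math.log1p(-p)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p.  Returns ``(r, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DegenerateSampleError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("a variable has zero variance")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _t_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    n = values.size
    mean = values.mean()
    se = values.std(ddof=1) / math.sqrt(n)
    half = scipy.stats.t.ppf(0.5 + level / 2.0, df=n - 1) * se
    return mean - half, mean + half


@dataclass
class ChallengeTable:
    """Results of one drug challenge across a cohort.

    ``subject_ratios``: per subject x parameter log10 drug/vehicle ratios
    (long format: subject, group, parameter, vehicle, drug, floored,
    log_ratio).  ``group_tests``: per group x parameter one-sample t of the
    log-ratios against 0, with mean, t-based confidence interval, t, df, p
    (NaN for degenerate groups).  ``correlations``: per group, Pearson r/p of
    the %premature log-ratio against every other parameter's log-ratio — the
    confound screen asking whether an anti-impulsive effect merely tracks
    disengagement or slowing.
    """

    subject_ratios: pd.DataFrame
    group_tests: pd.DataFrame
    correlations: pd.DataFrame


def challenge_table(
    metrics: pd.DataFrame,
    vehicle_condition: str = "vehicle",
    drug_condition: str | None = None,
    parameters: Sequence[str] | None = None,
    floor_params: Sequence[str] = DEFAULT_FLOOR_PARAMS,
    ci_level: float = 0.95,
    correlate_against: str = "pct_premature",
) -> ChallengeTable:
    """Assemble the full within-subject challenge analysis.

    ``metrics`` is long-format with columns ``subject``, ``group``,
    ``condition`` plus one column per behavioural parameter (the fields of
    :class:`impulscreen.task_engine.SessionMetrics`; per-session percentages
    and latencies).  Subjects lacking either condition, or with an undefined
    (absent) value for a parameter in either condition, are excluded from
    that parameter with a logged warning.
    """
    required = {"subject", "group", "condition"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    conditions = list(pd.unique(metrics["condition"]))
    if vehicle_condition not in conditions:
        raise ValueError(f"no rows for vehicle condition {vehicle_condition!r}")
    if drug_condition is None:
        others = [c for c in conditions if c != vehicle_condition]
        if len(others) != 1:
            raise ValueError(
                f"drug condition ambiguous ({others}); pass drug_condition"
            )
        drug_condition = others[0]
    if parameters is None:
        parameters = [
            c
            for c in metrics.columns
            if c not in required and pd.api.types.is_numeric_dtype(metrics[c])
        ]

    wide = metrics.pivot_table(
        index=["subject", "group"],
        columns="condition",
        values=list(parameters),
        aggfunc="mean",
    )

    rows = []
    for (subject, group) in wide.index:
        for param in parameters:
            try:
                veh = wide.loc[(subject, group), (param, vehicle_condition)]
                drug = wide.loc[(subject, group), (param, drug_condition)]
            except KeyError:
                veh = drug = np.nan
            if pd.isna(veh) or pd.isna(drug):
                logger.warning(
                    "subject %s excluded for %s: missing %s value",
                    subject,
                    param,
                    vehicle_condition if pd.isna(veh) else drug_condition,
                )
                continue
            floored = param in floor_params
            try:
                lr = log_ratio(drug, veh, apply_floor=floored)
            except DegenerateSampleError:
                logger.warning(
                    "subject %s excluded for %s: undefined ratio", subject, param
                )
                continue
            rows.append(
                dict(
                    subject=subject,
                    group=group,
                    parameter=param,
                    vehicle=veh,
                    drug=drug,
                    floored=floored,
                    log_ratio=lr,
                )
            )
    subject_ratios = pd.DataFrame(
        rows,
        columns=["subject", "group", "parameter", "vehicle", "drug", "floored", "log_ratio"],
    )

    test_rows = []
    for (group, param), chunk in subject_ratios.groupby(["group", "parameter"], sort=True):
        vals = chunk["log_ratio"].to_numpy()
        row = dict(
            group=group,
            parameter=param,
            n=len(vals),
            mean_log_ratio=float(vals.mean()) if len(vals) else np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            t=np.nan,
            df=len(vals) - 1,
            p=np.nan,
        )
        if len(vals) >= 2 and np.ptp(vals) > 0:
            t, df, p = one_sample_t(vals, 0.0)
            lo, hi = _t_ci(vals, ci_level)
            row.update(t=t, df=df, p=p, ci_low=lo, ci_high=hi)
        test_rows.append(row)
    group_tests = pd.DataFrame(
        test_rows,
        columns=["group", "parameter", "n", "mean_log_ratio", "ci_low", "ci_high", "t", "df", "p"],
    )

    corr_rows = []
    if correlate_against in set(subject_ratios["parameter"]):
        pivot = subject_ratios.pivot_table(
            index=["subject", "group"], columns="parameter", values="log_ratio"
        ).reset_index()
        for group, chunk in pivot.groupby("group", sort=True):
            base = chunk[correlate_against]
            for param in parameters:
                if param == correlate_against or param not in chunk.columns:
                    continue
                pair = pd.concat([base, chunk[param]], axis=1).dropna()
                if len(pair) < 3:
                    continue
                try:
                    r, p = pearson_r(pair.iloc[:, 0], pair.iloc[:, 1])
                except DegenerateSampleError:
                    continue
                corr_rows.append(
                    dict(group=group, against=correlate_against, parameter=param,
                         n=len(pair), r=r, p=p)
                )
    correlations = pd.DataFrame(
        corr_rows, columns=["group", "against", "parameter", "n", "r", "p"]
    )
    return ChallengeTable(subject_ratios, group_tests, correlations)
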