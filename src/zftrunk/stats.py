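"""Statistical layer for group comparisons of trunk measurements.

The protocol: measurements are log10-transformed, two groups are compared
with a two-tailed pooled-variance Student t test, three or more with
ordinary one-way ANOVA plus Tukey HSD, and categorical stainings with
Fisher's exact test (two categories) or the Pearson chi-square test (three
or more).  Touch-evoked escape-response counts are censored at 50 touches
at ingestion and then analyzed as plain numbers, as in the original
protocol.

Measurement tables are plain :class:`pandas.DataFrame` objects with columns
``unit_id, group, value`` (plus optional ``measure`` and ``embryo_id``);
transformations are recorded in ``df.attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

TOUCH_CAP = 50


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


def _check_table(t: pd.DataFrame) -> pd.DataFrame:
    for col in ("group", "value"):
        if col not in t.columns:
            raise ValueError(f"measurement table lacks a {col!r} column")
    if not np.isfinite(t["value"]).all():
        raise ValueError("measurement values must be finite")
    if (t["group"].astype(str) == "").any():
        raise ValueError("group labels must be non-empty")
    return t


def log_transform(t: pd.DataFrame, offset: float | None = None) -> pd.DataFrame:
    """log10-transform the ``value`` column.

    Values must be positive; zeros are an error unless an ``offset`` policy
    is supplied, in which case log10(value + offset) is used.  The applied
    transformation is recorded in ``df.attrs['transform']``.
    """
    t = _check_table(t)
    v = t["value"].to_numpy(float)
    if (v < 0).any():
        raise ValueError("cannot log-transform negative values")
    if offset is None:
        if (v == 0).any():
            raise ValueError(
                "zero values present; supply offset= to use log10(value + offset)"
            )
        out_v = np.log10(v)
        label = "log10(value)"
    else:
        if offset <= 0:
            raise ValueError("offset must be positive")
        out_v = np.log10(v + offset)
        label = f"log10(value + {offset})"
    out = t.copy()
    out["value"] = out_v
    out.attrs = dict(t.attrs)
    out.attrs["transform"] = label
    return out


def _groups(t: pd.DataFrame) -> dict[str, np.ndarray]:
    return {g: sub["value"].to_numpy(float) for g, sub in t.groupby("group", sort=True)}


def two_group_test(t: pd.DataFrame, welch: bool = False) -> TestResult:
    """Two-tailed Student t test between exactly two groups.

    Pooled-variance by default ("student t test"); ``welch=True`` switches
    to the unequal-variance form.  Groups are ordered alphabetically, so
    the sign of t is deterministic (first minus second).
    """
    t = _check_table(t)
    groups = _groups(t)
    if len(groups) != 2:
        raise ValueError(f"two_group_test needs exactly 2 groups, got {len(groups)}")
    (ga, a), (gb, b) = groups.items()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    dof = float(res.df)
    method = "welch_t" if welch else "student_t_pooled"
    return TestResult(float(res.statistic), dof, float(res.pvalue), method)


def multi_group_test(t: pd.DataFrame, alpha: float = 0.05):
    """Ordinary one-way ANOVA with Tukey HSD pairwise comparisons.

    Returns ``(TestResult, tukey_table)`` where the Tukey table is a
    DataFrame with columns group1, group2, meandiff, p_adj, lower, upper,
    reject.
    """
    t = _check_table(t)
    groups = _groups(t)
    if len(groups) < 3:
        raise ValueError(f"multi_group_test needs >= 3 groups, got {len(groups)}")
    sizes = {g: len(v) for g, v in groups.items()}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")
    F, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n = sum(sizes.values())
    anova = TestResult(float(F), float(k - 1), float(p), "one_way_anova")
    tuk = pairwise_tukeyhsd(
        t["value"].to_numpy(float), t["group"].astype(str).to_numpy(), alpha=alpha
    )
    tukey = pd.DataFrame(
        tuk.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    tukey["p_adj"] = np.asarray(tuk.pvalues, float)
    return anova, tukey


def categorical_test(table) -> TestResult:
    """Fisher's exact test (2x2) or Pearson chi-square (larger tables).

    ``table`` is a 2D array-like or DataFrame of non-negative integer
    counts, groups x categories.  The two-sided Fisher p sums the
    probabilities of all tables (at fixed margins) no more probable than
    the observed one.  Rows/columns with zero margin are an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.all(arr == np.round(arr)):
        raise ValueError("contingency table must hold non-negative integers")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero-margin row or column")
    if arr.shape == (2, 2):
        _, p = sps.fisher_exact(arr.astype(int), alternative="two-sided")
        return TestResult(float("nan"), 0.0, float(p), "fisher_exact")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(float(chi2), float(dof), float(p), "chi_square")


def ingest_touch_response(records: Iterable) -> pd.DataFrame:
    """Ingest touch-evoked escape-response counts, censoring at 50 touches.

    ``records`` yields ``(embryo_id, touches)`` pairs (or a DataFrame with
    those columns).  Counts above the cap are stored as 50 with
    ``censored=True`` — non-responders were recorded as 50 touches and
    analyzed as plain numbers.
    """
    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["embryo_id"], records["touches"]))
    else:
        pairs = [(e, n) for e, n in records]
    rows = []
    for embryo_id, touches in pairs:
        n = int(touches)
        if n < 1:
            raise ValueError(f"embryo {embryo_id!r}: touches must be >= 1, got {n}")
        capped = min(n, TOUCH_CAP)
        rows.append(
            {"embryo_id": embryo_id, "touches": capped, "censored": capped == TOUCH_CAP}
        )
    out = pd.DataFrame(rows, columns=["embryo_id", "touches", "censored"])
    out.attrs["censoring"] = f"touch counts capped at {TOUCH_CAP}"
    return out
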